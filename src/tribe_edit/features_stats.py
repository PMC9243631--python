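"""Downstream statistics on the predicted stress-granule transcriptome.

Transcript feature-length comparisons (Mann-Whitney), biotype breakdowns,
hypergeometric set-overlap tests, replicate QC matrices, intron-scope
editing reports, and smFISH colocalization plus the editing-vs-localization
regression.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from shapely import wkt as shapely_wkt
from shapely.geometry import Point

from .pileup_io import GeneModel
from .variant_detection import CallParams, spectrum_counts

EXACT_MW_CUTOFF = 10_000  # n1 * n2 at or below this: exact null distribution


def biotype_breakdown(gene_set, models: list[GeneModel] | dict[str, GeneModel]) -> dict[str, float]:
    """Fractions of each biotype among an annotated gene set."""
    by_id = models if isinstance(models, dict) else {g.gene_id: g for g in models}
    known = [g for g in gene_set if g in by_id]
    unknown = set(gene_set) - set(known)
    if unknown:
        warnings.warn(f"{len(unknown)} gene(s) missing from annotation; excluded", stacklevel=2)
    if not known:
        raise ValueError("no annotated genes in the set")
    counts: dict[str, int] = {}
    for g in known:
        counts[by_id[g].biotype] = counts.get(by_id[g].biotype, 0) + 1
    total = len(known)
    return {b: c / total for b, c in sorted(counts.items())}


def length_comparison(
    set_in,
    set_out,
    models: list[GeneModel] | dict[str, GeneModel],
    feature: str = "transcript",
) -> dict:
    """Compare a feature-length distribution between two gene sets.

    Returns median ratio (in/out), the Mann-Whitney U statistic of the first
    sample, and a two-sided p-value: the exact null distribution when
    n1 * n2 <= 1e4 and the data are tie-free, the tie-corrected normal
    approximation otherwise. Genes lacking the feature (e.g. UTRs of
    non-coding genes) are excluded.
    """
    by_id = models if isinstance(models, dict) else {g.gene_id: g for g in models}

    def lengths(genes) -> np.ndarray:
        vals = [by_id[g].feature_length(feature) for g in genes if g in by_id]
        return np.array([v for v in vals if v > 0], dtype=float)

    x, y = lengths(set_in), lengths(set_out)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both gene sets need at least one gene with the feature defined")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) * len(y) <= EXACT_MW_CUTOFF and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {
        "median_in": float(np.median(x)),
        "median_out": float(np.median(y)),
        "median_ratio": float(np.median(x) / np.median(y)),
        "U": float(res.statistic),
        "p_value": float(res.pvalue),
        "method": method,
        "n_in": len(x),
        "n_out": len(y),
    }


def hypergeometric_overlap(set_a, set_b, universe) -> tuple[int, float, float]:
    """Upper-tail hypergeometric test for the overlap of two gene sets.

    Returns (overlap count, overlap / |A|, P[X >= overlap]) where X counts
    the overlap of a random |B|-subset of the universe with A.
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValueError("both sets must be subsets of the universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, len(u), len(a), len(b)))
    frac = k / len(a) if a else float("nan")
    return k, frac, p


def replicate_qc(freq_table: pd.DataFrame, value: str = "editing_freq") -> dict:
    """Pairwise sample correlation and Euclidean distance matrices.

    ``freq_table`` holds per-gene per-sample values (gene_id, sample_id,
    value column); genes missing in a sample are treated as 0 for the
    distance and dropped pairwise for the correlation.
    """
    wide = freq_table.pivot_table(index="gene_id", columns="sample_id", values=value)
    if wide.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    corr = wide.corr(method="pearson")  # pairwise-complete
    constant = wide.std(ddof=0) == 0
    if constant.any():
        warnings.warn(
            f"constant sample(s) {list(wide.columns[constant])}: correlation undefined", stacklevel=2
        )
    dense = wide.fillna(0.0)
    dist = pd.DataFrame(
        squareform(pdist(dense.T.to_numpy(), metric="euclidean")),
        index=dense.columns,
        columns=dense.columns,
    )
    return {"correlation": corr, "distance": dist}


def intron_editing_report(
    variants: pd.DataFrame,
    counts: pd.DataFrame | None = None,
    params: CallParams | None = None,
) -> dict:
    """Intron-scope base-change spectrum with simple dominance calls.

    Reports the twelve-class spectrum restricted to intronic positions,
    whether A>G is the strictly dominant class, and (when the count table is
    supplied) whether the intronic A>G site count is higher under arsenite
    than in Schneider's.
    """
    spec = spectrum_counts(variants, scope="intron", params=params)
    by_class = dict(zip(spec["mismatch_class"], spec["count"]))
    ag = by_class.get("A>G", 0)
    others = [v for c, v in by_class.items() if c != "A>G"]
    out = {
        "spectrum": spec,
        "n_intronic_sites": int(spec["count"].sum()),
        "ag_dominant": bool(ag > 0 and ag > max(others)),
    }
    if counts is not None and len(variants.loc[variants["region"] == "intron"]):
        per_cond = spectrum_counts(variants, counts=counts, scope="intron", per_condition=True, params=params)
        ag_cond = per_cond.loc[per_cond["mismatch_class"] == "A>G"].set_index("condition")["count"]
        out["per_condition_ag"] = ag_cond.to_dict()
        if {"arsenite", "schneiders"} <= set(ag_cond.index):
            out["arsenite_exceeds_basal"] = bool(ag_cond["arsenite"] > ag_cond["schneiders"])
    return out


def smfish_colocalization(spots: pd.DataFrame, granules: pd.DataFrame) -> pd.DataFrame:
    """Per-gene fraction of RNA spots inside their cell's granule regions.

    Granule regions are WKT polygons per cell (column ``granule_wkt``);
    boundary points count as inside. Also reports per-gene spot totals;
    genes appear only if they have at least one spot.
    """
    polys: dict[str, list] = {}
    for row in granules.itertuples():
        polys.setdefault(row.cell_id, []).append(shapely_wkt.loads(row.granule_wkt))

    def inside(row) -> bool:
        regions = polys.get(row.cell_id, [])
        pt = Point(row.x, row.y)
        return any(region.intersects(pt) for region in regions)  # boundary-inclusive

    if spots.empty:
        return pd.DataFrame(columns=["gene_id", "n_spots", "n_in_granule", "fraction_in_granule"])
    flags = spots.apply(inside, axis=1)
    out = (
        spots.assign(in_granule=flags.to_numpy())
        .groupby("gene_id", observed=True)
        .agg(n_spots=("in_granule", "size"), n_in_granule=("in_granule", "sum"))
        .reset_index()
    )
    out["fraction_in_granule"] = out["n_in_granule"] / out["n_spots"]
    return out


def editing_localization_regression(
    fold_changes: pd.Series | dict,
    colocalization_fractions: pd.Series | dict,
    infinite_policy: str = "exclude",
    log_fold: bool = False,
) -> dict:
    """OLS of granule colocalization on editing fold change.

    Genes with infinite fold change (no basal editing) are excluded by
    default or winsorized to the largest finite fold change with
    ``infinite_policy='winsorize'``. ``log_fold`` regresses on log2 fold
    change instead of the raw ratio.
    """
    fc = pd.Series(fold_changes, dtype=float)
    frac = pd.Series(colocalization_fractions, dtype=float)
    common = fc.index.intersection(frac.index)
    fc, frac = fc[common], frac[common]
    finite = np.isfinite(fc)
    if infinite_policy == "exclude":
        fc, frac = fc[finite], frac[finite]
        n_excluded = int((~finite).sum())
    elif infinite_policy == "winsorize":
        if finite.any():
            fc = fc.clip(upper=fc[finite].max())
        n_excluded = 0
    else:
        raise ValueError("infinite_policy must be 'exclude' or 'winsorize'")
    if len(fc) < 3:
        raise ValueError("need at least 3 paired genes with finite fold change")
    x = np.log2(fc.to_numpy()) if log_fold else fc.to_numpy()
    if np.std(x) == 0:
        raise ValueError("zero variance in fold change; slope undefined")
    res = stats.linregress(x, frac.to_numpy())
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p_value": float(res.pvalue),
        "n": len(fc),
        "n_excluded_infinite": n_excluded,
    }
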
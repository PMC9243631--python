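"""Edit-site calling from base-count tables.

Candidate positions are pooled over all samples (discovery on merged
libraries), scored with a binomial-tail phred-like quality against a fixed
sequencing-error rate, and filtered on quality (> 250 by default), pooled
allele frequency (< 0.95, removing homozygous variants), depth, and a
known-variant exclusion list. Mismatch classes are reported in transcript
orientation: a genomic T>C on a minus-strand gene is an A>G edit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pileup_io import BASES, COMPLEMENT

#: the twelve possible single-base mismatch classes, transcript orientation
MISMATCH_CLASSES = tuple(f"{r}>{a}" for r in BASES for a in BASES if r != a)

MAX_QUAL = 5000.0


@dataclass
class CallParams:
    """Filter thresholds for edit-site calling."""

    error_rate: float = 1e-3
    qual_min: float = 250.0
    af_max: float = 0.95
    min_depth: int = 10
    min_alt: int = 3

    def validate(self) -> None:
        if not 0.0 < self.error_rate < 1.0:
            raise ValueError("error_rate must be in (0, 1)")
        if self.min_depth < 0 or self.min_alt < 0:
            raise ValueError("min_depth and min_alt must be non-negative")


@dataclass
class VariantPosition:
    """A retained candidate edit site."""

    chrom: str
    pos: int
    gene_id: str
    strand: str
    ref_base: str
    alt_base: str
    mismatch_class: str
    qual_score: float
    pooled_af: float
    pooled_alt: int
    pooled_depth: int
    region: str = "exon"
    flags: set[str] = field(default_factory=set)


def quality_score(alt_count, depth, error_rate: float = 1e-3):
    """Phred-like evidence that ``alt_count`` of ``depth`` exceeds error.

    ``-10 * log10 P[Binomial(depth, error_rate) >= alt_count]``, capped at
    5000; zero when depth or alt_count is zero. Monotone non-decreasing in
    alt_count at fixed depth. Accepts scalars or arrays.
    """
    if not 0.0 < error_rate < 1.0:
        raise ValueError("error_rate must be in (0, 1)")
    alt = np.asarray(alt_count)
    n = np.asarray(depth)
    if (alt > n).any() or (alt < 0).any():
        raise ValueError("need 0 <= alt_count <= depth")
    with np.errstate(divide="ignore"):
        tail = stats.binom.sf(alt - 1, np.maximum(n, 1), error_rate)
        score = np.where((n == 0) | (alt == 0), 0.0, -10.0 * np.log10(tail))
    score = np.minimum(np.nan_to_num(score, nan=MAX_QUAL, posinf=MAX_QUAL), MAX_QUAL)
    return float(score) if np.isscalar(alt_count) else score


def classify_base_change(ref_base: str, alt_base: str, strand: str) -> str:
    """Transcript-oriented mismatch class of a genomic substitution."""
    if ref_base not in BASES or alt_base not in BASES:
        raise ValueError(f"invalid base in ({ref_base!r}, {alt_base!r})")
    if ref_base == alt_base:
        raise ValueError("ref and alt must differ")
    if strand not in ("+", "-"):
        raise ValueError(f"invalid strand {strand!r}")
    if strand == "-":
        ref_base, alt_base = COMPLEMENT[ref_base], COMPLEMENT[alt_base]
    return f"{ref_base}>{alt_base}"


def _pool_counts(counts: pd.DataFrame) -> pd.DataFrame:
    keys = ["chrom", "pos", "gene_id", "strand", "ref_base", "region"]
    pooled = (
        counts.groupby(keys, sort=True, observed=True)[["count_A", "count_C", "count_G", "count_T", "depth"]]
        .sum()
        .reset_index()
    )
    return pooled


def _best_alt(pooled: pd.DataFrame) -> pd.DataFrame:
    """Highest-count non-reference base per position; ties to A<C<G<T order."""
    cmat = pooled[["count_A", "count_C", "count_G", "count_T"]].to_numpy(dtype=np.int64)
    ref_idx = pd.Series(pooled["ref_base"]).map({b: i for i, b in enumerate(BASES)}).to_numpy()
    masked = cmat.copy()
    known_ref = ref_idx >= 0
    rows = np.arange(len(pooled))
    # unknown reference (N): take the overall majority base as reference
    if (~known_ref).any():
        ref_idx = np.where(known_ref, ref_idx, cmat.argmax(axis=1))
    masked[rows, ref_idx.astype(int)] = -1
    alt_idx = masked.argmax(axis=1)  # argmax breaks ties at the lowest index
    out = pooled.copy()
    out["ref_base"] = np.array(BASES)[ref_idx.astype(int)]
    out["alt_base"] = np.array(BASES)[alt_idx]
    out["alt_count"] = cmat[rows, alt_idx]
    return out


def call_variant_positions(
    counts: pd.DataFrame,
    known_variants: set[tuple[str, int, str]] | None = None,
    params: CallParams | None = None,
) -> pd.DataFrame:
    """Call candidate edit sites on sample-pooled base counts.

    Returns one row per retained (position, alt): transcript-oriented
    mismatch class, phred-like quality of the pooled counts, and pooled
    allele frequency. A position yields at most one alternative allele (the
    highest-count non-reference base, ties broken in A<C<G<T order).
    """
    params = params or CallParams()
    params.validate()
    known = known_variants or set()
    if counts.empty:
        return _empty_variants()
    pooled = _best_alt(_pool_counts(counts))
    with np.errstate(invalid="ignore"):
        pooled["pooled_af"] = np.where(
            pooled["depth"] > 0, pooled["alt_count"] / pooled["depth"], 0.0
        )
    pooled["qual_score"] = quality_score(
        pooled["alt_count"].to_numpy(), pooled["depth"].to_numpy(), params.error_rate
    )
    pooled["known_variant"] = [
        (c, p, a) in known
        for c, p, a in zip(pooled["chrom"], pooled["pos"], pooled["alt_base"])
    ]
    keep = (
        (pooled["alt_count"] >= params.min_alt)
        & (pooled["depth"] >= params.min_depth)
        & (pooled["qual_score"] > params.qual_min)
        & (pooled["pooled_af"] < params.af_max)
        & ~pooled["known_variant"]
    )
    out = pooled.loc[keep].copy()
    out["mismatch_class"] = [
        classify_base_change(r, a, s)
        for r, a, s in zip(out["ref_base"], out["alt_base"], out["strand"])
    ]
    out = out.rename(columns={"alt_count": "pooled_alt", "depth": "pooled_depth"})
    cols = [
        "chrom", "pos", "gene_id", "strand", "ref_base", "alt_base",
        "mismatch_class", "region", "qual_score", "pooled_af", "pooled_alt", "pooled_depth",
    ]
    return out[cols].reset_index(drop=True)


def _empty_variants() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "chrom", "pos", "gene_id", "strand", "ref_base", "alt_base",
            "mismatch_class", "region", "qual_score", "pooled_af", "pooled_alt", "pooled_depth",
        ]
    )


def spectrum_counts(
    variants: pd.DataFrame,
    counts: pd.DataFrame | None = None,
    scope: str = "exon",
    per_condition: bool = False,
    params: CallParams | None = None,
) -> pd.DataFrame:
    """Tabulate retained sites per mismatch class (base-change spectrum).

    With ``per_condition`` (requires the base-count table), a site counts for
    a condition iff its condition-pooled alternative count passes ``min_alt``
    and the condition-pooled quality passes ``qual_min``. Always returns all
    twelve classes, zero-filled.
    """
    if scope not in ("exon", "intron"):
        raise ValueError("scope must be 'exon' or 'intron'")
    sel = variants.loc[variants["region"] == scope]
    if not per_condition:
        tab = sel["mismatch_class"].value_counts()
        return (
            pd.DataFrame({"mismatch_class": MISMATCH_CLASSES})
            .assign(count=lambda d: d["mismatch_class"].map(tab).fillna(0).astype(int))
        )
    if counts is None:
        raise ValueError("per_condition spectra require the base-count table")
    params = params or CallParams()
    key = ["chrom", "pos", "gene_id"]
    alt_col = {b: f"count_{b}" for b in BASES}
    merged = counts.merge(sel[key + ["alt_base", "mismatch_class"]], on=key, how="inner")
    merged["alt_count"] = merged.apply(lambda r: r[alt_col[r["alt_base"]]], axis=1)
    pooled = (
        merged.groupby(key + ["mismatch_class", "condition"], observed=True)[["alt_count", "depth"]]
        .sum()
        .reset_index()
    )
    pooled["qual"] = quality_score(
        pooled["alt_count"].to_numpy(), pooled["depth"].to_numpy(), params.error_rate
    )
    ok = pooled.loc[(pooled["alt_count"] >= params.min_alt) & (pooled["qual"] > params.qual_min)]
    tab = ok.groupby(["condition", "mismatch_class"], observed=True).size().unstack(fill_value=0)
    tab = tab.reindex(columns=MISMATCH_CLASSES, fill_value=0)
    return tab.reset_index().melt(id_vars="condition", var_name="mismatch_class", value_name="count")
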
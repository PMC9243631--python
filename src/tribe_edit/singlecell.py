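"""Per-cell editing metrics, pseudobulk aggregation and bulk concordance.

Single-cell tables reuse the bulk base-count schema with the cell barcode as
``sample_id`` plus a companion cell table (cell_id, condition, adar_count,
total_umis). Pseudobulk is the position-wise sum of raw counts over cells of
a condition, so variant calling and the EB differential test run on it
unchanged.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .editing_metrics import site_counts_for_genes
from .features_stats import hypergeometric_overlap
from .pileup_io import COUNT_TABLE_COLUMNS


def filter_cells(cells: pd.DataFrame, min_umis: int = 0) -> pd.DataFrame:
    """Retain cells with at least ``min_umis`` total counts."""
    kept = cells.loc[cells["total_umis"] >= min_umis].reset_index(drop=True)
    if kept.empty and len(cells):
        warnings.warn("no cells pass the UMI threshold", stacklevel=2)
    return kept


def pseudobulk_aggregate(sc_counts: pd.DataFrame, cells: pd.DataFrame | None = None) -> pd.DataFrame:
    """Sum per-cell base counts into one synthetic sample per condition.

    If ``cells`` is given, only its cell_ids contribute (post-filtering);
    all cells otherwise. Replicate is fixed at 1 and the sample_id becomes
    ``pseudobulk_<condition>``.
    """
    df = sc_counts
    if cells is not None:
        df = df.loc[df["sample_id"].isin(set(cells["cell_id"]))]
    keys = ["chrom", "pos", "gene_id", "strand", "ref_base", "region", "condition"]
    agg = (
        df.groupby(keys, observed=True)[["count_A", "count_C", "count_G", "count_T", "depth"]]
        .sum()
        .reset_index()
    )
    agg["sample_id"] = "pseudobulk_" + agg["condition"].astype(str)
    agg["replicate"] = 1
    return agg[COUNT_TABLE_COLUMNS]


def per_cell_mean_editing(sc_counts: pd.DataFrame, variants: pd.DataFrame) -> pd.DataFrame:
    """Mean editing frequency over genes for every cell.

    Within a cell, each gene's frequency is the unweighted mean of its
    covered retained sites' per-site frequencies; the cell value is the
    unweighted mean over genes with any covered site. Cells covering no
    retained site are absent from the result (flagged by omission).
    """
    site_counts = site_counts_for_genes(sc_counts, variants)
    if site_counts.empty:
        return pd.DataFrame(columns=["sample_id", "condition", "mean_editing_freq", "n_genes"])
    site_counts["freq"] = site_counts["alt_count"] / site_counts["depth"]
    gene_freq = (
        site_counts.groupby(["sample_id", "condition", "gene_id"], observed=True)["freq"]
        .mean()
        .reset_index()
    )
    out = (
        gene_freq.groupby(["sample_id", "condition"], observed=True)
        .agg(mean_editing_freq=("freq", "mean"), n_genes=("gene_id", "nunique"))
        .reset_index()
    )
    return out


def adar_editing_correlation(
    cells: pd.DataFrame, cell_editing: pd.DataFrame
) -> tuple[float, float]:
    """Pearson correlation of per-cell ADAR count with mean editing frequency."""
    merged = cells.merge(cell_editing, left_on="cell_id", right_on="sample_id", how="inner")
    if len(merged) < 3:
        raise ValueError("need at least 3 cells with defined mean editing")
    x = merged["adar_count"].to_numpy(float)
    y = merged["mean_editing_freq"].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def bulk_pseudobulk_overlap(
    diff_bulk: pd.DataFrame, diff_pseudobulk: pd.DataFrame
) -> dict:
    """Concordance of significant gene sets between bulk and pseudobulk.

    Fraction is |A intersect B| / |A| with A the bulk significant set; the
    p-value is the upper-tail hypergeometric probability over the union of
    tested genes.
    """
    universe = set(diff_bulk["gene_id"]) | set(diff_pseudobulk["gene_id"])
    set_a = set(diff_bulk.loc[diff_bulk["significant"], "gene_id"])
    set_b = set(diff_pseudobulk.loc[diff_pseudobulk["significant"], "gene_id"])
    if not set_a:
        return {"overlap": 0, "fraction": float("nan"), "p_value": float("nan")}
    overlap, _, p = hypergeometric_overlap(set_a, set_b, universe)
    return {"overlap": overlap, "fraction": overlap / len(set_a), "p_value": p}
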
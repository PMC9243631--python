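"""Per-position and per-gene editing frequencies and condition fold changes.

Two gene-level summaries are supported. Strategy A ("average editing
frequency", the primary analysis) averages the per-site frequencies of a
gene's retained edit sites; e.g. sites 17/53 = 0.32 and 23/58 = 0.39 average
to 0.358. Strategy B pools counts first: (17 + 23) / (53 + 58) = 0.36. The
strategies coincide exactly when all site depths are equal and diverge for
genes with strongly varying depth across sites.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pileup_io import BASES

_KEY = ["chrom", "pos", "gene_id"]


def position_editing_frequency(alt_count: int, depth: int) -> float:
    """Fraction of reads at a site carrying the edited base."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0 <= alt_count <= depth:
        raise ValueError("need 0 <= alt_count <= depth")
    return alt_count / depth


def site_counts_for_genes(counts: pd.DataFrame, variants: pd.DataFrame) -> pd.DataFrame:
    """Per-sample (alt_count, depth) at every retained variant site.

    Restricts the base-count table to retained sites and extracts the count
    of each site's called alternative allele. Rows with zero depth in a
    sample are dropped (no coverage is not evidence of no editing).
    """
    sel = variants[_KEY + ["alt_base", "strand", "region"]]
    merged = counts.merge(sel, on=_KEY, how="inner", suffixes=("", "_var"))
    if merged.empty:
        return pd.DataFrame(
            columns=_KEY + ["sample_id", "condition", "replicate", "alt_count", "depth"]
        )
    cmat = merged[[f"count_{b}" for b in BASES]].to_numpy()
    alt_idx = merged["alt_base"].map({b: i for i, b in enumerate(BASES)}).to_numpy()
    merged["alt_count"] = cmat[np.arange(len(merged)), alt_idx]
    merged = merged.loc[merged["depth"] > 0]
    return merged[_KEY + ["sample_id", "condition", "replicate", "alt_count", "depth"]].reset_index(drop=True)


def gene_average_editing_frequency(sites: pd.DataFrame | list[tuple[int, int]]) -> float:
    """Strategy A: unweighted mean of per-site frequencies."""
    alt, depth = _as_arrays(sites)
    covered = depth > 0
    if not covered.any():
        raise ValueError("no covered site")
    return float(np.mean(alt[covered] / depth[covered]))


def gene_pooled_editing_frequency(sites: pd.DataFrame | list[tuple[int, int]]) -> float:
    """Strategy B: summed edits over summed depth."""
    alt, depth = _as_arrays(sites)
    total = depth.sum()
    if total <= 0:
        raise ValueError("no covered site")
    return float(alt.sum() / total)


def _as_arrays(sites) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(sites, pd.DataFrame):
        return sites["alt_count"].to_numpy(float), sites["depth"].to_numpy(float)
    arr = np.asarray(sites, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected (alt, depth) pairs")
    return arr[:, 0], arr[:, 1]


def summarize_gene_condition(
    site_counts: pd.DataFrame,
    strategy: str = "A",
    replicate_mode: str = "pool",
) -> pd.DataFrame:
    """Per gene x condition editing summary.

    ``pool`` concatenates replicate site observations before applying the
    strategy (each replicate's coverage of a site is a separate observation
    for strategy A, and counts simply add for strategy B); ``mean`` applies
    the strategy per replicate and averages the replicate values.
    Returns columns gene_id, condition, editing_freq, n_sites, total_alt,
    total_depth.
    """
    if strategy not in ("A", "B"):
        raise ValueError("strategy must be 'A' or 'B'")
    if replicate_mode not in ("pool", "mean"):
        raise ValueError("replicate_mode must be 'pool' or 'mean'")
    if site_counts.empty:
        return pd.DataFrame(
            columns=["gene_id", "condition", "editing_freq", "n_sites", "total_alt", "total_depth"]
        )
    df = site_counts.copy()
    totals = (
        df.groupby(["gene_id", "condition"], observed=True)
        .agg(
            n_sites=("pos", "nunique"),
            total_alt=("alt_count", "sum"),
            total_depth=("depth", "sum"),
        )
        .reset_index()
    )
    if replicate_mode == "pool":
        if strategy == "A":
            df["freq"] = df["alt_count"] / df["depth"]
            freq = df.groupby(["gene_id", "condition"], observed=True)["freq"].mean()
        else:
            freq = (
                df.groupby(["gene_id", "condition"], observed=True)
                .apply(lambda g: g["alt_count"].sum() / g["depth"].sum(), include_groups=False)
            )
    else:
        if strategy == "A":
            df["freq"] = df["alt_count"] / df["depth"]
            per_rep = df.groupby(["gene_id", "condition", "replicate"], observed=True)["freq"].mean()
        else:
            per_rep = (
                df.groupby(["gene_id", "condition", "replicate"], observed=True)
                .apply(lambda g: g["alt_count"].sum() / g["depth"].sum(), include_groups=False)
            )
        freq = per_rep.groupby(["gene_id", "condition"], observed=True).mean()
    out = totals.merge(freq.rename("editing_freq").reset_index(), on=["gene_id", "condition"])
    return out[["gene_id", "condition", "editing_freq", "n_sites", "total_alt", "total_depth"]]


def per_sample_gene_frequencies(site_counts: pd.DataFrame, strategy: str = "A") -> pd.DataFrame:
    """Per gene x sample frequency table (heatmap / replicate-QC substrate)."""
    if site_counts.empty:
        return pd.DataFrame(columns=["gene_id", "sample_id", "condition", "editing_freq"])
    df = site_counts.copy()
    if strategy == "A":
        df["freq"] = df["alt_count"] / df["depth"]
        freq = df.groupby(["gene_id", "sample_id", "condition"], observed=True)["freq"].mean()
    elif strategy == "B":
        freq = (
            df.groupby(["gene_id", "sample_id", "condition"], observed=True)
            .apply(lambda g: g["alt_count"].sum() / g["depth"].sum(), include_groups=False)
        )
    else:
        raise ValueError("strategy must be 'A' or 'B'")
    return freq.rename("editing_freq").reset_index()


def editing_fold_change(freq_stress: float, freq_basal: float, pseudo: float = 0.0) -> tuple[float, bool]:
    """Stress/basal frequency ratio; (+inf, True) when basal is exactly zero.

    The boolean marks a group-3-like gene (edited only under stress) whose
    ratio is undefined without a pseudocount.
    """
    num = freq_stress + pseudo
    den = freq_basal + pseudo
    if den == 0:
        return (float("inf"), True) if num > 0 else (float("nan"), False)
    return num / den, False
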
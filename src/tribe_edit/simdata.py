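"""Synthetic bulk and single-cell datasets with known editing structure.

The generator emulates the experimental design of an RBP-ADARcd (hyperTRIBE)
stress-granule profiling experiment in cultured cells: three conditions
(uninduced / basal Schneider's medium / arsenite stress) in triplicate,
sparse per-transcript A-to-G edit sites (a handful of adenosines out of ~150
candidates per gene), beta-distributed site editing rates with binomial
sampling at negative-binomially overdispersed coverage, uniform sequencing
error across all twelve mismatch classes, both gene strands, and a low-depth
single-cell regime in which per-cell editing scales with the cell's ADAR
fusion expression.

Everything is generated in transcript orientation and complemented into
genome orientation for minus-strand genes at emission, so a plus-strand and
a minus-strand gene with the same seed carry identical transcript-oriented
signal.

Ground truth (per-gene group labels and per-site true rates) is returned
alongside every dataset so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .pileup_io import (
    BASES,
    COMPLEMENT,
    COUNT_TABLE_COLUMNS,
    CONDITIONS,
    GeneModel,
    GenomicInterval,
)

_BASE_TO_IDX = {b: i for i, b in enumerate(BASES)}
_COMP_IDX = np.array([_BASE_TO_IDX[COMPLEMENT[b]] for b in BASES])  # A<->T, C<->G

#: conditions carrying fusion-protein editing signal
_EDITING_CONDITIONS = ("schneiders", "arsenite")


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults describe the study conditions: triplicate bulk libraries in
    three conditions, ~150 candidate positions per gene of which five are
    truly edited, 20% stress-granule genes of which a quarter show no basal
    editing at all, mean coverage 100x, sequencing error 1e-3 per base, and
    a 300-cell single-cell regime at shallow depth.
    """

    n_genes: int = 1000
    positions_per_gene: int = 150
    edited_sites_per_gene: int = 5
    frac_sg_genes: float = 0.2
    frac_group3: float = 0.25
    frac_nonsg_unedited: float = 0.4
    frac_endogenous: float = 0.2
    frac_low_expression: float = 0.05
    mean_depth: float = 100.0
    depth_dispersion: float = 5.0
    editing_rate_basal: tuple[float, float] = (2.0, 38.0)
    editing_rate_arsenite: tuple[float, float] = (5.0, 15.0)
    seq_error_rate: float = 1e-3
    frac_minus_strand: float = 0.5
    n_replicates: int = 3
    intron_positions_per_gene: int = 0
    intron_edited_sites_per_gene: int = 0
    intron_depth_factor: float = 0.3
    n_cells: int = 300
    cell_depth_mean: float = 1.0
    adar_mean: float = 5.0
    adar_effect: float = 0.2
    rng_seed: int = 0
    position_spacing: int = 3
    chrom: str = "2L"

    def validate(self) -> None:
        probs = {
            "frac_sg_genes": self.frac_sg_genes,
            "frac_group3": self.frac_group3,
            "frac_nonsg_unedited": self.frac_nonsg_unedited,
            "frac_endogenous": self.frac_endogenous,
            "frac_low_expression": self.frac_low_expression,
            "seq_error_rate": self.seq_error_rate,
            "frac_minus_strand": self.frac_minus_strand,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name, (a, b) in (
            ("editing_rate_basal", self.editing_rate_basal),
            ("editing_rate_arsenite", self.editing_rate_arsenite),
        ):
            if not (a > 0 and b > 0):
                raise ValueError(f"{name} Beta parameters must be positive, got {(a, b)}")
        if self.edited_sites_per_gene > self.positions_per_gene:
            raise ValueError("edited_sites_per_gene exceeds positions_per_gene")
        if self.intron_edited_sites_per_gene > self.intron_positions_per_gene:
            raise ValueError("intron_edited_sites_per_gene exceeds intron_positions_per_gene")
        if min(self.n_genes, self.positions_per_gene, self.n_replicates) < 1:
            raise ValueError("n_genes, positions_per_gene, n_replicates must be >= 1")
        if self.mean_depth < 0 or self.depth_dispersion <= 0:
            raise ValueError("mean_depth must be >= 0 and depth_dispersion > 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Simulation truth: per-gene labels and per-site true editing rates."""

    genes: pd.DataFrame  # gene_id, group, sg, endogenous, strand, low_expression
    sites: pd.DataFrame  # gene_id, chrom, pos, region, rate per condition
    cells: pd.DataFrame | None = None  # cell_id, condition, adar_count


# ---------------------------------------------------------------------------
# gene-level layout
# ---------------------------------------------------------------------------

def _gene_layout(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_genes
    width = max(4, len(str(n)))
    gene_ids = np.array([f"gene{i + 1:0{width}d}" for i in range(n)])

    n_sg = int(round(config.frac_sg_genes * n))
    n_g3 = int(round(config.frac_group3 * n_sg))
    order = rng.permutation(n)
    sg = np.zeros(n, dtype=bool)
    sg[order[:n_sg]] = True
    group3 = np.zeros(n, dtype=bool)
    group3[order[:n_g3]] = True  # group-3 genes are a subset of SG genes

    non_sg_idx = order[n_sg:]
    n_unedited = int(round(config.frac_nonsg_unedited * len(non_sg_idx)))
    unedited = np.zeros(n, dtype=bool)
    unedited[non_sg_idx[:n_unedited]] = True

    strand = np.full(n, "+")
    n_minus = int(round(config.frac_minus_strand * n))
    strand[rng.permutation(n)[:n_minus]] = "-"

    low_expr = rng.random(n) < config.frac_low_expression

    # basally-edited genes (group 2 + edited non-SG) may be endogenously edited
    basal_edited = ~group3 & ~unedited
    endo = basal_edited & (rng.random(n) < config.frac_endogenous)

    group = np.where(group3, 3, np.where(sg, 2, 1))
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "group": group,
            "sg": sg,
            "unedited": unedited,
            "endogenous": endo,
            "strand": strand,
            "low_expression": low_expr,
        }
    )


def _site_rates(config: SimConfig, genes: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """True per-site editing rates per condition, for exonic and intronic sites.

    Non-SG edited genes share one rate across the two induced conditions
    (they are edited but not differentially), so a config with
    ``frac_sg_genes=0`` is an exact null for the differential test.
    """
    rows = []
    a_b, b_b = config.editing_rate_basal
    a_a, b_a = config.editing_rate_arsenite
    region_plan = [("exon", config.edited_sites_per_gene)]
    if config.intron_edited_sites_per_gene:
        region_plan.append(("intron", config.intron_edited_sites_per_gene))
    for g in genes.itertuples():
        for region, n_sites in region_plan:
            for _ in range(n_sites):
                if g.unedited:
                    basal = 0.0
                elif g.group == 3:
                    basal = 0.0
                else:
                    basal = float(rng.beta(a_b, b_b))
                if g.sg:
                    ars = float(rng.beta(a_a, b_a))
                else:
                    ars = basal
                unind = basal if g.endogenous else 0.0
                rows.append((g.gene_id, region, unind, basal, ars))
    return pd.DataFrame(
        rows, columns=["gene_id", "region", "rate_uninduced", "rate_schneiders", "rate_arsenite"]
    )


# ---------------------------------------------------------------------------
# bulk counts
# ---------------------------------------------------------------------------

def _positions_frame(config: SimConfig, genes: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Static per-position frame in transcript orientation.

    Edited sites have transcript reference A; all other positions draw a
    uniform reference base. Intronic candidate positions (if configured)
    follow the exonic block of each gene.
    """
    n_exon = config.positions_per_gene
    n_intron = config.intron_positions_per_gene
    per_gene = n_exon + n_intron
    n = config.n_genes * per_gene
    gene_idx = np.repeat(np.arange(config.n_genes), per_gene)
    offset = np.tile(np.arange(per_gene), config.n_genes)
    gene_span = (per_gene + 10) * config.position_spacing
    pos = gene_idx * gene_span + offset * config.position_spacing
    region = np.where(offset < n_exon, "exon", "intron")

    tref = rng.integers(0, 4, size=n)  # transcript-orientation reference base

    edited = np.zeros(n, dtype=bool)
    site_rate_idx = np.full(n, -1)
    rate_cursor = 0

    def pick_adenosines(lo: int, hi: int, n_pick: int) -> np.ndarray:
        """Edited sites come from existing adenosines so the overall base
        composition stays uniform; only tiny genes short of A's convert
        other positions."""
        block = np.arange(lo, hi)
        a_pos = block[tref[lo:hi] == _BASE_TO_IDX["A"]]
        if len(a_pos) >= n_pick:
            return rng.choice(a_pos, size=n_pick, replace=False)
        extra = rng.choice(
            block[tref[lo:hi] != _BASE_TO_IDX["A"]], size=n_pick - len(a_pos), replace=False
        )
        tref[extra] = _BASE_TO_IDX["A"]
        return np.concatenate([a_pos, extra])

    for gi in range(config.n_genes):
        base = gi * per_gene
        picks = [pick_adenosines(base, base + n_exon, config.edited_sites_per_gene)]
        if n_intron and config.intron_edited_sites_per_gene:
            picks.append(
                pick_adenosines(base + n_exon, base + per_gene, config.intron_edited_sites_per_gene)
            )
        for block in picks:
            block = np.sort(block)
            edited[block] = True
            site_rate_idx[block] = np.arange(rate_cursor, rate_cursor + len(block))
            rate_cursor += len(block)

    return pd.DataFrame(
        {
            "gene_idx": gene_idx,
            "pos": pos,
            "region": region,
            "tref": tref,
            "edited": edited,
            "site_rate_idx": site_rate_idx,
        }
    )


def _sample_counts(
    config: SimConfig,
    positions: pd.DataFrame,
    theta: np.ndarray,
    depth_mean: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Base counts (N x 4, transcript orientation) for one library.

    ``theta`` is the per-position true editing rate (0 at non-edited
    positions); ``depth_mean`` the per-position expected coverage. An edited
    base that is miscalled still reads as non-reference, so the observed
    alternative rate is theta + eps * (1 - theta).
    """
    n = len(positions)
    eps = config.seq_error_rate
    disp = config.depth_dispersion
    p_nb = disp / (disp + np.maximum(depth_mean, 1e-12))
    depth = np.where(depth_mean > 0, rng.negative_binomial(disp, p_nb), 0).astype(np.int64)

    counts = np.zeros((n, 4), dtype=np.int64)
    tref = positions["tref"].to_numpy()
    edited = positions["edited"].to_numpy()

    # edited adenosines: each read carries G with probability theta, then the
    # base is miscalled uniformly with probability eps, so the observed G
    # rate is theta (1 - eps) + (1 - theta) eps / 3 (a miscalled edited base
    # still reads non-reference, just on C or T); at theta = 0 the site is
    # indistinguishable from background error
    p_g = theta * (1.0 - eps) + (1.0 - theta) * eps / 3.0
    p_other = eps / 3.0  # C and T each
    alt = rng.binomial(depth, np.where(edited, p_g, 0.0))
    rem = depth - alt
    e_c = rng.binomial(rem, np.divide(p_other, 1.0 - p_g, where=p_g < 1, out=np.zeros_like(p_g)))
    rem = rem - e_c
    e_t = rng.binomial(
        rem, np.divide(p_other, 1.0 - p_g - p_other, where=(p_g + p_other) < 1, out=np.zeros_like(p_g))
    )
    counts[edited, _BASE_TO_IDX["G"]] = alt[edited]
    counts[edited, _BASE_TO_IDX["C"]] = e_c[edited]
    counts[edited, _BASE_TO_IDX["T"]] = e_t[edited]
    counts[edited, _BASE_TO_IDX["A"]] = (depth - alt - e_c - e_t)[edited]

    # everything else: uniform miscalls over the three wrong bases
    bg = ~edited
    n_err = rng.binomial(depth, eps) * bg
    e1 = rng.binomial(n_err, 1.0 / 3.0)
    e2 = rng.binomial(n_err - e1, 0.5)
    e3 = n_err - e1 - e2
    errs = np.stack([e1, e2, e3], axis=1)
    for b in range(4):
        mask = bg & (tref == b)
        if not mask.any():
            continue
        wrong = [w for w in range(4) if w != b]
        counts[np.ix_(mask, wrong)] = errs[mask]
        counts[mask, b] = depth[mask] - n_err[mask]
    return counts, depth


def _to_genome_orientation(counts: np.ndarray, tref: np.ndarray, minus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Complement reference bases and swap count columns for minus-strand genes."""
    gref = np.where(minus, _COMP_IDX[tref], tref)
    out = counts.copy()
    out[minus] = counts[minus][:, _COMP_IDX]
    return out, gref


def simulate_bulk_counts(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Triplicate three-condition bulk experiment.

    Returns (base-count table, expression table, ground truth). Deterministic
    for a fixed ``config.rng_seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    genes = _gene_layout(config, rng)
    site_rates = _site_rates(config, genes, rng)
    positions = _positions_frame(config, genes, rng)

    gene_ids = genes["gene_id"].to_numpy()
    minus_gene = genes["strand"].to_numpy() == "-"
    gidx = positions["gene_idx"].to_numpy()
    minus = minus_gene[gidx]
    tref = positions["tref"].to_numpy()
    region = positions["region"].to_numpy()

    expr_factor = np.where(genes["low_expression"].to_numpy(), 1e-3, 1.0)[gidx]
    depth_mean = config.mean_depth * expr_factor
    depth_mean = depth_mean * np.where(region == "intron", config.intron_depth_factor, 1.0)

    srix = positions["site_rate_idx"].to_numpy()
    rate_cols = {c: site_rates[f"rate_{c}"].to_numpy() for c in CONDITIONS}

    frames = []
    expr_rows = []
    for condition in CONDITIONS:
        theta = np.zeros(len(positions))
        edited = srix >= 0
        theta[edited] = rate_cols[condition][srix[edited]]
        for rep in range(1, config.n_replicates + 1):
            counts, depth = _sample_counts(config, positions, theta, depth_mean, rng)
            gcounts, gref = _to_genome_orientation(counts, tref, minus)
            sample_id = f"{condition}_rep{rep}"
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": config.chrom,
                        "pos": positions["pos"].to_numpy(),
                        "gene_id": gene_ids[gidx],
                        "strand": np.where(minus, "-", "+"),
                        "ref_base": np.array(BASES)[gref],
                        "region": region,
                        "sample_id": sample_id,
                        "condition": condition,
                        "replicate": rep,
                        "count_A": gcounts[:, 0],
                        "count_C": gcounts[:, 1],
                        "count_G": gcounts[:, 2],
                        "count_T": gcounts[:, 3],
                        "depth": depth,
                    }
                )
            )
            per_gene_reads = np.bincount(gidx, weights=depth, minlength=config.n_genes)
            expr_rows.append(
                pd.DataFrame(
                    {"gene_id": gene_ids, "sample_id": sample_id, "read_count": per_gene_reads.astype(np.int64)}
                )
            )

    table = pd.concat(frames, ignore_index=True)[COUNT_TABLE_COLUMNS]

    gene_length = (config.positions_per_gene + config.intron_positions_per_gene) * config.position_spacing
    read_counts = pd.concat(expr_rows, ignore_index=True)
    from .pileup_io import compute_tpm

    expression = compute_tpm(read_counts, pd.Series(gene_length, index=gene_ids, dtype=float))

    sites = site_rates.copy()
    sites.insert(1, "chrom", config.chrom)
    pos_of_sites = positions.loc[positions["site_rate_idx"] >= 0].sort_values("site_rate_idx")
    sites.insert(2, "pos", pos_of_sites["pos"].to_numpy())
    truth = GroundTruth(genes=genes, sites=sites)
    return table, expression, truth


# ---------------------------------------------------------------------------
# single cells
# ---------------------------------------------------------------------------

def simulate_single_cell_counts(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Shallow single-cell experiment over the basal and arsenite conditions.

    Cells split evenly between Schneider's and arsenite. Each cell draws an
    ADAR fusion transcript count; its editing rates are the bulk site rates
    scaled by ``min(1, adar_effect * adar_count)``, so a cell without ADAR
    shows only sequencing-error background. Only rows with nonzero depth are
    emitted (single-cell tables are sparse).
    """
    config.validate()
    if config.n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(config.rng_seed)
    genes = _gene_layout(config, rng)
    site_rates = _site_rates(config, genes, rng)
    positions = _positions_frame(config, genes, rng)

    gene_ids = genes["gene_id"].to_numpy()
    minus = (genes["strand"].to_numpy() == "-")[positions["gene_idx"].to_numpy()]
    tref = positions["tref"].to_numpy()
    gidx = positions["gene_idx"].to_numpy()
    srix = positions["site_rate_idx"].to_numpy()
    edited = srix >= 0

    conditions = np.where(np.arange(config.n_cells) % 2 == 0, "schneiders", "arsenite")
    adar = rng.poisson(config.adar_mean, size=config.n_cells)
    width = max(4, len(str(config.n_cells)))
    cell_ids = np.array([f"cell{i + 1:0{width}d}" for i in range(config.n_cells)])

    expr_factor = np.where(genes["low_expression"].to_numpy(), 1e-3, 1.0)[gidx]
    depth_mean = config.cell_depth_mean * expr_factor

    rate_cols = {c: site_rates[f"rate_{c}"].to_numpy() for c in CONDITIONS}
    frames = []
    total_umis = np.zeros(config.n_cells, dtype=np.int64)
    for ci in range(config.n_cells):
        condition = conditions[ci]
        mult = min(1.0, config.adar_effect * float(adar[ci]))
        theta = np.zeros(len(positions))
        theta[edited] = rate_cols[condition][srix[edited]] * mult
        counts, depth = _sample_counts(config, positions, theta, depth_mean, rng)
        total_umis[ci] = int(depth.sum())
        keep = depth > 0
        if not keep.any():
            continue
        gcounts, gref = _to_genome_orientation(counts[keep], tref[keep], minus[keep])
        frames.append(
            pd.DataFrame(
                {
                    "chrom": config.chrom,
                    "pos": positions["pos"].to_numpy()[keep],
                    "gene_id": gene_ids[gidx[keep]],
                    "strand": np.where(minus[keep], "-", "+"),
                    "ref_base": np.array(BASES)[gref],
                    "region": positions["region"].to_numpy()[keep],
                    "sample_id": cell_ids[ci],
                    "condition": condition,
                    "replicate": 1,
                    "count_A": gcounts[:, 0],
                    "count_C": gcounts[:, 1],
                    "count_G": gcounts[:, 2],
                    "count_T": gcounts[:, 3],
                    "depth": depth[keep],
                }
            )
        )
    table = (
        pd.concat(frames, ignore_index=True)[COUNT_TABLE_COLUMNS]
        if frames
        else pd.DataFrame(columns=COUNT_TABLE_COLUMNS)
    )
    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "condition": conditions,
            "adar_count": adar,
            "total_umis": total_umis,
        }
    )
    sites = site_rates.copy()
    sites.insert(1, "chrom", config.chrom)
    pos_of_sites = positions.loc[positions["site_rate_idx"] >= 0].sort_values("site_rate_idx")
    sites.insert(2, "pos", pos_of_sites["pos"].to_numpy())
    truth = GroundTruth(genes=genes, sites=sites, cells=cells)
    return table, cells, truth


# ---------------------------------------------------------------------------
# SAM reads (end-to-end pileup check)
# ---------------------------------------------------------------------------

def simulate_sam(config: SimConfig, reads_per_gene: int = 10, read_gap: int = 30) -> tuple[str, pd.DataFrame, list[GeneModel]]:
    """Small-scale read-level simulation for exercising the pileup builder.

    Each gene has two exons separated by an intron; every read spans the
    whole gene with an N-gapped CIGAR, carrying genome-strand bases (an
    edited adenosine on a minus-strand gene reads as C at a genomic T). The
    returned truth table counts exactly the bases written into the reads, so
    a pileup of the SAM must reproduce it verbatim.
    """
    config.validate()
    if config.n_genes > 10:
        raise ValueError("simulate_sam is for small configurations (n_genes <= 10)")
    rng = np.random.default_rng(config.rng_seed)
    genes_df = _gene_layout(config, rng)
    site_rates = _site_rates(config, genes_df, rng)
    positions = _positions_frame(config, genes_df, rng)

    half = config.positions_per_gene // 2
    spacing = config.position_spacing
    models: list[GeneModel] = []
    sam_lines: list[str] = []
    truth_rows = []

    srix = positions["site_rate_idx"].to_numpy()
    rate_ars = site_rates["rate_arsenite"].to_numpy()

    chrom_len = int(positions["pos"].max()) + read_gap + 1000
    header = f"@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:{config.chrom}\tLN:{chrom_len}\n"

    for gi, g in enumerate(genes_df.itertuples()):
        mask = (positions["gene_idx"] == gi).to_numpy()
        # each gene grows by read_gap when its intron is opened; offset the
        # whole gene so neighbours never overlap
        gpos = positions.loc[mask, "pos"].to_numpy() + gi * (read_gap + 10)
        tref = positions.loc[mask, "tref"].to_numpy()
        gsr = srix[mask]
        minus = g.strand == "-"

        # dense exon blocks around the candidate positions, split by an intron
        exon1 = GenomicInterval(config.chrom, int(gpos[0]), int(gpos[half - 1]) + 1, g.strand)
        exon2_start = int(gpos[half]) + read_gap
        shift = exon2_start - int(gpos[half])
        gpos = gpos.copy()
        gpos[half:] += shift  # move second block rightward to create an intron
        exon2 = GenomicInterval(config.chrom, exon2_start, int(gpos[-1]) + 1, g.strand)
        models.append(
            GeneModel(
                gene_id=g.gene_id, gene_name=g.gene_id, biotype="protein_coding",
                chrom=config.chrom, strand=g.strand, exons=[exon1, exon2],
            )
        )

        # genome-orientation reference along both exons; candidate positions
        # carry the simulated base, filler positions are fixed 'A'
        ref_by_pos: dict[int, int] = {}
        theta_by_pos: dict[int, float] = {}
        for p, t, s in zip(gpos, tref, gsr):
            gref = _COMP_IDX[t] if minus else t
            ref_by_pos[int(p)] = int(gref)
            theta_by_pos[int(p)] = float(rate_ars[s]) if s >= 0 else 0.0

        span1 = list(range(exon1.start, exon1.end))
        span2 = list(range(exon2.start, exon2.end))
        cigar = f"{len(span1)}M{exon2.start - exon1.end}N{len(span2)}M"
        counts: dict[int, np.ndarray] = {p: np.zeros(4, dtype=np.int64) for p in span1 + span2}
        for ri in range(reads_per_gene):
            bases = []
            for p in span1 + span2:
                refb = ref_by_pos.get(p, _BASE_TO_IDX["A"])
                theta = theta_by_pos.get(p, 0.0)
                if theta > 0 and rng.random() < theta:
                    # transcript A>G reads as genomic G (+) or C (-)
                    b = _BASE_TO_IDX["C"] if minus else _BASE_TO_IDX["G"]
                else:
                    b = refb
                if rng.random() < config.seq_error_rate:
                    b = int(rng.choice([w for w in range(4) if w != b]))
                bases.append(b)
                counts[p][b] += 1
            seq = "".join(BASES[b] for b in bases)
            sam_lines.append(
                f"{g.gene_id}_read{ri + 1}\t0\t{config.chrom}\t{exon1.start + 1}\t60\t{cigar}\t*\t0\t0\t{seq}\t*"
            )
        for p in sorted(counts):
            c = counts[p]
            region = "exon"
            truth_rows.append(
                (
                    config.chrom, p, g.gene_id, g.strand, "N", region,
                    "sample1", "schneiders", 1,
                    int(c[0]), int(c[1]), int(c[2]), int(c[3]), int(c.sum()),
                )
            )

    truth = pd.DataFrame(truth_rows, columns=COUNT_TABLE_COLUMNS)
    return header + "\n".join(sam_lines) + "\n", truth, models


# ---------------------------------------------------------------------------
# smFISH spots
# ---------------------------------------------------------------------------

def _logistic_recruitment(log2_fc: np.ndarray, slope: float, midpoint: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-slope * (log2_fc - midpoint)))


def simulate_smfish(
    truth: GroundTruth,
    n_cells_imaged: int = 10,
    granule_area_fraction: float = 0.1,
    spots_per_cell_mean: float = 10.0,
    recruitment_slope: float = 1.5,
    recruitment_midpoint: float = 1.0,
    spot_prob_override: float | None = None,
    uniform_placement: bool = False,
    max_log2_fc: float = 6.0,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place RNA spots in unit-square cells with one rectangular granule each.

    The probability that a spot of a gene falls inside the granule is a
    logistic function of the gene's true arsenite/basal log2 editing fold
    change (genes with zero basal editing are capped at ``max_log2_fc``).
    With ``uniform_placement`` spots ignore granules entirely, so the
    colocalization fraction converges to the granule area fraction.
    """
    if not 0.0 < granule_area_fraction < 1.0:
        raise ValueError("granule_area_fraction must be in (0, 1)")
    rng = np.random.default_rng(rng_seed)

    per_gene = truth.sites.groupby("gene_id")[["rate_schneiders", "rate_arsenite"]].mean()
    basal = per_gene["rate_schneiders"].to_numpy()
    ars = per_gene["rate_arsenite"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_fc = np.where(
            basal > 0, np.log2(np.maximum(ars, 1e-12) / basal), np.where(ars > 0, max_log2_fc, 0.0)
        )
    log2_fc = np.clip(log2_fc, -max_log2_fc, max_log2_fc)
    if spot_prob_override is not None:
        p_in = np.full(len(per_gene), float(spot_prob_override))
    else:
        p_in = _logistic_recruitment(log2_fc, recruitment_slope, recruitment_midpoint)

    side = float(np.sqrt(granule_area_fraction))
    granule_rows = []
    spot_rows = []
    width = max(3, len(str(n_cells_imaged)))
    for ci in range(n_cells_imaged):
        cell_id = f"img{ci + 1:0{width}d}"
        gx, gy = rng.uniform(0, 1 - side, size=2)
        wkt = (
            f"POLYGON (({gx:.6f} {gy:.6f}, {gx + side:.6f} {gy:.6f}, "
            f"{gx + side:.6f} {gy + side:.6f}, {gx:.6f} {gy + side:.6f}, {gx:.6f} {gy:.6f}))"
        )
        granule_rows.append((cell_id, wkt))
        n_spots = rng.poisson(spots_per_cell_mean, size=len(per_gene))
        for gidx, (gene_id, n_sp) in enumerate(zip(per_gene.index, n_spots)):
            for _ in range(int(n_sp)):
                if uniform_placement:
                    x, y = rng.uniform(0, 1, size=2)
                elif rng.random() < p_in[gidx]:
                    x = rng.uniform(gx, gx + side)
                    y = rng.uniform(gy, gy + side)
                else:
                    while True:  # rejection-sample the cytoplasm
                        x, y = rng.uniform(0, 1, size=2)
                        if not (gx <= x <= gx + side and gy <= y <= gy + side):
                            break
                spot_rows.append((gene_id, cell_id, x, y))
    spots = pd.DataFrame(spot_rows, columns=["gene_id", "cell_id", "x", "y"])
    granules = pd.DataFrame(granule_rows, columns=["cell_id", "granule_wkt"])
    return spots, granules
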
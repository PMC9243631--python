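"""Annotation, alignment and count-table I/O.

All internal coordinates are 0-based half-open; GTF/VCF/SAM use 1-based
conventions and are converted at the file boundary. The central substrate of
the pipeline is the *base-count table*: one row per (gene, genomic position,
sample) with counts of A/C/G/T observed in reads at that position.
"""

from __future__ import annotations

import os
import tempfile
import warnings
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
BASES = ("A", "C", "G", "T")

#: Fixed column order of a base-count table on disk and in memory.
COUNT_TABLE_COLUMNS = [
    "chrom",
    "pos",
    "gene_id",
    "strand",
    "ref_base",
    "region",
    "sample_id",
    "condition",
    "replicate",
    "count_A",
    "count_C",
    "count_G",
    "count_T",
    "depth",
]

CONDITIONS = ("uninduced", "schneiders", "arsenite")


class GTFParseError(ValueError):
    """Raised for a malformed GTF line; carries the 1-based line number."""


class CountTableSchemaError(ValueError):
    """Raised when a count table is missing columns or violates invariants."""


class SAMRecordError(ValueError):
    """Raised when an alignment record is internally inconsistent."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval, 0-based start, exclusive end."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals into a sorted disjoint list."""
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged


@dataclass
class GeneModel:
    """A gene with merged exon structure and derived feature lengths.

    UTR lengths are strand-aware: on the minus strand the 5' UTR lies on the
    high-coordinate side of the CDS.
    """

    gene_id: str
    gene_name: str
    biotype: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    @property
    def transcript_length(self) -> int:
        return sum(len(iv) for iv in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(len(iv) for iv in self.cds)

    def _exonic_length_left_of_cds(self) -> int:
        """Exonic nucleotides with coordinates below the CDS start."""
        cds_start = min(iv.start for iv in self.cds)
        return sum(min(iv.end, cds_start) - iv.start for iv in self.exons if iv.start < cds_start)

    def _exonic_length_right_of_cds(self) -> int:
        cds_end = max(iv.end for iv in self.cds)
        return sum(iv.end - max(iv.start, cds_end) for iv in self.exons if iv.end > cds_end)

    @property
    def utr5_length(self) -> int:
        if not self.cds:
            return 0
        if self.strand == "+":
            return self._exonic_length_left_of_cds()
        return self._exonic_length_right_of_cds()

    @property
    def utr3_length(self) -> int:
        if not self.cds:
            return 0
        if self.strand == "+":
            return self._exonic_length_right_of_cds()
        return self._exonic_length_left_of_cds()

    def feature_length(self, feature: str) -> int:
        return {
            "transcript": self.transcript_length,
            "cds": self.cds_length,
            "utr5": self.utr5_length,
            "utr3": self.utr3_length,
        }[feature]


def _validate_gtf_lines(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GTFParseError(f"malformed GTF line {lineno}: expected 9 tab-separated fields")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GTFParseError(f"malformed GTF line {lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise GTFParseError(f"malformed GTF line {lineno}: bad coordinate range {start}-{end}")


def read_gtf(path: str) -> list[GeneModel]:
    """Parse an Ensembl-dialect GTF into gene models.

    GTF 1-based inclusive coordinates become internal 0-based half-open.
    Exons of all transcripts of a gene are merged; genes without exon lines
    are skipped with a warning.
    """
    _validate_gtf_lines(path)
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons_by_gene: dict[str, list[GenomicInterval]] = {}
    cds_by_gene: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, dict] = {}

    def gene_key(feat) -> str:
        return feat.attributes["gene_id"][0]

    for feat in db.all_features():
        gid = gene_key(feat)
        if gid not in meta:
            meta[gid] = {
                "gene_name": gid,
                "biotype": "protein_coding",
                "chrom": feat.seqid,
                "strand": feat.strand if feat.strand in "+-" else "+",
            }
        if "gene_name" in feat.attributes:
            meta[gid]["gene_name"] = feat.attributes["gene_name"][0]
        if "gene_biotype" in feat.attributes:
            meta[gid]["biotype"] = feat.attributes["gene_biotype"][0]
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, meta[gid]["strand"])
        if feat.featuretype == "exon":
            exons_by_gene.setdefault(gid, []).append(iv)
        elif feat.featuretype == "CDS":
            cds_by_gene.setdefault(gid, []).append(iv)

    genes: list[GeneModel] = []
    for gid, m in meta.items():
        exons = merge_intervals(exons_by_gene.get(gid, []))
        if not exons:
            warnings.warn(f"gene {gid} has no exons; skipped", stacklevel=2)
            continue
        genes.append(
            GeneModel(
                gene_id=gid,
                gene_name=m["gene_name"],
                biotype=m["biotype"],
                chrom=m["chrom"],
                strand=m["strand"],
                exons=exons,
                cds=merge_intervals(cds_by_gene.get(gid, [])),
            )
        )
    return genes


def write_gtf(genes: list[GeneModel], path: str) -> None:
    """Emit gene/exon/CDS lines (1-based inclusive) for a list of gene models."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; '
                f'gene_biotype "{g.biotype}";'
            )
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for iv in g.exons:
                fh.write(
                    f"{g.chrom}\tsim\texon\t{iv.start + 1}\t{iv.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
            for iv in g.cds:
                fh.write(
                    f"{g.chrom}\tsim\tCDS\t{iv.start + 1}\t{iv.end}\t.\t{g.strand}\t0\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# SAM pileup
# ---------------------------------------------------------------------------

def _gene_trees(genes: list[GeneModel]) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees mapping positions to (gene, region)."""
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        for iv in g.exons:
            tree[iv.start: iv.end] = (g, "exon")
        for iv in g.introns:
            tree[iv.start: iv.end] = (g, "intron")
    return trees


def build_pileup_from_sam(
    sam: str,
    genes: list[GeneModel],
    sample_id: str = "sample1",
    condition: str = "schneiders",
    replicate: int = 1,
    include_introns: bool = True,
) -> pd.DataFrame:
    """Pile up primary alignments of a SAM file (path or text) into base counts.

    CIGAR semantics follow the SAM specification: M/=/X positions contribute a
    base count; N/D reference positions receive no counts; insertions and
    soft clips consume query only. A position overlapping several genes gets
    one row per gene.
    """
    if "\n" in sam or sam.lstrip().startswith("@"):
        tmp = tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False)
        tmp.write(sam)
        tmp.close()
        path, cleanup = tmp.name, True
    else:
        path, cleanup = sam, False

    counts: dict[str, dict[int, np.ndarray]] = {}
    base_index = {b: i for i, b in enumerate(BASES)}
    try:
        with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
            for read in fh:
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                seq = read.query_sequence
                if seq is None:
                    continue
                if read.infer_query_length() not in (None, len(seq)):
                    raise SAMRecordError(
                        f"read {read.query_name}: CIGAR consumes "
                        f"{read.infer_query_length()} query bases but SEQ has {len(seq)}"
                    )
                chrom = read.reference_name
                per_chrom = counts.setdefault(chrom, {})
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    base = seq[qpos].upper()
                    if base not in base_index:
                        continue
                    arr = per_chrom.get(rpos)
                    if arr is None:
                        arr = per_chrom[rpos] = np.zeros(4, dtype=np.int64)
                    arr[base_index[base]] += 1
    finally:
        if cleanup:
            os.unlink(path)

    trees = _gene_trees(genes)
    rows = []
    for chrom, per_chrom in counts.items():
        tree = trees.get(chrom)
        if tree is None:
            continue
        for pos in sorted(per_chrom):
            for hit in sorted(tree[pos], key=lambda h: h.data[0].gene_id):
                gene, region = hit.data
                if region == "intron" and not include_introns:
                    continue
                c = per_chrom[pos]
                rows.append(
                    (
                        chrom, pos, gene.gene_id, gene.strand, "N", region,
                        sample_id, condition, replicate,
                        int(c[0]), int(c[1]), int(c[2]), int(c[3]), int(c.sum()),
                    )
                )
    return pd.DataFrame(rows, columns=COUNT_TABLE_COLUMNS)


# ---------------------------------------------------------------------------
# Expression / TPM
# ---------------------------------------------------------------------------

def compute_tpm(read_counts: pd.DataFrame, gene_lengths: dict[str, int] | pd.Series) -> pd.DataFrame:
    """Length-normalize read counts to transcripts per million.

    ``read_counts`` has columns gene_id, sample_id, read_count. Returns an
    expression table with a ``tpm`` column; TPM sums to 1e6 per sample
    whenever any count is nonzero.
    """
    lengths = pd.Series(gene_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    df = read_counts.copy()
    df["rate"] = df["read_count"].astype(float) / df["gene_id"].map(lengths)
    totals = df.groupby("sample_id")["rate"].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        df["tpm"] = np.where(totals > 0, 1e6 * df["rate"] / totals, 0.0)
    return df[["gene_id", "sample_id", "read_count", "tpm"]]


def tpm_filter(expression: pd.DataFrame, sample_conditions: dict[str, str], min_tpm: float = 1.0) -> set[str]:
    """Genes retained by the expression filter.

    A gene is kept if its replicate-mean TPM exceeds ``min_tpm`` in at least
    one condition (the most permissive reading of a per-million floor of 1).
    """
    df = expression.copy()
    df["condition"] = df["sample_id"].map(sample_conditions)
    means = df.groupby(["gene_id", "condition"])["tpm"].mean()
    keep = means[means > min_tpm].reset_index()["gene_id"].unique()
    return set(keep)


# ---------------------------------------------------------------------------
# Count-table round trip
# ---------------------------------------------------------------------------

def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COUNT_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise CountTableSchemaError(f"count table missing column(s): {', '.join(missing)}")
    counts = table[["count_A", "count_C", "count_G", "count_T"]].to_numpy()
    if len(table) and not (counts.sum(axis=1) == table["depth"].to_numpy()).all():
        raise CountTableSchemaError("depth does not equal the sum of base counts")
    if len(table) and (table["depth"] < 0).any():
        raise CountTableSchemaError("negative depth")
    return table[COUNT_TABLE_COLUMNS]


def write_count_table(table: pd.DataFrame, path: str) -> None:
    validate_count_table(table).to_csv(path, sep="\t", index=False)


def read_count_table(path: str) -> pd.DataFrame:
    table = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "sample_id": str, "gene_id": str, "strand": str,
               "ref_base": str, "region": str, "condition": str},
    )
    return validate_count_table(table)


# ---------------------------------------------------------------------------
# Known variants
# ---------------------------------------------------------------------------

def read_known_variants(path: str) -> set[tuple[str, int, str]]:
    """Read a known-variant exclusion list as (chrom, 0-based pos, alt) triples.

    Accepts a VCF (positions are 1-based; every ALT allele of a record is
    included) or a 3-column TSV of chrom, 1-based position, alt base.
    """
    with open(path) as fh:
        head = fh.read(64)
    out: set[tuple[str, int, str]] = set()
    if head.startswith("##fileformat=VCF"):
        with pysam.VariantFile(path) as vf:
            for rec in vf:
                for alt in rec.alts or ():
                    out.add((rec.chrom, rec.pos - 1, alt))
        return out
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"known-variants line {lineno}: expected chrom, pos, alt")
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"known-variants line {lineno}: unparseable position {fields[1]!r}") from exc
            out.add((fields[0], pos - 1, fields[2]))
    return out
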
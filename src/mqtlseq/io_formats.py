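"""Readers and writers for the tabular and annotation formats the pipeline touches.

Internal coordinates are 1-based inclusive throughout the package, matching the
convention of GFF3 and of published SNP physical positions.  BED export is the
single 0-based, half-open surface; the conversion is ``start - 1, end``.

Allele-depth tables can come from a VCF with per-sample AD fields (read through
cyvcf2) or from a plain TSV with ``chrom, pos, ref, alt, <sample>_ref,
<sample>_alt, ...`` columns.  Only biallelic SNP records are kept from VCF
input; multiallelic and indel records are skipped with a counted warning.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("mqtlseq")

VALID_BASES = frozenset("ACGT")

#: Sample roles the QTL-seq statistics expect.  Roles are assigned explicitly
#: (config/argument), never inferred from sample names.
ROLE_NAMES = ("parent_early", "parent_late", "bulk_early", "bulk_late")


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass
class AlleleCountTable:
    """Per-SNP, per-sample ref/alt read counts.

    ``df`` columns: chrom, pos, ref, alt, mean_bq, then ``<sample>_ref`` and
    ``<sample>_alt`` for every sample in ``samples``.  Rows are sorted by
    (chrom, pos) and positions are unique within a chromosome.
    """

    df: pd.DataFrame
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.df
        required = ["chrom", "pos", "ref", "alt", "mean_bq"]
        for col in required:
            if col not in df.columns:
                raise FormatError(f"allele-count table missing column {col!r}")
        for s in self.samples:
            for suffix in ("_ref", "_alt"):
                col = s + suffix
                if col not in df.columns:
                    raise FormatError(f"missing depth column {col!r}")
                if (df[col] < 0).any():
                    raise FormatError(f"negative depth in column {col!r}")
        bad = ~(df["ref"].isin(VALID_BASES) & df["alt"].isin(VALID_BASES))
        if bad.any():
            pos = df.loc[bad, "pos"].iloc[0]
            raise FormatError(f"non-ACGT allele at position {pos}")
        if not df.sort_values(["chrom", "pos"], kind="mergesort").index.equals(df.index):
            logger.warning("allele-count table was unsorted; sorting by (chrom, pos)")
            self.df = df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        dup = df.duplicated(subset=["chrom", "pos"])
        if dup.any():
            row = df.loc[dup].iloc[0]
            raise FormatError(f"duplicate position {row['chrom']}:{row['pos']}")

    def depth(self, sample: str) -> np.ndarray:
        return (self.df[sample + "_ref"] + self.df[sample + "_alt"]).to_numpy()

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class QtlInterval:
    """A called QTL region with 1-based inclusive flanking SNP positions."""

    chrom: str
    start_snp_pos: int
    end_snp_pos: int
    peak_delta: float
    mean_index_early: float = float("nan")
    mean_index_late: float = float("nan")
    population: str = "NA"
    level: float = 99.0

    def __post_init__(self) -> None:
        if self.start_snp_pos >= self.end_snp_pos:
            raise ValueError("interval start must be < end")

    @property
    def length_bp(self) -> int:
        return self.end_snp_pos - self.start_snp_pos


# ---------------------------------------------------------------------------
# Allele-count tables


def read_allele_counts(path: str, format: str | None = None) -> AlleleCountTable:
    """Load an allele-depth table from VCF (with AD) or TSV.

    ``format`` is ``"vcf"`` or ``"tsv"``; if None it is guessed from the file
    extension.  The result is validated and sorted by (chrom, pos); duplicate
    positions raise :class:`FormatError`.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "tsv"
    if format == "vcf":
        return _read_allele_counts_vcf(path)
    if format == "tsv":
        return _read_allele_counts_tsv(path)
    raise ValueError(f"unknown format {format!r}")


def _read_allele_counts_tsv(path: str) -> AlleleCountTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    samples = [c[:-4] for c in df.columns if c.endswith("_ref")]
    if not samples:
        raise FormatError(f"{path}: no <sample>_ref columns found")
    if "mean_bq" not in df.columns:
        df["mean_bq"] = 40.0
    df["pos"] = df["pos"].astype(np.int64)
    return AlleleCountTable(df.reset_index(drop=True), samples)


def _read_allele_counts_vcf(path: str) -> AlleleCountTable:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows = []
    n_skipped = 0
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            n_skipped += 1
            continue
        ad = var.format("AD")
        if ad is None:
            raise FormatError(
                f"{path}: record {var.CHROM}:{var.POS} has no AD (allele depth) field"
            )
        bq = var.QUAL if var.QUAL is not None else 40.0
        row = {
            "chrom": var.CHROM,
            "pos": var.POS,
            "ref": var.REF,
            "alt": var.ALT[0],
            "mean_bq": float(bq),
        }
        for i, s in enumerate(samples):
            ref_d, alt_d = int(ad[i][0]), int(ad[i][1])
            row[s + "_ref"] = max(ref_d, 0)
            row[s + "_alt"] = max(alt_d, 0)
        rows.append(row)
    if n_skipped:
        logger.warning("%s: skipped %d non-biallelic-SNP records", path, n_skipped)
    df = pd.DataFrame(rows)
    return AlleleCountTable(df, samples)


def write_allele_counts(table: AlleleCountTable, path: str) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phenotype tables


def read_phenotypes(path: str) -> pd.DataFrame:
    """Read a phenotype TSV with columns individual, population, environment,
    replicate, dtf and validate its key uniqueness and positivity."""
    df = pd.read_csv(path, sep="\t")
    return validate_phenotypes(df)


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("individual", "environment", "replicate", "dtf"):
        if col not in df.columns:
            raise FormatError(f"phenotype table missing column {col!r}")
    if (df["dtf"] <= 0).any():
        raise FormatError("non-positive days-to-flowering value")
    if df.duplicated(subset=["individual", "environment", "replicate"]).any():
        raise FormatError("duplicate (individual, environment, replicate) key")
    return df


def write_phenotypes(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene models (GFF3 + FASTA)


@dataclass
class GeneModel:
    """A protein-coding gene with strand-ordered CDS segments.

    ``cds`` holds 1-based inclusive (start, end) pairs in transcription order:
    ascending genomic order on '+' genes, descending on '-' genes.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        segs = sorted(self.cds)
        for (a1, b1), (a2, b2) in zip(segs, segs[1:]):
            if a2 <= b1:
                raise FormatError(f"overlapping CDS segments in gene {self.gene_id}")
        for a, b in segs:
            if a < self.start or b > self.end:
                raise FormatError(f"CDS outside gene span in {self.gene_id}")

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds)


def read_gene_models(path: str) -> list[GeneModel]:
    """Parse gene and CDS features from a GFF3 file into GeneModel objects."""
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: dict[str, GeneModel] = {}
    gene_meta: dict[str, tuple[str, str, int, int]] = {}
    for g in db.features_of_type("gene"):
        gene_meta[g.id] = (g.seqid, g.strand, g.start, g.end)
    cds_by_gene: dict[str, list[tuple[int, int]]] = {gid: [] for gid in gene_meta}
    for c in db.features_of_type("CDS"):
        parents = c.attributes.get("Parent", [])
        if not parents or parents[0] not in gene_meta:
            raise FormatError(f"{path}: CDS at {c.seqid}:{c.start} without parent gene")
        cds_by_gene[parents[0]].append((c.start, c.end))
    for gid, (chrom, strand, start, end) in gene_meta.items():
        segs = sorted(cds_by_gene[gid])
        if strand == "-":
            segs = segs[::-1]
        genes[gid] = GeneModel(gid, chrom, strand, start, end, segs)
    return sorted(genes.values(), key=lambda g: (g.chrom, g.start))


def write_gene_models(genes: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tmqtlseq\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (a, b) in enumerate(sorted(g.cds)):
                fh.write(
                    f"{g.chrom}\tmqtlseq\tCDS\t{a}\t{b}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                )


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# QTL intervals (BED)

_BED_COLUMNS = [
    "chrom",
    "start",
    "end",
    "population",
    "peak_delta",
    "strand",
    "mean_index_early",
    "mean_index_late",
    "level",
]


def write_intervals(intervals: list[QtlInterval], path: str) -> None:
    """Write QTL intervals as BED (0-based half-open) with extra columns."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_BED_COLUMNS) + "\n")
        for iv in intervals:
            strand = "+" if iv.peak_delta >= 0 else "-"
            fh.write(
                f"{iv.chrom}\t{iv.start_snp_pos - 1}\t{iv.end_snp_pos}\t"
                f"{iv.population}\t{iv.peak_delta:.6g}\t{strand}\t"
                f"{iv.mean_index_early:.6g}\t{iv.mean_index_late:.6g}\t{iv.level:g}\n"
            )


def read_intervals(path: str) -> list[QtlInterval]:
    intervals = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            intervals.append(
                QtlInterval(
                    chrom=f[0],
                    start_snp_pos=int(f[1]) + 1,
                    end_snp_pos=int(f[2]),
                    population=f[3],
                    peak_delta=float(f[4]),
                    mean_index_early=float(f[6]),
                    mean_index_late=float(f[7]),
                    level=float(f[8]),
                )
            )
    return intervals


# ---------------------------------------------------------------------------
# Config plumbing


def load_config(path: str) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def check_roles(roles: dict) -> dict:
    missing = [r for r in ROLE_NAMES if r not in roles]
    if missing:
        raise FormatError(f"sample-role map missing roles: {missing}")
    return {r: roles[r] for r in ROLE_NAMES}


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        stream=__import__("sys").stderr,
    )
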
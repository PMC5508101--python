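"""SNP structural annotation: genomic context and coding effect.

Positions are classified as CDS, intron (gene span minus CDS), URR (upstream
regulatory region, a fixed window 5' of the gene, strand-aware), DRR
(downstream regulatory region, 3' of the gene) or intergenic, with precedence
CDS > intron > URR > DRR > intergenic on ambiguity.  Coding substitutions are
translated with the standard genetic code and labelled synonymous, missense
or nonsense.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io_formats import GeneModel

CATEGORIES = ("CDS", "intron", "URR", "DRR", "intergenic")

_COMP = str.maketrans("ACGT", "TGCA")

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class CodingEffect:
    effect: str  # synonymous | missense | nonsense
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    codon_number: int  # 1-based codon index in the CDS
    codon_position: int  # 1-based position within the codon


@dataclass
class AnnotatedSnp:
    chrom: str
    pos: int
    category: str
    gene_id: str | None = None
    coding: CodingEffect | None = None

    def __post_init__(self) -> None:
        if (self.category == "CDS") != (self.coding is not None):
            raise ValueError("coding effect must be present iff category is CDS")


def _regulatory_windows(gene: GeneModel, urr_len: int, drr_len: int):
    """1-based inclusive (start, end) of the URR and DRR windows."""
    if gene.strand == "+":
        urr = (gene.start - urr_len, gene.start - 1)
        drr = (gene.end + 1, gene.end + drr_len)
    else:
        urr = (gene.end + 1, gene.end + urr_len)
        drr = (gene.start - drr_len, gene.start - 1)
    return urr, drr


def classify_location(
    pos: int,
    gene_models: list[GeneModel],
    urr_len: int = 2000,
    drr_len: int = 2000,
    chrom_length: int | None = None,
) -> tuple[str, str | None]:
    """Classify one position against a list of gene models on its chromosome.

    Returns (category, gene_id or None).  When the URR/DRR windows of several
    genes overlap the position, the nearest gene wins; remaining ties go to
    the lexicographically lower gene ID.
    """
    if pos < 1 or (chrom_length is not None and pos > chrom_length):
        raise ValueError(f"position {pos} outside chromosome bounds")
    genic_hits: list[tuple[int, str, str]] = []  # (precedence, gene_id, cat)
    reg_hits: list[tuple[int, str, str]] = []  # (distance, gene_id, cat)
    for g in gene_models:
        if g.start <= pos <= g.end:
            in_cds = any(a <= pos <= b for a, b in g.cds)
            genic_hits.append((0 if in_cds else 1, g.gene_id, "CDS" if in_cds else "intron"))
            continue
        urr, drr = _regulatory_windows(g, urr_len, drr_len)
        if urr[0] <= pos <= urr[1]:
            dist = min(abs(pos - g.start), abs(pos - g.end))
            reg_hits.append((dist, g.gene_id, "URR"))
        elif drr[0] <= pos <= drr[1]:
            dist = min(abs(pos - g.start), abs(pos - g.end))
            reg_hits.append((dist, g.gene_id, "DRR"))
    if genic_hits:
        genic_hits.sort()
        prec, gid, cat = genic_hits[0]
        return cat, gid
    if reg_hits:
        # URR beats DRR at equal distance; then nearest gene; then lower ID
        reg_hits.sort(key=lambda h: (h[0], 0 if h[2] == "URR" else 1, h[1]))
        dist, gid, cat = reg_hits[0]
        return cat, gid
    return "intergenic", None


def _spliced_cds(gene: GeneModel, chrom_seq: str) -> str:
    parts = []
    for a, b in gene.cds:
        seg = chrom_seq[a - 1 : b]
        parts.append(seg if gene.strand == "+" else seg.translate(_COMP)[::-1])
    return "".join(parts)


def _genomic_to_cds_offset(gene: GeneModel, pos: int) -> int:
    offset = 0
    for a, b in gene.cds:
        if a <= pos <= b:
            return offset + (pos - a if gene.strand == "+" else b - pos)
        offset += b - a + 1
    raise ValueError(f"position {pos} not in CDS of {gene.gene_id}")


def coding_effect(
    pos: int,
    ref_base: str,
    alt_base: str,
    gene: GeneModel,
    chrom_seq: str,
) -> CodingEffect:
    """Effect of a single-base substitution inside a CDS.

    ``ref_base``/``alt_base`` are on the + strand of the assembly; for genes
    on the - strand they are complemented before being placed in the codon.
    The reference base must match the assembly at ``pos``.
    """
    if chrom_seq[pos - 1] != ref_base:
        raise ValueError(
            f"reference mismatch at {pos}: assembly has {chrom_seq[pos - 1]}, "
            f"record says {ref_base}"
        )
    offset = _genomic_to_cds_offset(gene, pos)
    cds = _spliced_cds(gene, chrom_seq)
    codon_number = offset // 3
    codon_pos = offset % 3
    ref_codon = cds[codon_number * 3 : codon_number * 3 + 3]
    sub = alt_base if gene.strand == "+" else alt_base.translate(_COMP)
    alt_codon = ref_codon[:codon_pos] + sub + ref_codon[codon_pos + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == ref_aa:
        effect = "synonymous"
    elif alt_codon in STOP_CODONS:
        effect = "nonsense"
    else:
        effect = "missense"
    return CodingEffect(
        effect, ref_codon, alt_codon, ref_aa, alt_aa, codon_number + 1, codon_pos + 1
    )


def annotate_snps(
    records: pd.DataFrame,
    gene_models: list[GeneModel],
    sequences: dict[str, str] | None = None,
    urr_len: int = 2000,
    drr_len: int = 2000,
) -> list[AnnotatedSnp]:
    """Classify every SNP record; add coding effects where sequence is given.

    ``records`` needs chrom/pos and, for coding effects, ref/alt columns.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)
    gene_lookup = {g.gene_id: g for g in gene_models}
    out = []
    has_alleles = "ref" in records.columns and "alt" in records.columns
    for row in records.itertuples(index=False):
        cat, gid = classify_location(
            int(row.pos), by_chrom.get(row.chrom, []), urr_len, drr_len
        )
        coding = None
        if cat == "CDS":
            if sequences is None or not has_alleles:
                raise ValueError(
                    "coding SNPs present but no reference sequence / alleles given"
                )
            coding = coding_effect(
                int(row.pos), row.ref, row.alt, gene_lookup[gid], sequences[row.chrom]
            )
        out.append(AnnotatedSnp(row.chrom, int(row.pos), cat, gid, coding))
    return out


def summarize_annotation(annotated: list[AnnotatedSnp]) -> pd.DataFrame:
    """Counts and one-decimal percentages per category and coding effect."""
    rows = []
    n = len(annotated)
    if n == 0:
        return pd.DataFrame(columns=["level", "group", "count", "percent"])
    cats = pd.Series([a.category for a in annotated])
    for cat in CATEGORIES:
        k = int((cats == cat).sum())
        rows.append(("category", cat, k, round(100.0 * k / n, 1)))
    genic = int((cats != "intergenic").sum())
    rows.append(("genic_split", "genic", genic, round(100.0 * genic / n, 1)))
    rows.append(("genic_split", "intergenic", n - genic, round(100.0 * (n - genic) / n, 1)))
    coding = [a.coding.effect for a in annotated if a.coding is not None]
    nc = len(coding)
    if nc:
        s = pd.Series(coding)
        for eff in ("synonymous", "missense", "nonsense"):
            k = int((s == eff).sum())
            rows.append(("coding_split", eff, k, round(100.0 * k / nc, 1)))
    return pd.DataFrame(rows, columns=["level", "group", "count", "percent"])
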
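"""Synthetic RIL-cross, bulk-sequencing and diversity-panel generators.

The generators emulate the data-generating process the analysis assumes:

* an F9 recombinant inbred line (RIL) population from a biparental cross,
  produced by single-seed descent with Haldane (no-interference) crossovers;
* days-to-flowering phenotypes with additive QTL effects, environment and
  genotype-by-environment terms scaled to a target entry-mean heritability;
* extreme-tail bulks of homozygous individuals (10 per bulk by default);
* short-read allele counts per bulk/parent with Poisson total depth (~30x)
  and binomial allele sampling;
* a random annotated gene space (FASTA + GFF3) for variant classification;
* cultivated/wild haplotype panels with a locus-specific diversity reduction
  mimicking a domestication sweep.

All generators are pure functions of (config, seed): identical inputs give
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AlleleCountTable, GeneModel

# Allele coding: 0 = early-flowering parent allele (the reference genome),
# 2 = late-flowering parent allele, 1 = residual heterozygote.

BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SimConfig:
    """Parameters of the synthetic RIL-bulk experiment.

    Defaults mirror the desk-scale fixture: one 55-Mb chromosome-4-like
    pseudomolecule, 260 F9 RILs, two planted additive QTLs, ~30x depth and
    bulks of 10 homozygous extreme individuals.
    """

    n_ril: int = 260
    generation: int = 9
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"Ca4": 55_000_000}
    )
    marker_spacing: int = 5_000
    qtls: list[tuple[str, int, float]] = field(
        default_factory=lambda: [("Ca4", 26_800_000, 12.0), ("Ca4", 46_400_000, 9.0)]
    )
    baseline: float = 64.0  # mid-parent days to flowering
    h2: float = 0.8
    depth_mean: float = 30.0
    bulk_size: int = 10
    recomb_rate: float = 2.5  # cM per Mb
    seed: int = 1

    def validate(self) -> None:
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must be in (0, 1)")
        if self.bulk_size > self.n_ril // 2:
            raise ValueError("bulk_size must be <= n_ril / 2")
        if self.generation < 2:
            raise ValueError("generation must be >= 2 (F2 or later)")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"zero-length chromosome {chrom!r}")
        for chrom, pos, _ in self.qtls:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"QTL on unknown chromosome {chrom!r}")
            if not 1 <= pos <= self.chrom_lengths[chrom]:
                raise ValueError(f"QTL position {pos} outside {chrom!r}")


@dataclass
class TruthSet:
    """Ground truth of a simulated RIL population.

    ``genotypes`` is (n_ril, n_markers) with dosage of the late-parent allele
    in {0, 1, 2}.  ``chroms``/``positions`` give marker coordinates; ``qtls``
    the planted (chrom, pos, effect) triples with ``qtl_marker_idx`` the index
    of the marker nearest each QTL.
    """

    genotypes: np.ndarray
    chroms: np.ndarray
    positions: np.ndarray
    individuals: list[str]
    qtls: list[tuple[str, int, float]]
    qtl_marker_idx: np.ndarray
    config: SimConfig

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def het_fraction(self) -> float:
        return float(np.mean(self.genotypes == 1))


@dataclass
class Bulks:
    early: list[str]
    late: list[str]

    def indices(self, individuals: list[str]) -> tuple[np.ndarray, np.ndarray]:
        lookup = {ind: i for i, ind in enumerate(individuals)}
        return (
            np.array([lookup[i] for i in self.early]),
            np.array([lookup[i] for i in self.late]),
        )


def _marker_grid(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    chroms, positions = [], []
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        pos = np.arange(config.marker_spacing, length + 1, config.marker_spacing)
        chroms.append(np.full(pos.size, chrom, dtype=object))
        positions.append(pos)
    return np.concatenate(chroms), np.concatenate(positions).astype(np.int64)


def _adjacent_recomb_fractions(
    chroms: np.ndarray, positions: np.ndarray, recomb_rate: float
) -> np.ndarray:
    """Per-marker probability of switching haplotype phase during one meiosis.

    Entry i is the recombination fraction between marker i-1 and i (Haldane
    map function on recomb_rate * physical distance); the first marker of each
    chromosome gets 0.5 (independent segregation across chromosomes).
    """
    r = np.empty(positions.size)
    d_bp = np.diff(positions).astype(float)
    d_cm = d_bp / 1e6 * recomb_rate
    r[1:] = 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))
    r[0] = 0.5
    new_chrom = np.empty(positions.size, dtype=bool)
    new_chrom[0] = True
    new_chrom[1:] = chroms[1:] != chroms[:-1]
    r[new_chrom] = 0.5
    return r


def _gamete(h0: np.ndarray, h1: np.ndarray, r: np.ndarray, rng) -> np.ndarray:
    """Draw one gamete per individual by a Markov crossover walk."""
    switch = rng.random(h0.shape) < r[None, :]
    phase = np.cumsum(switch, axis=1) % 2
    return np.where(phase == 0, h0, h1)


def simulate_ril_population(config: SimConfig, rng=None) -> TruthSet:
    """Simulate an F_t RIL population by single-seed descent.

    Starting from the F1 (fully heterozygous), each generation performs one
    meiosis per gamete with interference-free Haldane crossovers and selfs the
    plant; genotypes are recorded at every marker of the grid.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chroms, positions = _marker_grid(config)
    r = _adjacent_recomb_fractions(chroms, positions, config.recomb_rate)
    n, m = config.n_ril, positions.size
    h0 = np.zeros((n, m), dtype=np.int8)  # early-parent haplotype
    h1 = np.ones((n, m), dtype=np.int8)  # late-parent haplotype
    for _ in range(config.generation - 1):
        g0 = _gamete(h0, h1, r, rng)
        g1 = _gamete(h0, h1, r, rng)
        h0, h1 = g0, g1
    genotypes = (h0 + h1).astype(np.int8)
    individuals = [f"RIL_{i + 1:04d}" for i in range(n)]
    qtl_idx = np.array(
        [
            int(np.argmin(np.where(chroms == c, np.abs(positions - p), np.inf)))
            for c, p, _ in config.qtls
        ],
        dtype=np.int64,
    )
    return TruthSet(genotypes, chroms, positions, individuals, list(config.qtls), qtl_idx, config)


def ril_recombinant_fraction(r_meiosis: float) -> float:
    """Map expansion for selfed RILs at fixation: R = 2r / (1 + 2r)."""
    return 2.0 * r_meiosis / (1.0 + 2.0 * r_meiosis)


def expected_het_fraction(generation: int) -> float:
    """Residual per-locus heterozygote fraction after t-1 selfing rounds."""
    return 0.5 ** (generation - 1)


# ---------------------------------------------------------------------------
# Phenotypes


def genetic_values(truth: TruthSet) -> np.ndarray:
    """Additive genetic value per individual: baseline + sum a_q * (g_q - 1)."""
    g = truth.config.baseline + np.zeros(truth.genotypes.shape[0])
    for (c, p, effect), idx in zip(truth.qtls, truth.qtl_marker_idx):
        g = g + effect * (truth.genotypes[:, idx].astype(float) - 1.0)
    return g


def simulate_phenotypes(
    truth: TruthSet,
    config: SimConfig | None = None,
    environments: list[str] | None = None,
    n_rep: int = 2,
    env_effects: dict[str, float] | None = None,
    include_parents: bool = True,
    rng=None,
) -> pd.DataFrame:
    """Simulate replicated multi-environment days-to-flowering phenotypes.

    dtf = genetic value + environment effect + G-by-E deviation + residual.
    The G-by-E and residual variances are scaled from the realized genetic
    variance so the expected entry-mean heritability equals ``config.h2``
    (equal split between the two noise components).
    """
    if config is None:
        config = truth.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if environments is None:
        environments = ["env1", "env2"]
    n_env, n = len(environments), len(truth.individuals)
    if env_effects is None:
        offsets = np.linspace(-3.0, 3.0, n_env) if n_env > 1 else np.array([0.0])
        env_effects = dict(zip(environments, offsets))

    gvals = genetic_values(truth)
    sigma2_g = float(np.var(gvals, ddof=1)) if n > 1 else 0.0
    if sigma2_g > 0:
        # c * (1/E + 1/(E*R)) = sigma2_g * (1/h2 - 1), with sigma2_ge = sigma2_e = c
        c = sigma2_g * (1.0 / config.h2 - 1.0) / (1.0 / n_env + 1.0 / (n_env * n_rep))
    else:
        c = 0.0
    sd = np.sqrt(c)

    rows = []
    gxe = rng.normal(0.0, sd, size=(n, n_env)) if sd > 0 else np.zeros((n, n_env))
    for j, env in enumerate(environments):
        for rep in range(1, n_rep + 1):
            resid = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
            dtf = gvals + env_effects[env] + gxe[:, j] + resid
            for i, ind in enumerate(truth.individuals):
                rows.append((ind, "RIL", env, rep, dtf[i]))
    if include_parents:
        total_effect = sum(e for _, _, e in truth.qtls)
        parent_sd = max(sd * 0.3, 0.0)
        for name, sign in (("parent_early", -1.0), ("parent_late", 1.0)):
            base = config.baseline + sign * total_effect
            for env in environments:
                for rep in range(1, n_rep + 1):
                    noise = rng.normal(0.0, parent_sd) if parent_sd > 0 else 0.0
                    rows.append((name, "parent", env, rep, base + env_effects[env] + noise))
    df = pd.DataFrame(
        rows, columns=["individual", "population", "environment", "replicate", "dtf"]
    )
    return df


# ---------------------------------------------------------------------------
# Bulks and read counts


def constitute_bulks(
    truth: TruthSet,
    phenotypes: pd.DataFrame,
    bulk_size: int | None = None,
    qtl_flank: int = 500_000,
) -> Bulks:
    """Select extreme-tail homozygous individuals for the two bulks.

    Individuals are ranked by mean dtf over all environments/replicates.  Only
    individuals with no residual heterozygosity at markers within
    ``qtl_flank`` of a declared QTL are eligible.  The lowest ``bulk_size``
    form the early bulk and the highest the late bulk; ties are broken
    deterministically by individual ID.
    """
    if bulk_size is None:
        bulk_size = truth.config.bulk_size
    ril = phenotypes[phenotypes["individual"].isin(truth.individuals)]
    means = ril.groupby("individual")["dtf"].mean()
    means = means.reindex(truth.individuals)

    eligible = np.ones(len(truth.individuals), dtype=bool)
    for chrom, pos, _ in truth.qtls:
        in_region = (truth.chroms == chrom) & (
            np.abs(truth.positions - pos) <= qtl_flank
        )
        if in_region.any():
            eligible &= ~(truth.genotypes[:, in_region] == 1).any(axis=1)

    idx = np.flatnonzero(eligible)
    if idx.size < 2 * bulk_size:
        raise ValueError(
            f"insufficient homozygous extremes: need {2 * bulk_size}, "
            f"have {idx.size} eligible individuals"
        )
    dtf = means.to_numpy()[idx]
    order = np.lexsort((idx, dtf))  # ascending dtf, ties by index (ID order)
    early = sorted(truth.individuals[i] for i in idx[order[:bulk_size]])
    late = sorted(truth.individuals[i] for i in idx[order[-bulk_size:]])
    if set(early) & set(late):
        raise ValueError("bulks overlap; population too small for disjoint tails")
    return Bulks(early=early, late=late)


def bulk_allele_frequencies(truth: TruthSet, bulks: Bulks) -> tuple[np.ndarray, np.ndarray]:
    """True late-parent (alt) allele frequency per marker in each bulk."""
    ei, li = bulks.indices(truth.individuals)
    p_early = truth.genotypes[ei].mean(axis=0) / 2.0
    p_late = truth.genotypes[li].mean(axis=0) / 2.0
    return p_early, p_late


def simulate_bulk_readcounts(
    truth: TruthSet,
    bulks: Bulks,
    config: SimConfig | None = None,
    rng=None,
    mean_bq: float = 35.0,
) -> AlleleCountTable:
    """Sample per-SNP read counts for the two parents and two bulks.

    For each SNP and bulk the true alt frequency is the mean allele dosage/2
    over bulk members; total depth ~ Poisson(depth_mean) and alt reads ~
    Binomial(depth, p).  Parents are fixed homozygotes (p = 0 for the early
    parent, which is the reference, and p = 1 for the late parent).
    """
    if config is None:
        config = truth.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    m = truth.n_markers
    p_early, p_late = bulk_allele_frequencies(truth, bulks)
    freqs = {
        "parent_early": np.zeros(m),
        "parent_late": np.ones(m),
        "bulk_early": p_early,
        "bulk_late": p_late,
    }
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    df = pd.DataFrame(
        {
            "chrom": truth.chroms,
            "pos": truth.positions,
            "ref": BASES[ref_idx],
            "alt": BASES[alt_idx],
            "mean_bq": np.full(m, float(mean_bq)),
        }
    )
    for sample, p in freqs.items():
        depth = rng.poisson(config.depth_mean, size=m)
        alt = rng.binomial(depth, p)
        df[sample + "_ref"] = depth - alt
        df[sample + "_alt"] = alt
    return AlleleCountTable(df, list(freqs))


# ---------------------------------------------------------------------------
# Gene-model / genome fixtures

_STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class GenomeAnnotation:
    sequences: dict[str, str]
    genes: list[GeneModel]
    #: the built-in worked codon case: an AAT codon whose middle base carries
    #: an A->G substitution (Asn -> Ser missense) in the first forward gene
    worked_case: dict


def generate_gene_models(
    chrom: str = "Ca4",
    chrom_length: int = 200_000,
    n_genes: int = 12,
    seed: int = 1,
    rng=None,
) -> GenomeAnnotation:
    """Generate a random annotated mini-genome (sequence + gene models).

    Genes alternate strands, have 1-3 CDS exons with valid start/stop codons
    and no internal stops.  The first forward-strand gene carries an AAT codon
    at codon 2 whose middle base provides the A->G worked case used to check
    coding-effect calls.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    seq = rng.integers(0, 4, size=chrom_length)
    seq = "".join(BASES[seq])
    seq = list(seq)

    genes: list[GeneModel] = []
    worked_case: dict = {}
    cursor = 5_000
    for gi in range(n_genes):
        cursor += int(rng.integers(3_000, 8_000))
        strand = "+" if gi % 2 == 0 else "-"
        n_exon = int(rng.integers(1, 4))
        n_codons = int(rng.integers(60, 200))
        codons = ["ATG"]
        while len(codons) < n_codons - 1:
            c = "".join(BASES[rng.integers(0, 4, size=3)])
            if c not in _STOPS:
                codons.append(c)
        codons.append("TAA")
        if strand == "+" and not worked_case:
            codons[1] = "AAT"
        coding = "".join(codons)

        # split the coding sequence into exons separated by introns
        cuts = sorted(rng.choice(np.arange(1, len(coding) // 3), size=n_exon - 1, replace=False) * 3) if n_exon > 1 else []
        pieces, prev = [], 0
        for cut in cuts:
            pieces.append(coding[prev:cut])
            prev = cut
        pieces.append(coding[prev:])
        if strand == "-":
            pieces = pieces[::-1]  # genomic order: last transcribed piece first

        segs: list[tuple[int, int]] = []
        gpos = cursor
        for k, piece in enumerate(pieces):
            a, b = gpos, gpos + len(piece) - 1
            segs.append((a, b))
            insert = piece if strand == "+" else _revcomp(piece)
            seq[a - 1 : b] = list(insert)
            gpos = b + 1 + (int(rng.integers(100, 500)) if k < len(pieces) - 1 else 0)
        gene_start, gene_end = segs[0][0], segs[-1][1]
        if gene_end > chrom_length - 3_000:
            break
        ordered = segs if strand == "+" else segs[::-1]
        gene = GeneModel(f"Gene{gi + 1:03d}", chrom, strand, gene_start, gene_end, ordered)
        genes.append(gene)
        if strand == "+" and not worked_case:
            # codon 2 occupies CDS offsets 3..5; middle base at offset 4
            pos = _cds_offset_to_genomic(gene, 4)
            worked_case = {"gene_id": gene.gene_id, "pos": pos, "ref": "A", "alt": "G"}
        cursor = gene_end
    return GenomeAnnotation({chrom: "".join(seq)}, genes, worked_case)


def _cds_offset_to_genomic(gene: GeneModel, offset: int) -> int:
    """Map a 0-based offset in the spliced CDS to a genomic position."""
    for a, b in gene.cds:
        seg_len = b - a + 1
        if offset < seg_len:
            return a + offset if gene.strand == "+" else b - offset
        offset -= seg_len
    raise ValueError("offset beyond CDS length")


# ---------------------------------------------------------------------------
# Diversity panels


def simulate_diversity_panel(
    n_cultivated: int = 93,
    n_wild: int = 79,
    n_sites: int = 2_000,
    reduction: float = 0.9,
    sweep_region: tuple[int, int] = (800_001, 1_200_000),
    seed: int = 1,
    site_spacing: int = 1_000,
    n_founders: int = 20,
    spectrum: str = "uniform",
    chrom: str = "Ca4",
):
    """Simulate cultivated and wild haplotype panels with a planted sweep.

    The wild panel draws per-site alt-allele frequencies either from a
    uniform(0.05, 0.5) folded spectrum (``spectrum="uniform"``) or from the
    neutral-coalescent site-frequency spectrum (``spectrum="neutral"``, under
    which Tajima's D is centred near zero).  The cultivated panel passes the
    wild haplotypes through an ``n_founders``-lineage bottleneck; inside
    ``sweep_region`` per-site heterozygosity is further scaled so the expected
    cultivated/wild diversity ratio in the region is ``1 - reduction``.
    """
    from .diversity import HaplotypeMatrix

    if not 0.0 <= reduction <= 1.0:
        raise ValueError("reduction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    positions = np.arange(1, n_sites + 1, dtype=np.int64) * site_spacing
    lo, hi = sweep_region
    in_region = (positions >= lo) & (positions <= hi)
    if not in_region.any():
        raise ValueError("sweep_region contains no simulated sites")

    if spectrum == "uniform":
        p_wild = rng.uniform(0.05, 0.5, size=n_sites)
        wild = (rng.random((n_wild, n_sites)) < p_wild[None, :]).astype(np.int8)
    elif spectrum == "neutral":
        counts = np.arange(1, n_wild)
        weights = 1.0 / counts
        weights /= weights.sum()
        alt_counts = rng.choice(counts, size=n_sites, p=weights)
        wild = np.zeros((n_wild, n_sites), dtype=np.int8)
        for j, k in enumerate(alt_counts):
            carriers = rng.choice(n_wild, size=k, replace=False)
            wild[carriers, j] = 1
    else:
        raise ValueError(f"unknown spectrum {spectrum!r}")

    founders = rng.choice(n_wild, size=min(n_founders, n_wild), replace=False)
    p_c = wild[founders].mean(axis=0)
    f = 1.0 - reduction
    het = 2.0 * p_c * (1.0 - p_c)
    target_het = np.where(in_region, f * het, het)
    # invert 2p(1-p) = target for the root nearest the bottlenecked frequency
    disc = np.sqrt(np.clip(1.0 - 2.0 * target_het, 0.0, 1.0))
    p_low = 0.5 * (1.0 - disc)
    p_high = 0.5 * (1.0 + disc)
    p_target = np.where(p_c <= 0.5, p_low, p_high)
    cultivated = (rng.random((n_cultivated, n_sites)) < p_target[None, :]).astype(np.int8)

    wild_m = HaplotypeMatrix(
        matrix=wild,
        positions=positions,
        sample_ids=[f"W{i + 1:03d}" for i in range(n_wild)],
        label="wild",
        chrom=chrom,
    )
    cult_m = HaplotypeMatrix(
        matrix=cultivated,
        positions=positions,
        sample_ids=[f"C{i + 1:03d}" for i in range(n_cultivated)],
        label="cultivated",
        chrom=chrom,
    )
    return cult_m, wild_m
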
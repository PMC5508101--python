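# Methods

## Scope and data model

The package analyses bulked-segregant resequencing experiments on biparental
RIL populations of a selfing species.  Its inputs are allele-depth tables
(VCF with per-sample AD, or TSV) for two bulks and two parents, gene models
(GFF3) with a reference sequence (FASTA) for annotation, replicated
phenotype tables, and genotype matrices for diversity scans.  Internal
coordinates are 1-based inclusive everywhere; BED export is the only 0-based
surface, so published SNP positions can be used verbatim.  Sample roles
(parent_early, parent_late, bulk_early, bulk_late) are always assigned
explicitly, never guessed from names.

## SNP-index statistics

Per SNP, `index = depth_alt / (depth_ref + depth_alt)` with "alt" meaning
the allele differing from the reference (early-parent) assembly, and
`delta = index_early − index_late`.  Because the reference *is* one of the
parents, a trait-fixed locus gives index ≈ 0 in the like-parent bulk and
≈ 1 in the other, so delta is signed; calling works on |delta| and the sign
convention is a configuration option (`orientation`).

Filters keep SNPs with total depth ≥ 10 in **both** bulks, mean base quality
≥ 20, parents homozygous for opposite alleles (indices rounding to 0/1 at
the 0.1/0.9 cutoffs), and drop SNPs below a 0.3 index floor in both bulks —
the standard guard against systematic alignment artefacts, disablable with
`low_index_floor=None`.  Per-filter removal counts are returned.

Sliding windows are anchored at position 1 with window W and increment s;
window values are unweighted means over member SNPs (not depth-weighted), a
trailing partial window is kept when it contains a SNP, and empty windows
carry `n_snps = 0` with undefined means.  The canonical parameters for real
pseudomolecules are W = 10 Mb, s = 1 kb; the synthetic fixtures use W = 5 Mb,
s = 1 Mb (calling) and 2-Mb non-overlapping tiles (calibration) — see
"Problem sizes" below.

## Null confidence bands

The no-QTL null is simulated directly from the experimental design: each
bulk draws `bulk_size` genotypes from the F_t selfing distribution
(heterozygote probability h = (1/2)^(t−1), homozygote classes (1−h)/2 each),
the bulk allele frequency is mean dosage / 2, and reads are binomial at the
given depth.  Two-sided empirical quantiles of delta give the 95 / 99 /
99.9% bands, tabulated on a depth grid {10, 20, 30, 50, 75, 100, 150 as
configured} with 10,000 replicates per depth and linearly interpolated at
each SNP's min(bulk depths); depths below the grid are clamped to the
nearest grid value (no extrapolation).  The window bound is the mean of
member-SNP bounds, mirroring how the window delta is the mean of member
deltas.  This is conservative for windows (read noise averages out but the
genotype-sampling component is shared across linked SNPs), which the type-I
calibration study confirms: exceedance of the 99% band on independent tiles
runs below 1%.

## QTL calling, consensus, candidates

A window supports a QTL when (i) its mean delta lies outside the attached
band at the chosen level, (ii) |mean delta| > 0.5, and (iii) the bulk index
means are near-fixed in opposite directions (high bulk ≥ 0.8, low bulk
≤ 0.2).  Maximal runs of ≥ 2 consecutive supporting windows with a constant
delta sign become intervals, with endpoints snapped to the outermost SNPs of
the run and the per-SNP peak delta reported.  Interval length is defined as
`end − start` (not end − start + 1), which is the convention that makes the
published flanking positions and interval sizes mutually consistent.  When
several intervals are called, `primary_call` designates the one containing
the genome-wide peak window.

Consensus across two populations sharing a parent: overlapping intervals on
the same chromosome with the same delta sign intersect to
[max(starts), min(ends)]; same-sign matching prevents merging QTLs with
opposite parental contributions.  Non-overlapping calls are reported as
population-specific.  Inside a consensus interval, candidate SNPs are those
at the maximal |delta| (within a tolerance), mapped to genes through the
location classifier; genes are ranked by their count of peak SNPs, ties
broken by proximity to the delta peak.

## Variant annotation

Positions classify as CDS, intron (gene span minus CDS — UTRs are not
modelled, matching the category set used in this literature), URR/DRR
(fixed strand-aware flanks, default 2,000 bp each, configurable because
reported URR/DRR proportions depend directly on this choice), or intergenic,
with precedence CDS > intron > URR > DRR > intergenic and nearest-gene
tie-breaking for overlapping flanks.  Coding effects locate the codon from
spliced CDS coordinates (strand-aware), substitute the complemented base on
minus-strand genes, translate with the standard nuclear code, and label the
change synonymous / missense / nonsense.  A metamorphic test checks that
minus-strand annotation equals the plus-strand computation on the
reverse-complemented genome.

## Phenotype statistics

Trait summaries report mean, sample SD (n−1), range and CV% = 100·SD/mean to
one decimal.  Broad-sense heritability is computed on an entry-mean basis
from the expected mean squares of a balanced genotype × environment ANOVA
with replication (statsmodels OLS/anova_lm):

    σ²e = MS_error,  σ²ge = (MS_GxE − MS_error)/R,  σ²g = (MS_G − MS_GxE)/(E·R)
    H² = σ²g / (σ²g + σ²ge/E + σ²e/(E·R))

Negative component estimates are truncated at 0 and flagged; with one
environment the GxE term drops out.  Unbalanced tables are rejected with a
pointer to per-environment analysis rather than silently reweighted.
Environments are treated as fixed.  Transgressive segregation counts RIL
entry means beyond each parental mean ± 2 SD.

## Diversity scans

Panels of inbred accessions are haplotype matrices; genotype dosage 0/2
expands to two identical haplotypes and residual heterozygotes to one ref +
one alt.  Per site, π = (n/(n−1))·2p̂(1−p̂) (equal to the mean pairwise
difference, which the tests verify against brute force); windows are 100-kb
non-overlapping with per-site means reported so windows of unequal site
counts compare fairly.  Tajima's D uses the standard a1…e2 constants and is
undefined (NaN) with no segregating sites.  The cultivated/wild reduction
ratio is 100 × Σπ_cultivated / Σπ_wild over the windows overlapping a
region; because windows are the unit, regions should align with the 100-kb
grid.  `single_marker_pve` is a deliberately simple one-way R² screen — it
replaces no mixed-model association and carries no structure/kinship
correction.

## The synthetic-data generator

The generator reproduces the statistical structure the analysis assumes, at
desk scale:

* **RIL cross** — F9 single-seed descent from a fully heterozygous F1, one
  meiosis per gamete per generation, Haldane (interference-free) crossovers,
  default 2.5 cM/Mb (a chickpea-like ~845 cM genetic map over a 334-Mb
  assembly).  Closed forms used as oracles: residual heterozygosity
  (1/2)^(t−1) and RIL map expansion R = 2r/(1+2r).
* **Phenotypes** — dtf = baseline + Σ a_q(g_q − 1) + environment + G×E +
  residual, with the two noise variances set equal and scaled from the
  realized genetic variance so the expected entry-mean H² equals the target.
  Defaults: baseline 64 d (mid-parent of 43/85 d parents), QTL effects
  12 + 9 d, H² 0.8, two environments × two replicates.
* **Bulks** — the 10 lowest- and 10 highest-DTF individuals with no residual
  heterozygosity within ±500 kb of a declared QTL (mirroring the practice of
  verifying bulk homozygosity before sequencing); ties break by individual
  ID, shortfalls raise an error naming the deficit.
* **Read counts** — per SNP and sample, depth ~ Poisson(30) and alt reads ~
  Binomial(depth, p) with p the bulk mean dosage/2; parents are fixed
  homozygotes.  Everything is a pure function of (config, seed).
* **Gene space** — random multi-exon genes on both strands with valid
  start/stop codons and no internal stops, written as FASTA + GFF3, plus a
  built-in worked codon case (an AAT codon whose middle A→G gives the
  Asn→Ser missense call) used as a fixed point for the annotation code.
* **Diversity panels** — wild site frequencies from a uniform(0.05, 0.5)
  folded spectrum by default, or from the neutral coalescent spectrum
  (`spectrum="neutral"`), which is the setting under which Tajima's D is
  centred at zero — a flat spectrum has an intermediate-frequency excess and
  strongly positive D, so neutrality checks use the neutral spectrum.  The
  cultivated panel passes through a 20-founder bottleneck; inside the sweep
  region per-site heterozygosity is scaled by exact inversion of 2p(1−p) so
  the expected cultivated/wild ratio equals 1 − reduction.

What the generator does **not** emulate: alignment and variant-calling
artefacts, depth heterogeneity beyond Poisson, segregation distortion,
epistasis, linkage disequilibrium structure of real germplasm panels
(cultivated haplotypes are exchangeable draws, not pedigreed lineages), or
coalescent-exact wild genealogies.  Passing tests therefore demonstrate that
the statistics behave correctly under the stated sampling model, not that
real-data artefacts are handled.

## Problem sizes and numerical choices

The default fixture is one 55-Mb chromosome with SNPs every 5 kb (~11,000
markers) and populations of 260/204 RILs — small enough that the full test
suite runs in about a minute and the acceptance script in well under one.
Calibration and recovery studies use 20 seeded replicates each:

* *Type-I calibration*: 4 × 40 Mb no-QTL genomes, 40 RILs, random-tail
  bulks, 2-Mb non-overlapping tiles; pooled 99%-band exceedance and 99.9%
  false calls.
* *Planted-QTL recovery*: one 15-day QTL at 27.5 Mb, 260 RILs; a hit is the
  primary call's midpoint within one 5-Mb window of truth.  The 5-Mb window
  is matched to the linkage-decay scale of the bulk signal (the windowed
  delta falls to the 99% band roughly 6 Mb from a fixed QTL at 2.5 cM/Mb);
  markedly smaller windows make run edges — and hence midpoints — noisy.
* *Heritability recovery*: 260 RILs, 2 environments × 2 replicates.
* *Sweep recovery*: 93 + 79 accessions, 2,000 sites, 90% reduction over a
  400-kb window-aligned region.
* *Heterozygosity decay*: 500 RILs × 1,000 loci.  The check uses the
  empirical standard error across individuals: loci on a linked grid are
  correlated within an individual, so a naive all-loci binomial SE would be
  an order of magnitude too small.

Other numerical choices: empirical band quantiles are two-sided
(e.g. 0.005/0.995 for the 99% band); windows with no SNPs are excluded from
calling; `min_windows = 2` suppresses single-window spikes; negative ANOVA
variance components truncate to zero with a flag; Tajima's D raises on a
non-positive variance term rather than returning a misleading number.

## Known limitations

Real 10-Mb/1-kb windowing over eight pseudomolecules is supported but slow
in pure pandas relative to specialized implementations; the window bound is
a per-SNP-band mean rather than a re-simulated windowed null (conservative,
as measured); the association utility is a naive R² screen; URR/DRR
proportions depend on the configurable flank length; and the consensus step
trusts the config's claim that populations share a parent — it performs no
genetic verification.
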
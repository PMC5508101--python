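# mqtlseq

Multiple QTL-seq analysis for bulked-segregant trait mapping in selfing
crops, built around the chickpea flowering-time use case: recombinant inbred
line (RIL) populations phenotyped for days to 50% flowering (DTF), extreme
early/late bulks of homozygous individuals resequenced together with the two
parents, and QTLs mapped from bulk allele-frequency differentials.

It is written for geneticists running (or simulating) bulked-segregant
whole-genome sequencing experiments who want a tested, scriptable pipeline
rather than a one-off analysis: every stage is a plain library function, the
command line is a thin wrapper, and a bundled synthetic-data generator makes
the whole pipeline runnable and testable offline.

## The statistics

For each SNP that differentiates the two parents, the **SNP-index** of a bulk
is the fraction of reads carrying the allele that differs from the reference
(early-parent) assembly,

    SNP-index = depth_alt / (depth_ref + depth_alt),

and **Δ(SNP-index)** is the difference between the early- and late-flowering
bulks.  At a locus co-segregating with the trait the two bulks are fixed for
opposite alleles and Δ approaches ±1; elsewhere it fluctuates around 0.  SNPs
are filtered (total depth ≥ 10 in both bulks, mean base quality ≥ 20,
homozygous-differentiated parents, low-index floor 0.3) and smoothed with a
sliding-window mean.  Significance comes from a **simulated null**: bulks of
10 F9 genotypes are drawn with residual heterozygosity (1/2)^8, reads are
sampled binomially at the observed depth, and empirical 95/99/99.9% bands of
the null Δ are attached per window.  Runs of significant windows with
|Δ| > 0.5 and near-fixed bulk indices (≥ 0.8 / ≤ 0.2) become QTL intervals.
The **multiple QTL-seq** step intersects calls from two populations sharing a
parent, narrowing each QTL to the consensus overlap, inside which peak-Δ
candidate SNPs are mapped onto gene models (CDS / intron / URR / DRR /
intergenic; synonymous / missense / nonsense).  A diversity module computes
windowed θπ, Watterson's θ and Tajima's D for cultivated vs. wild panels and
the θπ(cultivated)/θπ(wild) reduction ratio at sweep loci.

## Worked example

Two simulated F9 RIL populations (260 and 204 lines) sharing an early parent,
one planted QTL at 27.5 Mb on a 55-Mb chromosome, bulks of 10 homozygous
extremes at ~30× depth:

```python
import mqtlseq as mq
from mqtlseq import synthetic_data as sd
from mqtlseq.evaluation import ROLES

bands = mq.build_null_bands(bulk_size=10, generation=9,
                            depths=(10, 20, 30, 50, 75), seed=11)
calls = {}
for pop, (n_ril, seed) in {"popA": (260, 11), "popB": (204, 12)}.items():
    cfg = sd.SimConfig(n_ril=n_ril, qtls=[("Ca4", 27_500_000, 15.0)], seed=seed)
    truth = sd.simulate_ril_population(cfg)
    phen = sd.simulate_phenotypes(truth)
    bulks = sd.constitute_bulks(truth, phen)
    table = sd.simulate_bulk_readcounts(truth, bulks)
    records, _ = mq.filter_snps(table, ROLES)
    profile = mq.sliding_window_profile(records, 5_000_000, 1_000_000,
                                        cfg.chrom_lengths)
    profile = mq.attach_bands(profile, records, bands)
    calls[pop] = mq.call_qtls(profile, records, level=99.0, population=pop)

consensus, _ = mq.intersect_qtls(calls["popA"], calls["popB"])
```

which prints (via the obvious report loop):

```
popA: Ca4:18005000-36000000  (18.0 Mb, peak delta -1.00)
popB: Ca4:22005000-34000000  (11.99 Mb, peak delta -1.00)
consensus: Ca4:22005000-34000000  (11.99 Mb)
```

Each population alone brackets the QTL with a broad interval (linkage decay
around a fixed QTL is slow on a ~140-cM chromosome); intersecting the two
populations narrows the region — the core value of the multiple-QTL-seq
design.  The peak Δ of −1.00 means the bulks are fully fixed for opposite
alleles at the QTL; the sign is negative because the reference assembly *is*
the early parent, so the early bulk's SNP-index is near 0 there (the
orientation is configurable).

The same run is available as one command:

```sh
mqtlseq run --seed 7 --out runs/demo/
```

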
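import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from mqtlseq import synthetic_data as sd
from mqtlseq.phenotype_stats import broad_sense_heritability
from mqtlseq.variant_annotation import coding_effect


def small_config(**kw):
    defaults = dict(
        n_ril=100,
        chrom_lengths={"Ca4": 5_000_000},
        marker_spacing=50_000,
        qtls=[("Ca4", 2_500_000, 10.0)],
        seed=1,
    )
    defaults.update(kw)
    return sd.SimConfig(**defaults)


class TestRilSimulation:
    def test_zero_recombination_gives_parental_blocks(self):
        cfg = small_config(recomb_rate=0.0, qtls=[])
        truth = sd.simulate_ril_population(cfg)
        # within each individual every marker shares one genotype
        assert all(np.unique(row).size == 1 for row in truth.genotypes)

    def test_f9_heterozygosity_matches_selfing_series(self):
        # loci 10 cM apart to weaken linkage between markers
        cfg = sd.SimConfig(
            n_ril=500,
            chrom_lengths={"c1": 40_000_000},
            marker_spacing=4_000_000,
            qtls=[],
            seed=11,
        )
        truth = sd.simulate_ril_population(cfg)
        per_ind = (truth.genotypes == 1).mean(axis=1)
        expected = sd.expected_het_fraction(9)
        se = per_ind.std(ddof=1) / np.sqrt(cfg.n_ril)
        assert abs(per_ind.mean() - expected) <= 3 * se + 1e-12

    def test_adjacent_marker_recombination_matches_ril_map_expansion(self):
        cfg = sd.SimConfig(
            n_ril=2_000,
            chrom_lengths={"c1": 2_000_000},
            marker_spacing=1_000_000,
            qtls=[],
            recomb_rate=1.0,
            seed=5,
        )
        truth = sd.simulate_ril_population(cfg)
        g = truth.genotypes
        hom = (g[:, 0] != 1) & (g[:, 1] != 1)
        rec = ((g[:, 0] == 0) & (g[:, 1] == 2)) | ((g[:, 0] == 2) & (g[:, 1] == 0))
        r = 0.5 * (1 - np.exp(-2 * 1.0 / 100))
        expected = sd.ril_recombinant_fraction(r)
        observed = rec[hom].sum() / hom.sum()
        se = np.sqrt(expected * (1 - expected) / hom.sum())
        assert abs(observed - expected) <= 3 * se

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            small_config(chrom_lengths={"c1": 0}, qtls=[]).validate()

    def test_determinism(self):
        cfg = small_config()
        t1 = sd.simulate_ril_population(cfg)
        t2 = sd.simulate_ril_population(small_config())
        assert np.array_equal(t1.genotypes, t2.genotypes)


class TestPhenotypes:
    def test_no_qtl_no_noise_gives_identical_rils(self):
        cfg = small_config(qtls=[])
        truth = sd.simulate_ril_population(cfg)
        phen = sd.simulate_phenotypes(truth, include_parents=False)
        for env, sub in phen.groupby("environment"):
            assert sub["dtf"].nunique() == 1

    def test_parents_differ_by_summed_qtl_effects(self):
        cfg = small_config(qtls=[("Ca4", 1_000_000, 8.0), ("Ca4", 4_000_000, 5.0)])
        truth = sd.simulate_ril_population(cfg)
        phen = sd.simulate_phenotypes(truth)
        means = phen.groupby("individual")["dtf"].mean()
        gap = means["parent_late"] - means["parent_early"]
        assert gap == pytest.approx(2 * 13.0, abs=3.0)

    def test_h2_recovery_single_run(self):
        cfg = sd.SimConfig(
            n_ril=260, marker_spacing=500_000, h2=0.8, seed=9
        )
        truth = sd.simulate_ril_population(cfg)
        phen = sd.simulate_phenotypes(truth)
        result = broad_sense_heritability(phen)
        assert 70 <= result.h2_percent <= 90


class TestBulks:
    def test_bulk_sizes_and_disjointness(self):
        cfg = small_config(n_ril=60, bulk_size=10)
        truth = sd.simulate_ril_population(cfg)
        phen = sd.simulate_phenotypes(truth)
        bulks = sd.constitute_bulks(truth, phen)
        assert len(bulks.early) == len(bulks.late) == 10
        assert not set(bulks.early) & set(bulks.late)

    def test_tie_break_on_identical_phenotypes_is_deterministic(self):
        cfg = small_config(qtls=[])
        truth = sd.simulate_ril_population(cfg)
        phen = sd.simulate_phenotypes(truth, include_parents=False)
        # no QTL, no noise: all dtf identical -> extreme IDs chosen by order
        bulks = sd.constitute_bulks(truth, phen, bulk_size=5)
        assert bulks.early == truth.individuals[:5]
        assert bulks.late == sorted(truth.individuals[-5:])

    def test_insufficient_homozygotes_raises(self):
        cfg = small_config(n_ril=10, bulk_size=5)
        truth = sd.simulate_ril_population(cfg)
        truth.genotypes[:, :] = 1  # everyone heterozygous at the QTL
        phen = sd.simulate_phenotypes(truth)
        with pytest.raises(ValueError, match="insufficient homozygous"):
            sd.constitute_bulks(truth, phen)

    def test_large_effect_qtl_fixes_early_bulk(self):
        fixed = 0
        for seed in range(1, 21):
            cfg = small_config(n_ril=120, seed=seed, qtls=[("Ca4", 2_500_000, 15.0)])
            truth = sd.simulate_ril_population(cfg)
            phen = sd.simulate_phenotypes(truth)
            bulks = sd.constitute_bulks(truth, phen)
            p_early, _ = sd.bulk_allele_frequencies(truth, bulks)
            fixed += int(p_early[truth.qtl_marker_idx[0]] == 0.0)
        assert fixed >= 19


class TestReadCounts:
    def test_fixed_reference_bulk_has_zero_alt_reads(self):
        cfg = small_config()
        truth = sd.simulate_ril_population(cfg)
        truth.genotypes[:, :] = 0
        phen = sd.simulate_phenotypes(truth)
        bulks = sd.constitute_bulks(truth, phen)
        table = sd.simulate_bulk_readcounts(truth, bulks)
        assert (table.df["bulk_early_alt"] == 0).all()
        assert (table.df["bulk_late_alt"] == 0).all()
        assert (table.df["parent_early_alt"] == 0).all()

    def test_half_frequency_bulk_mean_index_near_half(self):
        cfg = sd.SimConfig(
            n_ril=20,
            chrom_lengths={"c1": 10_000_000},
            marker_spacing=1_000,
            qtls=[],
            depth_mean=30,
            seed=3,
        )
        truth = sd.simulate_ril_population(cfg)
        truth.genotypes[:, :] = 1  # every member heterozygous: p = 0.5
        bulks = sd.Bulks(truth.individuals[:10], truth.individuals[10:20])
        table = sd.simulate_bulk_readcounts(truth, bulks)
        idx = table.df["bulk_early_alt"] / (
            table.df["bulk_early_alt"] + table.df["bulk_early_ref"]
        )
        assert idx.mean() == pytest.approx(0.5, abs=0.01)

    def test_same_seed_gives_identical_tables(self):
        cfg = small_config()
        truth = sd.simulate_ril_population(cfg)
        phen = sd.simulate_phenotypes(truth)
        bulks = sd.constitute_bulks(truth, phen)
        t1 = sd.simulate_bulk_readcounts(truth, bulks)
        t2 = sd.simulate_bulk_readcounts(truth, bulks)
        pd.testing.assert_frame_equal(t1.df, t2.df)


class TestGeneModels:
    def test_all_cds_translate_cleanly(self, genome_annotation):
        for g in genome_annotation.genes:
            seq = genome_annotation.sequences[g.chrom]
            parts = []
            for a, b in g.cds:
                s = seq[a - 1 : b]
                parts.append(s if g.strand == "+" else str(Seq(s).reverse_complement()))
            cds = "".join(parts)
            assert len(cds) % 3 == 0
            prot = str(Seq(cds).translate())
            assert prot.startswith("M") and prot.endswith("*")
            assert "*" not in prot[:-1]

    def test_worked_codon_case_is_asn_to_ser(self, genome_annotation):
        wc = genome_annotation.worked_case
        gene = next(g for g in genome_annotation.genes if g.gene_id == wc["gene_id"])
        eff = coding_effect(
            wc["pos"], wc["ref"], wc["alt"], gene, genome_annotation.sequences[gene.chrom]
        )
        assert (eff.ref_codon, eff.alt_codon) == ("AAT", "AGT")
        assert (eff.ref_aa, eff.alt_aa) == ("N", "S")
        assert eff.effect == "missense"


class TestDiversityPanels:
    def test_no_reduction_keeps_region_like_background(self):
        from mqtlseq.diversity import diversity_ratio, diversity_windows

        cult, wild = sd.simulate_diversity_panel(reduction=0.0, seed=4)
        wc, ww = diversity_windows(cult), diversity_windows(wild)
        inside, _ = diversity_ratio(wc, ww, (800_001, 1_200_000))
        outside, _ = diversity_ratio(wc, ww, (1, 800_000))
        assert abs(inside - outside) < 10.0

    def test_neutral_wild_panel_tajimas_d_near_zero(self):
        from mqtlseq.diversity import tajimas_d

        ds = [
            tajimas_d(sd.simulate_diversity_panel(seed=s, spectrum="neutral")[1])
            for s in range(20)
        ]
        assert abs(np.mean(ds)) < 0.5

    def test_sweep_region_outside_sites_rejected(self):
        with pytest.raises(ValueError, match="sweep_region"):
            sd.simulate_diversity_panel(sweep_region=(10**9, 2 * 10**9), seed=1)

    def test_invalid_reduction_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_diversity_panel(reduction=1.5, seed=1)
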
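import itertools

import numpy as np
import pytest

from mqtlseq import diversity as dv


def hap(rows):
    m = np.array(rows, dtype=np.int8)
    return dv.HaplotypeMatrix(m, np.arange(1, m.shape[1] + 1) * 1_000)


def brute_force_pi(matrix: np.ndarray) -> float:
    """Mean pairwise Hamming distance over all haplotype pairs."""
    n = matrix.shape[0]
    total = sum(
        np.sum(matrix[i] != matrix[j]) for i, j in itertools.combinations(range(n), 2)
    )
    return total / (n * (n - 1) / 2)


def oracle_tajimas_d(matrix: np.ndarray) -> float:
    """Independent constant-by-constant Tajima's D computation."""
    n = matrix.shape[0]
    p = matrix.mean(axis=0)
    s = int(((p > 0) & (p < 1)).sum())
    pi = brute_force_pi(matrix)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))


class TestThetaPi:
    def test_monomorphic_window_is_zero(self):
        assert dv.theta_pi(hap([[0, 0, 0], [0, 0, 0]])) == 0.0

    def test_two_haplotypes_three_differences(self):
        assert dv.theta_pi(hap([[0, 0, 0, 1], [1, 1, 1, 1]])) == pytest.approx(3.0)

    def test_matches_brute_force_pairwise_differences(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            m = (rng.random((20, 50)) < rng.uniform(0.1, 0.5)).astype(np.int8)
            h = dv.HaplotypeMatrix(m, np.arange(1, 51))
            assert dv.theta_pi(h) == pytest.approx(brute_force_pi(m), abs=1e-10)

    def test_invariant_to_sample_order_and_allele_relabelling(self):
        rng = np.random.default_rng(9)
        m = (rng.random((12, 40)) < 0.3).astype(np.int8)
        h = dv.HaplotypeMatrix(m, np.arange(1, 41))
        shuffled = dv.HaplotypeMatrix(m[rng.permutation(12)], np.arange(1, 41))
        flipped = dv.HaplotypeMatrix(1 - m, np.arange(1, 41))
        assert dv.theta_pi(h) == pytest.approx(dv.theta_pi(shuffled), abs=1e-12)
        assert dv.theta_pi(h) == pytest.approx(dv.theta_pi(flipped), abs=1e-12)

    def test_single_haplotype_rejected(self):
        with pytest.raises(ValueError):
            hap([[0, 1, 0]])


class TestTajimasD:
    def test_matches_independent_constants_oracle(self):
        m = np.array([[0, 0, 0, 0], [0, 0, 0, 0], [1, 1, 1, 1], [1, 1, 1, 1]], dtype=np.int8)
        h = dv.HaplotypeMatrix(m, np.arange(1, 5))
        assert dv.tajimas_d(h) == pytest.approx(oracle_tajimas_d(m), abs=1e-10)
        rng = np.random.default_rng(10)
        for _ in range(5):
            m = (rng.random((20, 50)) < rng.uniform(0.1, 0.4)).astype(np.int8)
            if not ((m.mean(0) > 0) & (m.mean(0) < 1)).any():
                continue
            h = dv.HaplotypeMatrix(m, np.arange(1, 51))
            assert dv.tajimas_d(h) == pytest.approx(oracle_tajimas_d(m), abs=1e-10)

    def test_constants_satisfy_published_identities(self):
        for n in range(4, 51):
            c = dv.tajima_constants(n)
            assert c["c1"] == pytest.approx(c["b1"] - 1 / c["a1"], abs=1e-12)
            assert c["e1"] == pytest.approx(c["c1"] / c["a1"], abs=1e-12)
            assert c["e2"] == pytest.approx(c["c2"] / (c["a1"] ** 2 + c["a2"]), abs=1e-12)

    def test_singleton_excess_gives_negative_d(self):
        m = np.zeros((10, 5), dtype=np.int8)
        for j in range(5):
            m[j % 10, j] = 1  # five singleton sites
        assert dv.tajimas_d(dv.HaplotypeMatrix(m, np.arange(1, 6))) < 0

    def test_no_segregating_sites_is_nan(self):
        assert np.isnan(dv.tajimas_d(hap([[0, 0], [0, 0], [0, 0], [0, 0]])))

    def test_d_invariant_under_folding(self):
        rng = np.random.default_rng(11)
        m = (rng.random((10, 30)) < 0.3).astype(np.int8)
        h1 = dv.HaplotypeMatrix(m, np.arange(1, 31))
        h2 = dv.HaplotypeMatrix(1 - m, np.arange(1, 31))
        assert dv.tajimas_d(h1) == pytest.approx(dv.tajimas_d(h2), abs=1e-12)


class TestWindows:
    def test_windowed_segregating_sites_sum_to_total(self):
        rng = np.random.default_rng(12)
        m = (rng.random((10, 200)) < 0.3).astype(np.int8)
        h = dv.HaplotypeMatrix(m, rng.choice(np.arange(1, 1_000_001), 200, replace=False))
        win = dv.diversity_windows(h, window_size=100_000)
        total_s = int(((m.mean(0) > 0) & (m.mean(0) < 1)).sum())
        assert win["S"].sum() == total_s
        assert win["n_sites"].sum() == 200
        assert (win["theta_pi"] >= 0).all()

    def test_genotype_dosage_expansion(self):
        dosage = np.array([[0, 2, 1], [2, 0, 1]])
        h = dv.HaplotypeMatrix.from_genotypes(dosage, [10, 20, 30])
        assert h.matrix.shape == (4, 3)
        # heterozygote dosage 1 expands to one ref + one alt haplotype
        assert sorted(h.matrix[:, 2].tolist()) == [0, 0, 1, 1]
        assert h.matrix[:, 0].tolist() == [0, 0, 1, 1]


class TestDiversityRatio:
    def test_identical_panels_give_100_percent(self):
        rng = np.random.default_rng(13)
        m = (rng.random((20, 100)) < 0.3).astype(np.int8)
        h = dv.HaplotypeMatrix(m, np.arange(1, 101) * 1_000)
        w = dv.diversity_windows(h, 50_000)
        ratio, per_window = dv.diversity_ratio(w, w)
        assert ratio == 100.0
        assert np.allclose(per_window["ratio_percent"].dropna(), 100.0)

    def test_subsampling_does_not_bias_pi(self):
        rng = np.random.default_rng(14)
        ratios = []
        for _ in range(20):
            m = (rng.random((60, 400)) < rng.uniform(0.1, 0.5, size=400)).astype(np.int8)
            pos = np.arange(1, 401) * 1_000
            full = dv.HaplotypeMatrix(m, pos)
            sub = dv.HaplotypeMatrix(m[rng.choice(60, 30, replace=False)], pos)
            r, _ = dv.diversity_ratio(
                dv.diversity_windows(sub, 100_000), dv.diversity_windows(full, 100_000)
            )
            ratios.append(r)
        assert np.mean(ratios) == pytest.approx(100.0, abs=2.0)

    def test_zero_wild_diversity_rejected(self):
        h = hap([[0, 0], [0, 0], [0, 0], [0, 0]])
        w = dv.diversity_windows(h, 10_000)
        with pytest.raises(ValueError, match="undefined"):
            dv.diversity_ratio(w, w)


class TestSingleMarkerPve:
    def test_deterministic_phenotype_gives_full_r2(self):
        g = np.array([0, 0, 2, 2, 1, 1])
        y = g * 5.0 + 10
        assert dv.single_marker_pve(g, y) == pytest.approx(100.0)

    def test_null_marker_explains_little(self):
        rng = np.random.default_rng(15)
        small = 0
        for _ in range(20):
            g = rng.choice([0, 2], size=200)
            y = rng.normal(size=200)
            small += int(dv.single_marker_pve(g, y) < 5.0)
        assert small >= 18

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(16)
        pves = []
        for _ in range(10):
            g = rng.choice([0, 2], size=200)
            signal = (g - 1.0) * 1.0  # var = 1 on dosage scale
            noise = rng.normal(scale=np.sqrt(1.5), size=200)  # PVE = 1/2.5 = 40%
            pves.append(dv.single_marker_pve(g, signal + noise))
        assert np.mean(pves) == pytest.approx(40.0, abs=8.0)

    def test_monomorphic_marker_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            dv.single_marker_pve([1, 1, 1, 1], [1.0, 2.0, 3.0, 4.0])
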
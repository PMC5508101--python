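"""Replication studies on synthetic data.

Genome-scale results from real resequencing experiments cannot be recomputed
from a desk-scale package, so the method is validated by property studies on
the bundled generators instead: type-I calibration of the null bands, planted
QTL recovery, heritability and diversity-reduction parameter recovery, and
the selfing-series heterozygosity decay.  Each study fixes the experimental
conditions (bulk size 10, ~30x depth, F9 generation) and varies only the
seed; the same routines back both the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np

from . import null_simulation as ns
from . import qtl_calling as qc
from . import qtlseq_core as core
from . import synthetic_data as sd
from .diversity import diversity_ratio, diversity_windows
from .io_formats import ROLE_NAMES
from .phenotype_stats import broad_sense_heritability

ROLES = {r: r for r in ROLE_NAMES}

#: analysis window/step used on the synthetic fixtures: the window is matched
#: to the linkage-decay scale of the bulk signal on a 55-Mb, ~140-cM
#: chromosome (scaled down from the 10-Mb window used on real pseudomolecules)
CALL_WINDOW = 5_000_000
CALL_STEP = 1_000_000

#: tiling used for type-I calibration: independent (non-overlapping) windows
TILE_WINDOW = 2_000_000

BAND_DEPTHS = (10, 20, 30, 50, 75)


def _study_seed(seed: int, i: int) -> int:
    return (seed * 1_000 + i) % 2_147_483_647


def shared_bands(seed: int, n_reps: int = 10_000) -> ns.NullBands:
    return ns.build_null_bands(
        bulk_size=10, generation=9, depths=BAND_DEPTHS, n_reps=n_reps, seed=seed
    )


def _simulate_and_index(cfg: sd.SimConfig, window: int, step: int, bands: ns.NullBands):
    truth = sd.simulate_ril_population(cfg)
    phen = sd.simulate_phenotypes(truth)
    bulks = sd.constitute_bulks(truth, phen)
    table = sd.simulate_bulk_readcounts(truth, bulks)
    records, _ = core.filter_snps(table, ROLES)
    profile = core.sliding_window_profile(records, window, step, cfg.chrom_lengths)
    profile = ns.attach_bands(profile, records, bands)
    return truth, records, profile


def null_calibration_study(seed: int, n_runs: int = 20, n_ril: int = 40) -> dict:
    """Type-I behaviour with no QTL planted.

    Simulates ``n_runs`` bulk experiments on a 4 x 40 Mb genome with no QTL,
    tiles each genome into independent windows and measures (i) the pooled
    fraction of windows whose mean delta exceeds the 99% null band and
    (ii) how many runs yield zero QTL calls at the 99.9% level with the
    default delta > 0.5 and near-fixed-index criteria.
    """
    bands = shared_bands(_study_seed(seed, 999))
    chrom_lengths = {f"chr{i}": 40_000_000 for i in range(1, 5)}
    n_exceed = n_windows = 0
    zero_call_runs = 0
    for i in range(n_runs):
        cfg = sd.SimConfig(
            n_ril=n_ril, chrom_lengths=chrom_lengths, qtls=[], seed=_study_seed(seed, i)
        )
        _, records, profile = _simulate_and_index(cfg, TILE_WINDOW, TILE_WINDOW, bands)
        df = profile.df
        occupied = df["n_snps"].to_numpy() > 0
        exceed = (df["mean_delta"] > df["ci99_high"]) | (df["mean_delta"] < df["ci99_low"])
        n_exceed += int((exceed.to_numpy() & occupied).sum())
        n_windows += int(occupied.sum())
        calls = qc.call_qtls(profile, records, level=99.9)
        zero_call_runs += int(len(calls) == 0)
    return {
        "exceed_fraction": n_exceed / n_windows,
        "n_windows": n_windows,
        "zero_call_runs": zero_call_runs,
        "n_runs": n_runs,
    }


def planted_qtl_recovery_study(
    seed: int, n_runs: int = 20, qtl_pos: int = 27_500_000, effect: float = 15.0
) -> dict:
    """Recovery of a single large-effect QTL from phenotype-selected bulks.

    Plants one QTL on the 55-Mb fixture, selects extreme homozygous bulks,
    calls QTLs at the 99% level and scores a hit when the primary call's
    midpoint lies within one analysis window of the true position.
    """
    bands = shared_bands(_study_seed(seed, 999))
    hits = 0
    offsets = []
    fixed_runs = 0
    for i in range(n_runs):
        cfg = sd.SimConfig(
            n_ril=260, qtls=[("Ca4", qtl_pos, effect)], seed=_study_seed(seed, i)
        )
        truth, records, profile = _simulate_and_index(cfg, CALL_WINDOW, CALL_STEP, bands)
        phen_bulk_fixed = _bulk_fixed_at_qtl(truth)
        fixed_runs += int(phen_bulk_fixed)
        calls = qc.call_qtls(profile, records, level=99.0)
        best = qc.primary_call(calls, profile)
        if best is None:
            offsets.append(float("nan"))
            continue
        mid = (best.start_snp_pos + best.end_snp_pos) / 2.0
        offsets.append((mid - qtl_pos) / 1e6)
        if abs(mid - qtl_pos) <= CALL_WINDOW:
            hits += 1
    return {
        "hits": hits,
        "n_runs": n_runs,
        "hit_rate": hits / n_runs,
        "offsets_mb": offsets,
        "bulk_fixed_runs": fixed_runs,
    }


def _bulk_fixed_at_qtl(truth: sd.TruthSet) -> bool:
    phen = sd.simulate_phenotypes(truth)
    bulks = sd.constitute_bulks(truth, phen)
    p_early, p_late = sd.bulk_allele_frequencies(truth, bulks)
    qi = truth.qtl_marker_idx[0]
    return bool(p_early[qi] == 0.0 and p_late[qi] == 1.0)


def h2_recovery_study(seed: int, n_runs: int = 20, target_h2: float = 0.8) -> dict:
    """Entry-mean heritability recovery from simulated two-env trials."""
    values = []
    for i in range(n_runs):
        cfg = sd.SimConfig(
            n_ril=260, marker_spacing=500_000, h2=target_h2, seed=_study_seed(seed, i)
        )
        truth = sd.simulate_ril_population(cfg)
        phen = sd.simulate_phenotypes(truth)
        values.append(broad_sense_heritability(phen).h2_percent)
    values = np.array(values)
    lo, hi = 100 * target_h2 - 5, 100 * target_h2 + 5
    return {
        "h2_values": values.tolist(),
        "mean_h2": float(values.mean()),
        "n_within_pm5": int(((values >= lo) & (values <= hi)).sum()),
        "n_runs": n_runs,
    }


def diversity_reduction_study(
    seed: int, n_runs: int = 20, reduction: float = 0.9
) -> dict:
    """Recovery of a planted sweep-region diversity reduction."""
    region = (800_001, 1_200_000)
    ratios = []
    for i in range(n_runs):
        cult, wild = sd.simulate_diversity_panel(
            reduction=reduction, sweep_region=region, seed=_study_seed(seed, i)
        )
        ratio, _ = diversity_ratio(
            diversity_windows(cult), diversity_windows(wild), region
        )
        ratios.append(ratio)
    return {
        "ratios_percent": ratios,
        "mean_ratio_percent": float(np.mean(ratios)),
        "n_runs": n_runs,
    }


def het_decay_study(seed: int, n_ril: int = 500, n_loci: int = 1_000) -> dict:
    """Observed residual heterozygosity at F9 against the (1/2)^8 closed form.

    The z-score uses the empirical standard error across individuals (the
    independent sampling unit; loci within an individual are linked).
    """
    spacing = 55_000_000 // n_loci
    cfg = sd.SimConfig(
        n_ril=n_ril,
        marker_spacing=spacing,
        chrom_lengths={"Ca4": spacing * n_loci},
        qtls=[],
        seed=_study_seed(seed, 0),
    )
    truth = sd.simulate_ril_population(cfg)
    per_ind = (truth.genotypes == 1).mean(axis=1)
    obs = float(per_ind.mean())
    exp = sd.expected_het_fraction(cfg.generation)
    se = float(per_ind.std(ddof=1) / np.sqrt(n_ril))
    return {
        "observed": obs,
        "expected": exp,
        "se": se,
        "z": (obs - exp) / se if se > 0 else 0.0,
    }
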
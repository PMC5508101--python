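"""Simulation-based null distribution and confidence bands for delta(SNP-index).

Under the no-QTL null both bulks are random draws of ``bulk_size`` RIL
genotypes; at selfing generation t a locus is heterozygous with probability
h = (1/2)^(t-1) and homozygous for either parent with probability (1-h)/2
each.  The bulk allele frequency is the mean allele dosage / 2 and sequencing
adds binomial read sampling at the given depth.  Empirical two-sided quantiles
of the simulated delta give the 95/99/99.9% bands, tabulated on a depth grid
and interpolated per SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qtlseq_core import WindowProfile, sliding_window_profile

logger = logging.getLogger("mqtlseq")

DEFAULT_DEPTH_GRID = (10, 20, 30, 50, 75, 100, 150)

#: band level (%) -> (low, high) quantiles of the null delta distribution
LEVEL_QUANTILES = {
    95.0: (0.025, 0.975),
    99.0: (0.005, 0.995),
    99.9: (0.0005, 0.9995),
}

_BAND_COLS = [
    "ci95_low",
    "ci95_high",
    "ci99_low",
    "ci99_high",
    "ci999_low",
    "ci999_high",
]


def band_columns(level: float) -> tuple[str, str]:
    tag = {95.0: "ci95", 99.0: "ci99", 99.9: "ci999"}.get(float(level))
    if tag is None:
        raise ValueError(f"unsupported band level {level!r}; use 95, 99 or 99.9")
    return tag + "_low", tag + "_high"


def simulate_null_delta(
    bulk_size: int,
    generation: int,
    depth: int,
    n_reps: int = 10_000,
    seed: int | None = None,
    rng=None,
) -> np.ndarray:
    """Draw an empirical null sample of delta(SNP-index)."""
    if bulk_size < 1 or depth < 1:
        raise ValueError("bulk_size and depth must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    h = 0.5 ** (generation - 1)
    p_geno = [(1 - h) / 2, h, (1 - h) / 2]  # dosage 0 / 1 / 2

    def bulk_freq() -> np.ndarray:
        dosage = rng.choice([0, 1, 2], size=(n_reps, bulk_size), p=p_geno)
        return dosage.mean(axis=1) / 2.0

    idx = []
    for _ in range(2):
        p = bulk_freq()
        reads = rng.binomial(depth, p)
        idx.append(reads / depth)
    return idx[0] - idx[1]


@dataclass
class NullBands:
    """Per-depth table of two-sided null quantiles of delta(SNP-index)."""

    table: pd.DataFrame  # index: depth; columns: _BAND_COLS
    n_reps: int
    bulk_size: int
    generation: int
    seed: int

    def bounds_at_depth(self, depths: np.ndarray, level: float) -> tuple[np.ndarray, np.ndarray]:
        """Linearly interpolate band bounds at arbitrary depths.

        Depths outside the simulated grid are clamped to the nearest grid
        value (with a warning below the grid: extrapolation is refused).
        """
        lo_col, hi_col = band_columns(level)
        grid = self.table.index.to_numpy(dtype=float)
        depths = np.asarray(depths, dtype=float)
        if (depths < grid[0]).any():
            logger.warning(
                "%d SNP depths below the simulated grid minimum %g; using nearest band",
                int((depths < grid[0]).sum()),
                grid[0],
            )
        lo = np.interp(depths, grid, self.table[lo_col].to_numpy())
        hi = np.interp(depths, grid, self.table[hi_col].to_numpy())
        return lo, hi

    def to_tsv(self, path: str) -> None:
        out = self.table.copy()
        out.insert(0, "depth", out.index)
        header = (
            f"# n_reps={self.n_reps} bulk_size={self.bulk_size} "
            f"generation={self.generation} seed={self.seed}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            out.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "NullBands":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
            table = pd.read_csv(fh, sep="\t").set_index("depth")
        return cls(
            table,
            n_reps=int(meta["n_reps"]),
            bulk_size=int(meta["bulk_size"]),
            generation=int(meta["generation"]),
            seed=int(meta["seed"]),
        )


def build_null_bands(
    bulk_size: int = 10,
    generation: int = 9,
    depths: tuple[int, ...] = DEFAULT_DEPTH_GRID,
    n_reps: int = 10_000,
    seed: int = 7,
) -> NullBands:
    """Tabulate null delta(SNP-index) quantiles over a depth grid."""
    rows = {}
    for k, depth in enumerate(sorted(depths)):
        rng = np.random.default_rng(seed + 1000 * k)
        delta = simulate_null_delta(bulk_size, generation, depth, n_reps, rng=rng)
        row = {}
        for level, (qlo, qhi) in LEVEL_QUANTILES.items():
            lo_col, hi_col = band_columns(level)
            row[lo_col] = float(np.quantile(delta, qlo))
            row[hi_col] = float(np.quantile(delta, qhi))
        rows[depth] = row
    table = pd.DataFrame.from_dict(rows, orient="index")[_BAND_COLS]
    table.index.name = "depth"
    return NullBands(table, n_reps, bulk_size, generation, seed)


def attach_bands(
    profile: WindowProfile, records: pd.DataFrame, bands: NullBands
) -> WindowProfile:
    """Attach per-window confidence-band columns to a window profile.

    Each SNP's bounds are looked up at its min bulk depth; the window bound is
    the unweighted mean of member-SNP bounds, mirroring how the window delta
    is the mean of member-SNP deltas.
    """
    rec = records.copy()
    band_cols = []
    for level in LEVEL_QUANTILES:
        lo_col, hi_col = band_columns(level)
        lo, hi = bands.bounds_at_depth(rec["min_bulk_depth"].to_numpy(), level)
        rec[lo_col] = lo
        rec[hi_col] = hi
        band_cols += [lo_col, hi_col]
    band_profile = sliding_window_profile(
        rec,
        profile.window,
        profile.step,
        profile.chrom_lengths,
        value_cols=tuple(band_cols),
    )
    df = profile.df.copy()
    for col in band_cols:
        df[col] = band_profile.df["mean_" + col].to_numpy()
    return WindowProfile(df, profile.window, profile.step, dict(profile.chrom_lengths))
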
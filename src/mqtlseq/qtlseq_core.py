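"""SNP-index and delta(SNP-index) computation, filtering and window smoothing.

The SNP-index of a bulk at a SNP is the fraction of reads carrying the allele
that differs from the reference (early-parent) assembly:
``index = depth_alt / (depth_ref + depth_alt)``.  delta(SNP-index) is the
difference of the two bulk indices; by default ``early - late``, with the
orientation exposed because either polarity is a valid reading of the bulk
labels relative to the reference parent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AlleleCountTable, check_roles

logger = logging.getLogger("mqtlseq")


def snp_index(depth_ref, depth_alt):
    """Fraction of reads differing from the reference: alt / (ref + alt)."""
    depth_ref = np.asarray(depth_ref, dtype=float)
    depth_alt = np.asarray(depth_alt, dtype=float)
    total = depth_ref + depth_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, depth_alt / total, np.nan)
    return out if out.ndim else float(out)


def delta_snp_index(index_early, index_late, orientation: str = "early_minus_late"):
    """delta(SNP-index): difference of bulk SNP-indices (sign configurable)."""
    if orientation == "early_minus_late":
        return np.asarray(index_early) - np.asarray(index_late)
    if orientation == "late_minus_early":
        return np.asarray(index_late) - np.asarray(index_early)
    raise ValueError(f"unknown orientation {orientation!r}")


def compute_snp_indices(
    table: AlleleCountTable, roles: dict, orientation: str = "early_minus_late"
) -> pd.DataFrame:
    """Per-SNP index table for both bulks and parents.

    Returns a DataFrame with chrom, pos, per-role SNP-index, bulk depths and
    ``delta``; rows where either bulk has zero depth get NaN indices.
    """
    roles = check_roles(roles)
    df = table.df
    out = pd.DataFrame({"chrom": df["chrom"], "pos": df["pos"], "mean_bq": df["mean_bq"]})
    for role, sample in roles.items():
        ref = df[sample + "_ref"].to_numpy()
        alt = df[sample + "_alt"].to_numpy()
        out["index_" + role] = snp_index(ref, alt)
        out["depth_" + role] = ref + alt
    out["delta"] = delta_snp_index(
        out["index_bulk_early"], out["index_bulk_late"], orientation
    )
    out["min_bulk_depth"] = np.minimum(out["depth_bulk_early"], out["depth_bulk_late"])
    return out


def filter_snps(
    table: AlleleCountTable,
    roles: dict,
    min_depth: int = 10,
    min_bq: float = 20.0,
    low_index_floor: float | None = 0.3,
    require_differentiated_parents: bool = True,
    orientation: str = "early_minus_late",
) -> tuple[pd.DataFrame, dict]:
    """Apply the QTL-seq SNP filters and return (records, removal counts).

    Keeps SNPs with total depth >= ``min_depth`` in both bulks, mean base
    quality >= ``min_bq``, parents homozygous for opposite alleles (indices
    rounding to 0 and 1 at the 0.1/0.9 cutoffs), and not below
    ``low_index_floor`` in both bulks (a guard against systematic
    alignment/call errors; pass None to disable).
    """
    rec = compute_snp_indices(table, roles, orientation)
    counts = {"input": len(rec)}
    keep = np.ones(len(rec), dtype=bool)

    m = (rec["depth_bulk_early"] >= min_depth) & (rec["depth_bulk_late"] >= min_depth)
    m &= (rec["depth_parent_early"] > 0) & (rec["depth_parent_late"] > 0)
    counts["depth"] = int((~m & keep).sum())
    keep &= m.to_numpy()

    m = rec["mean_bq"] >= min_bq
    counts["base_quality"] = int((~m & keep).sum())
    keep &= m.to_numpy()

    if require_differentiated_parents:
        pe, pl = rec["index_parent_early"], rec["index_parent_late"]
        m = ((pe <= 0.1) & (pl >= 0.9)) | ((pe >= 0.9) & (pl <= 0.1))
        m &= pe.notna() & pl.notna()
        counts["parent_homozygosity"] = int((~m & keep).sum())
        keep &= m.to_numpy()

    if low_index_floor is not None:
        m = ~(
            (rec["index_bulk_early"] < low_index_floor)
            & (rec["index_bulk_late"] < low_index_floor)
        )
        counts["low_index_floor"] = int((~m & keep).sum())
        keep &= m.to_numpy()

    counts["kept"] = int(keep.sum())
    if counts["kept"] == 0:
        logger.warning("all %d SNPs removed by filters", counts["input"])
    return rec.loc[keep].reset_index(drop=True), counts


# ---------------------------------------------------------------------------
# Sliding windows


@dataclass
class WindowProfile:
    """Ordered sliding windows of per-SNP means.

    ``df`` columns: chrom, start, end (1-based inclusive), n_snps, partial,
    mean_index_early, mean_index_late, mean_delta (NaN where n_snps == 0),
    plus any confidence-band columns attached later.
    """

    df: pd.DataFrame
    window: int
    step: int
    chrom_lengths: dict[str, int] = field(default_factory=dict)


_DEFAULT_VALUE_COLS = ("index_bulk_early", "index_bulk_late", "delta")
_PROFILE_NAMES = {
    "index_bulk_early": "mean_index_early",
    "index_bulk_late": "mean_index_late",
    "delta": "mean_delta",
}


def _window_starts(chrom_length: int, window: int, step: int) -> tuple[np.ndarray, int]:
    """Anchored window starts 1, 1+s, ... <= L - W + 1, plus one trailing
    partial start when the tiling does not reach the chromosome end."""
    if window > chrom_length:
        logger.warning("window %d exceeds chromosome length %d; clamping", window, chrom_length)
        return np.array([1], dtype=np.int64), chrom_length
    last_full = chrom_length - window + 1
    starts = np.arange(1, last_full + 1, step, dtype=np.int64)
    if starts[-1] + step <= chrom_length:
        starts = np.append(starts, starts[-1] + step)  # trailing partial window
    return starts, window


def sliding_window_profile(
    records: pd.DataFrame,
    window: int,
    step: int,
    chrom_lengths: dict[str, int],
    value_cols: tuple[str, ...] = _DEFAULT_VALUE_COLS,
) -> WindowProfile:
    """Unweighted window means of per-SNP values over an anchored tiling.

    Windows are [a, a+W-1] for a = 1, 1+s, 1+2s, ...; a SNP belongs to every
    window whose span contains its position.  Windows with no SNPs carry
    n_snps = 0 and NaN means.  A final partial window (flagged) is kept when
    it contains at least one SNP.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    frames = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        sub = records[records["chrom"] == chrom].sort_values("pos")
        pos = sub["pos"].to_numpy()
        starts, w_eff = _window_starts(length, window, step)
        ends = np.minimum(starts + w_eff - 1, length)
        partial = ends - starts + 1 < w_eff
        i = np.searchsorted(pos, starts, side="left")
        j = np.searchsorted(pos, ends, side="right")
        n = (j - i).astype(np.int64)
        cols = {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "n_snps": n,
            "partial": partial,
        }
        for col in value_cols:
            vals = sub[col].to_numpy(dtype=float)
            cs = np.concatenate([[0.0], np.nancumsum(vals)])
            sums = cs[j] - cs[i]
            with np.errstate(invalid="ignore", divide="ignore"):
                means = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
            cols[_PROFILE_NAMES.get(col, "mean_" + col)] = means
        frame = pd.DataFrame(cols)
        frame = frame[(~frame["partial"]) | (frame["n_snps"] > 0)]
        frames.append(frame)
    df = pd.concat(frames, ignore_index=True)
    return WindowProfile(df, window, step, dict(chrom_lengths))


# ---------------------------------------------------------------------------
# Genome-summary arithmetic (map densities, per-chromosome shares)


def map_density_kb(span_bp: float, n_snps: int) -> float:
    """Average inter-SNP spacing in kb, to two decimals: span / n / 1000."""
    if n_snps <= 0:
        raise ValueError("n_snps must be positive")
    return round(span_bp / n_snps / 1000.0, 2)


def chromosome_share_percent(n_chrom_snps: int, n_total_snps: int) -> float:
    """Percentage of all SNPs mapped to one chromosome, to one decimal."""
    if n_total_snps <= 0:
        raise ValueError("n_total_snps must be positive")
    return round(100.0 * n_chrom_snps / n_total_snps, 1)
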
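"""Calling major QTL intervals from banded window profiles, intersecting calls
across populations that share a parent (the multiple-QTL-seq step), and
delineating peak candidate SNPs/genes inside consensus intervals.

A window is QTL-supporting when its mean delta(SNP-index) lies outside the
simulated null band at the chosen significance level, exceeds ``min_delta`` in
magnitude, and the two bulk SNP-index means are near-fixed in opposite
directions (high bulk >= ``high_min``, low bulk <= ``low_max``).  Maximal runs
of at least ``min_windows`` consecutive supporting windows with a consistent
delta sign become intervals, with endpoints snapped to the outermost SNPs of
the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneModel, QtlInterval
from .null_simulation import band_columns
from .qtlseq_core import WindowProfile

logger = logging.getLogger("mqtlseq")


@dataclass
class ConsensusInterval:
    """Overlap of one QTL call from each of two populations."""

    chrom: str
    start: int
    end: int
    sources: list[QtlInterval] = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def interval_length(start_pos: int, end_pos: int, unit: str = "bp") -> float:
    """Interval span ``end - start`` in bp, kb (one decimal) or Mb (two)."""
    if start_pos >= end_pos:
        raise ValueError("start must be < end")
    bp = end_pos - start_pos
    if unit == "bp":
        return bp
    if unit == "kb":
        return round(bp / 1e3, 1)
    if unit == "Mb":
        return round(bp / 1e6, 2)
    raise ValueError(f"unknown unit {unit!r}")


def window_passes(
    profile_df: pd.DataFrame,
    level: float = 99.0,
    min_delta: float = 0.5,
    high_min: float = 0.8,
    low_max: float = 0.2,
) -> np.ndarray:
    """Vector of booleans: does each window satisfy the calling predicate?"""
    lo_col, hi_col = band_columns(level)
    d = profile_df["mean_delta"].to_numpy()
    outside = (d > profile_df[hi_col].to_numpy()) | (d < profile_df[lo_col].to_numpy())
    e = profile_df["mean_index_early"].to_numpy()
    l = profile_df["mean_index_late"].to_numpy()
    high = np.maximum(e, l)
    low = np.minimum(e, l)
    return (
        (profile_df["n_snps"].to_numpy() > 0)
        & outside
        & (np.abs(d) > min_delta)
        & (high >= high_min)
        & (low <= low_max)
    )


def call_qtls(
    profile: WindowProfile,
    records: pd.DataFrame,
    level: float = 99.0,
    min_delta: float = 0.5,
    high_min: float = 0.8,
    low_max: float = 0.2,
    min_windows: int = 2,
    population: str = "NA",
) -> list[QtlInterval]:
    """Call maximal significant runs of windows as QTL intervals."""
    df = profile.df
    if (df["n_snps"] > 0).sum() == 0:
        logger.warning("no windows contain SNPs; returning no calls")
        return []
    passes = window_passes(df, level, min_delta, high_min, low_max)
    sign = np.sign(np.nan_to_num(df["mean_delta"].to_numpy()))
    intervals: list[QtlInterval] = []
    for chrom in df["chrom"].unique():
        cmask = (df["chrom"] == chrom).to_numpy()
        cdf = df[cmask].reset_index(drop=True)
        cpass = passes[cmask]
        csign = sign[cmask]
        runs = _runs(cpass, csign)
        sub = records[records["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        delta = sub["delta"].to_numpy(dtype=float)
        ie = sub["index_bulk_early"].to_numpy(dtype=float)
        il = sub["index_bulk_late"].to_numpy(dtype=float)
        for a, b in runs:
            if b - a + 1 < min_windows:
                continue
            span_start = int(cdf.loc[a, "start"])
            span_end = int(cdf.loc[b, "end"])
            inside = (pos >= span_start) & (pos <= span_end)
            if not inside.any():
                continue
            p = pos[inside]
            d = delta[inside]
            peak = float(d[np.argmax(np.abs(d))])
            intervals.append(
                QtlInterval(
                    chrom=str(chrom),
                    start_snp_pos=int(p.min()),
                    end_snp_pos=int(p.max()),
                    peak_delta=peak,
                    mean_index_early=float(np.mean(ie[inside])),
                    mean_index_late=float(np.mean(il[inside])),
                    population=population,
                    level=level,
                )
            )
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start_snp_pos))


def _runs(passes: np.ndarray, sign: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive True entries with constant sign."""
    runs = []
    start = None
    for i in range(passes.size):
        if passes[i] and (start is None or sign[i] == sign[i - 1]):
            if start is None:
                start = i
        else:
            if start is not None:
                runs.append((start, i - 1))
            start = i if passes[i] else None
    if start is not None:
        runs.append((start, passes.size - 1))
    return runs


def primary_call(
    calls: list[QtlInterval], profile: WindowProfile
) -> QtlInterval | None:
    """The call containing (or nearest to) the genome-wide peak window.

    When several intervals are called, the major QTL is taken to be the one
    harbouring the window of maximal |mean delta|.
    """
    if not calls:
        return None
    df = profile.df
    peak = df.loc[df["mean_delta"].abs().idxmax()]
    center = (peak["start"] + peak["end"]) / 2.0

    def dist(iv: QtlInterval) -> float:
        if iv.chrom != peak["chrom"]:
            return float("inf")
        if iv.start_snp_pos <= center <= iv.end_snp_pos:
            return 0.0
        return min(abs(iv.start_snp_pos - center), abs(iv.end_snp_pos - center))

    return min(calls, key=dist)


def intersect_qtls(
    calls_a: list[QtlInterval], calls_b: list[QtlInterval]
) -> tuple[list[ConsensusInterval], list[QtlInterval]]:
    """Intersect QTL calls from two populations sharing a parent.

    For each pair of overlapping intervals on the same chromosome with the
    same delta sign, the consensus is [max(starts), min(ends)].  Calls that
    overlap nothing in the other population are returned as
    population-specific.  Both outputs are sorted by (chrom, start).
    """
    consensus: list[ConsensusInterval] = []
    matched_a, matched_b = set(), set()
    for i, a in enumerate(calls_a):
        for j, b in enumerate(calls_b):
            if a.chrom != b.chrom:
                continue
            if np.sign(a.peak_delta) != np.sign(b.peak_delta):
                continue
            start = max(a.start_snp_pos, b.start_snp_pos)
            end = min(a.end_snp_pos, b.end_snp_pos)
            if start < end:
                consensus.append(ConsensusInterval(a.chrom, start, end, [a, b]))
                matched_a.add(i)
                matched_b.add(j)
    specific = [iv for i, iv in enumerate(calls_a) if i not in matched_a]
    specific += [iv for j, iv in enumerate(calls_b) if j not in matched_b]
    consensus.sort(key=lambda c: (c.chrom, c.start))
    specific.sort(key=lambda c: (c.chrom, c.start_snp_pos))
    return consensus, specific


def delineate_candidates(
    consensus: ConsensusInterval,
    snp_records: pd.DataFrame,
    gene_models: list[GeneModel],
    top_delta_tol: float = 0.0,
    urr_len: int = 2000,
    drr_len: int = 2000,
) -> tuple[pd.DataFrame, list[tuple[str, int]]]:
    """Peak-delta candidate SNPs and genes inside a consensus interval.

    Returns (candidate SNP table with location category and gene, genes
    ranked by their count of maximal-delta SNPs, ties broken by proximity to
    the delta peak).
    """
    from .variant_annotation import classify_location

    sub = snp_records[
        (snp_records["chrom"] == consensus.chrom)
        & (snp_records["pos"] >= consensus.start)
        & (snp_records["pos"] <= consensus.end)
    ].copy()
    if sub.empty:
        raise ValueError("consensus interval contains no SNPs")
    absd = sub["delta"].abs()
    peak = absd.max()
    cand = sub[absd >= peak - top_delta_tol].copy()
    peak_pos = int(sub.loc[absd.idxmax(), "pos"])

    genes_on_chrom = [g for g in gene_models if g.chrom == consensus.chrom]
    cats, gene_ids = [], []
    for pos in cand["pos"]:
        cat, gid = classify_location(int(pos), genes_on_chrom, urr_len, drr_len)
        cats.append(cat)
        gene_ids.append(gid)
    cand["category"] = cats
    cand["gene_id"] = gene_ids

    counts: dict[str, int] = {}
    for gid in gene_ids:
        if gid is not None:
            counts[gid] = counts.get(gid, 0) + 1
    gene_pos = {g.gene_id: (g.start + g.end) // 2 for g in genes_on_chrom}
    ranked = sorted(
        counts.items(),
        key=lambda kv: (-kv[1], abs(gene_pos.get(kv[0], peak_pos) - peak_pos), kv[0]),
    )
    return cand.reset_index(drop=True), ranked
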
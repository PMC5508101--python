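"""Windowed nucleotide diversity (theta-pi), Watterson's theta, Tajima's D,
cultivated/wild diversity-reduction ratios, and a simple single-marker
variance-explained utility.

Panels of inbred accessions are represented as haplotype matrices: a 0/2
genotype dosage expands to two identical haplotypes, a residual heterozygote
(dosage 1) to one reference plus one alternate haplotype.

Per site with alt frequency p among n haplotypes,
``pi_site = (n / (n - 1)) * 2 * p * (1 - p)`` — the unbiased mean pairwise
difference; window pi is the sum over sites.  Tajima's D uses the standard
constants a1, a2, b1, b2, c1, c2, e1, e2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class HaplotypeMatrix:
    """Samples-by-sites 0/1 haplotype matrix with 1-based site positions."""

    matrix: np.ndarray
    positions: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    label: str = ""
    chrom: str = "chr"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.positions.size:
            raise ValueError("matrix shape does not match positions")
        if self.matrix.shape[0] < 2:
            raise ValueError("need at least two haplotypes")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_genotypes(
        cls, dosage: np.ndarray, positions, sample_ids=None, label: str = "", chrom: str = "chr"
    ) -> "HaplotypeMatrix":
        """Expand 0/1/2 genotype dosages of inbred accessions to haplotypes."""
        dosage = np.asarray(dosage)
        h1 = (dosage >= 1).astype(np.int8)
        h2 = (dosage == 2).astype(np.int8)
        matrix = np.empty((2 * dosage.shape[0], dosage.shape[1]), dtype=np.int8)
        matrix[0::2] = h1
        matrix[1::2] = h2
        ids = sample_ids or [f"S{i}" for i in range(dosage.shape[0])]
        hap_ids = [f"{s}_{a}" for s in ids for a in (1, 2)]
        return cls(matrix, positions, hap_ids, label, chrom)


def _site_pi(matrix: np.ndarray) -> np.ndarray:
    n = matrix.shape[0]
    p = matrix.mean(axis=0)
    return (n / (n - 1.0)) * 2.0 * p * (1.0 - p)


def tajima_constants(n: int) -> dict[str, float]:
    """The standard Tajima's D normalisation constants for n haplotypes."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def theta_pi(matrix: HaplotypeMatrix, window: tuple[int, int] | None = None) -> float:
    """Sum over sites in the window of unbiased per-site pi."""
    m = _slice(matrix, window)
    if m.shape[1] == 0:
        return 0.0
    return float(_site_pi(m).sum())


def watterson_theta(matrix: HaplotypeMatrix, window: tuple[int, int] | None = None) -> float:
    m = _slice(matrix, window)
    s = int(_segregating(m).sum())
    return s / tajima_constants(m.shape[0])["a1"]


def tajimas_d(matrix: HaplotypeMatrix, window: tuple[int, int] | None = None) -> float:
    """Tajima's D over the window; NaN when no site segregates."""
    m = _slice(matrix, window)
    n = m.shape[0]
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 haplotypes")
    seg = _segregating(m)
    s = int(seg.sum())
    if s == 0:
        return float("nan")
    c = tajima_constants(n)
    pi = float(_site_pi(m).sum())
    var = c["e1"] * s + c["e2"] * s * (s - 1)
    if var <= 0:
        raise ValueError("non-positive variance term in Tajima's D")
    return (pi - s / c["a1"]) / np.sqrt(var)


def _segregating(m: np.ndarray) -> np.ndarray:
    p = m.mean(axis=0)
    return (p > 0) & (p < 1)


def _slice(matrix: HaplotypeMatrix, window: tuple[int, int] | None) -> np.ndarray:
    if window is None:
        return matrix.matrix
    lo, hi = window
    mask = (matrix.positions >= lo) & (matrix.positions <= hi)
    return matrix.matrix[:, mask]


def diversity_windows(matrix: HaplotypeMatrix, window_size: int = 100_000) -> pd.DataFrame:
    """Non-overlapping windowed pi, Watterson's theta and Tajima's D.

    Windows are anchored at position 1; per-site means divide by the number
    of assayed sites in the window so windows of unequal site count remain
    comparable.
    """
    last = int(matrix.positions.max())
    starts = np.arange(1, last + 1, window_size, dtype=np.int64)
    rows = []
    for a in starts:
        b = a + window_size - 1
        m = _slice(matrix, (a, b))
        n_sites = m.shape[1]
        s = int(_segregating(m).sum()) if n_sites else 0
        pi = float(_site_pi(m).sum()) if n_sites else 0.0
        theta_w = s / tajima_constants(matrix.n_haplotypes)["a1"] if n_sites else 0.0
        if s > 0:
            d = tajimas_d(matrix, (a, b))
        else:
            d = float("nan")
        rows.append(
            {
                "chrom": matrix.chrom,
                "start": int(a),
                "end": int(b),
                "n_sites": n_sites,
                "S": s,
                "theta_pi": pi,
                "theta_pi_per_site": pi / n_sites if n_sites else float("nan"),
                "theta_w": theta_w,
                "tajima_d": d,
            }
        )
    return pd.DataFrame(rows)


def diversity_ratio(
    windows_cultivated: pd.DataFrame,
    windows_wild: pd.DataFrame,
    region: tuple[int, int] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Cultivated/wild diversity ratio over a region, as a percentage.

    Ratio = 100 * (sum of cultivated window pi) / (sum of wild window pi),
    restricted to windows overlapping ``region`` when given.  Also returns
    per-window ratios.
    """
    wc, ww = windows_cultivated, windows_wild
    if region is not None:
        lo, hi = region
        keep_c = (wc["end"] >= lo) & (wc["start"] <= hi)
        keep_w = (ww["end"] >= lo) & (ww["start"] <= hi)
        wc, ww = wc[keep_c], ww[keep_w]
    total_w = float(ww["theta_pi"].sum())
    if total_w == 0:
        raise ValueError("wild diversity is zero in the region; ratio undefined")
    ratio = round(100.0 * float(wc["theta_pi"].sum()) / total_w, 1)
    merged = wc.merge(ww, on=["chrom", "start", "end"], suffixes=("_c", "_w"))
    with np.errstate(invalid="ignore", divide="ignore"):
        merged["ratio_percent"] = 100.0 * merged["theta_pi_c"] / merged["theta_pi_w"]
    per_window = merged[["chrom", "start", "end", "ratio_percent"]]
    return ratio, per_window


def single_marker_pve(genotypes, phenotypes) -> float:
    """Percent phenotypic variance explained by genotype-class means (R^2).

    A deliberately simple one-way fixed-effects fit (no kinship or structure
    covariates); a quick screen, not an association test.
    """
    g = np.asarray(genotypes)
    y = np.asarray(phenotypes, dtype=float)
    if g.size != y.size or g.size < 3:
        raise ValueError("need matched genotype/phenotype vectors, n >= 3")
    classes = np.unique(g)
    if classes.size < 2:
        raise ValueError("monomorphic marker")
    grand = y.mean()
    ss_tot = float(((y - grand) ** 2).sum())
    ss_between = 0.0
    for c in classes:
        yc = y[g == c]
        ss_between += yc.size * (yc.mean() - grand) ** 2
    return 100.0 * ss_between / ss_tot
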
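"""Marey maps and local recombination-rate landscapes.

A Marey map plots genetic position (cM) against physical position (Mb).
Loci breaking joint monotonicity are pruned by keeping a maximum-cardinality
subset whose cM sequence is non-decreasing when ordered by Mb (longest
non-decreasing subsequence); unanchored loci are dropped with a reason.
The retained points are interpolated with a monotone piecewise-cubic
(PCHIP / Fritsch-Carlson) fit whose derivative gives the local rate in
cM/Mb.  Chromosome and genome-wide averages use coordinate spans:
chromosome = cM span / Mb span of mapped loci, genome-wide = sum of cM
spans / sum of Mb spans.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator

from .io import MarkerLocus
from .distortion import DistortionResult


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (so 7.875 -> 7.9), as in reported tables."""
    f = 10.0 ** decimals
    return float(np.floor(np.abs(x) * f + 0.5) / f * np.sign(x)) if x else 0.0


@dataclass
class MareyMap:
    chromosome: str
    points_Mb: np.ndarray
    points_cM: np.ndarray
    excluded_loci: list[tuple[str, str]] = field(default_factory=list)  # (marker_id, reason)

    @property
    def n_points(self) -> int:
        return int(self.points_Mb.size)

    @property
    def cM_span(self) -> float:
        return float(self.points_cM[-1] - self.points_cM[0])

    @property
    def Mb_span(self) -> float:
        return float(self.points_Mb[-1] - self.points_Mb[0])


@dataclass
class RateProfile:
    chromosome: str
    grid_Mb: np.ndarray
    fitted_cM: np.ndarray
    local_rate: np.ndarray
    chromosome_avg: float


@dataclass
class RateDistortionRegression:
    chromosome: str
    n: int
    r_squared: Optional[float]
    p_value: Optional[float]
    slope_sign: int
    note: str = ""


# ---------------------------------------------------------------------------
# outlier filtering
# ---------------------------------------------------------------------------

def _longest_nondecreasing(values: Sequence[float]) -> list[int]:
    """Indices of a longest non-decreasing subsequence (earliest on ties)."""
    tails: list[float] = []  # tails[k] = smallest possible tail of a (k+1)-length run
    tail_idx: list[int] = []
    prev = [-1] * len(values)
    for i, v in enumerate(values):
        k = bisect.bisect_right(tails, v)
        if k == len(tails):
            tails.append(v)
            tail_idx.append(i)
        else:
            tails[k] = v
            tail_idx[k] = i
        prev[i] = tail_idx[k - 1] if k > 0 else -1
    out = []
    i = tail_idx[-1] if tail_idx else -1
    while i >= 0:
        out.append(i)
        i = prev[i]
    return out[::-1]


def filter_marey_outliers(loci: Sequence[MarkerLocus]) -> MareyMap:
    """Prune one chromosome's loci to a monotone Marey point set."""
    chroms = {l.chromosome for l in loci}
    if len(chroms) != 1:
        raise ValueError(f"loci span several chromosomes: {sorted(chroms)}")
    chrom = chroms.pop()

    excluded = [(l.marker_id, "unanchored") for l in loci if l.physical_pos is None]
    anchored = [l for l in loci if l.physical_pos is not None]
    if len(anchored) < 2:
        raise ValueError(f"{chrom}: fewer than 2 anchored loci")
    anchored.sort(key=lambda l: (l.physical_pos, l.genetic_pos, l.marker_id))
    cms = [l.genetic_pos for l in anchored]
    keep = set(_longest_nondecreasing(cms))
    excluded += [
        (anchored[i].marker_id, "non-monotone") for i in range(len(anchored)) if i not in keep
    ]
    kept = [anchored[i] for i in sorted(keep)]
    return MareyMap(
        chromosome=chrom,
        points_Mb=np.array([l.physical_pos for l in kept]),
        points_cM=np.array([l.genetic_pos for l in kept]),
        excluded_loci=excluded,
    )


# ---------------------------------------------------------------------------
# monotone interpolation and rates
# ---------------------------------------------------------------------------

def fit_monotone_interpolant(m: MareyMap) -> PchipInterpolator:
    """Monotone C1 piecewise-cubic through the Marey points.

    Duplicate Mb positions are collapsed to their mean cM with a warning.
    """
    mb, cm = m.points_Mb, m.points_cM
    uniq, inverse, counts = np.unique(mb, return_inverse=True, return_counts=True)
    if np.any(counts > 1):
        warnings.warn(f"{m.chromosome}: duplicate Mb positions collapsed to mean cM")
        cm = np.array([cm[inverse == i].mean() for i in range(uniq.size)])
        mb = uniq
    if mb.size < 2:
        raise ValueError(f"{m.chromosome}: need >= 2 distinct Mb positions")
    return PchipInterpolator(mb, cm)


def local_rates(
    interpolant: PchipInterpolator,
    grid_Mb: np.ndarray,
    chromosome: str = "",
) -> RateProfile:
    """Derivative of the fitted curve on a grid, clamped at 0."""
    grid_Mb = np.asarray(grid_Mb, dtype=float)
    fitted = interpolant(grid_Mb)
    rate = np.maximum(interpolant.derivative()(grid_Mb), 0.0)
    lo, hi = interpolant.x[0], interpolant.x[-1]
    span_Mb = hi - lo
    avg = float((interpolant(hi) - interpolant(lo)) / span_Mb) if span_Mb > 0 else float("nan")
    return RateProfile(
        chromosome=chromosome,
        grid_Mb=grid_Mb,
        fitted_cM=np.asarray(fitted, dtype=float),
        local_rate=np.asarray(rate, dtype=float),
        chromosome_avg=avg,
    )


def default_grid(m: MareyMap, spacing_Mb: float = 0.5) -> np.ndarray:
    lo, hi = float(m.points_Mb[0]), float(m.points_Mb[-1])
    grid = np.arange(lo, hi, spacing_Mb)
    return np.append(grid, hi)


def average_rates(spans: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Average cM/Mb per chromosome and genome-wide from coordinate spans.

    ``spans`` maps chromosome -> (cM span, Mb span of mapped loci).  The
    genome-wide average is total cM over total Mb.  A ``rounded`` column
    gives the one-decimal value used in reports.
    """
    if not spans:
        raise ValueError("no chromosomes")
    rows = []
    for chrom, (cm, mb) in spans.items():
        if mb <= 0:
            raise ValueError(f"{chrom}: zero or negative Mb span")
        rows.append({"chromosome": chrom, "cM": cm, "Mb": mb, "rate_cM_per_Mb": cm / mb})
    total_cm = sum(v[0] for v in spans.values())
    total_mb = sum(v[1] for v in spans.values())
    rows.append(
        {
            "chromosome": "genome-wide",
            "cM": total_cm,
            "Mb": total_mb,
            "rate_cM_per_Mb": total_cm / total_mb,
        }
    )
    df = pd.DataFrame(rows)
    df["rounded"] = [round_half_up(v, 1) for v in df["rate_cM_per_Mb"]]
    return df


def spans_from_loci(loci: Sequence[MarkerLocus]) -> dict[str, tuple[float, float]]:
    """(cM span, Mb span) of mapped anchored loci per chromosome."""
    spans: dict[str, tuple[float, float]] = {}
    by_chrom: dict[str, list[MarkerLocus]] = {}
    for l in loci:
        if l.physical_pos is not None:
            by_chrom.setdefault(l.chromosome, []).append(l)
    for chrom, ls in by_chrom.items():
        cms = [l.genetic_pos for l in ls]
        mbs = [l.physical_pos for l in ls]
        spans[chrom] = (max(cms) - min(cms), max(mbs) - min(mbs))
    return spans


# ---------------------------------------------------------------------------
# rate vs distortion regression
# ---------------------------------------------------------------------------

def rate_vs_distortion(
    interpolant: PchipInterpolator,
    results: Sequence[DistortionResult],
    chromosome: str = "",
) -> RateDistortionRegression:
    """OLS of -log10(p) on the local recombination rate at each locus."""
    anchored = [r for r in results if r.locus.physical_pos is not None]
    if len(anchored) < 3:
        return RateDistortionRegression(chromosome, len(anchored), None, None, 0, "n < 3")
    mb = np.array([r.locus.physical_pos for r in anchored])
    rate = np.maximum(interpolant.derivative()(mb), 0.0)
    nlp = np.array([r.neg_log10_p for r in anchored])
    if np.allclose(rate, rate[0]):
        return RateDistortionRegression(
            chromosome, len(anchored), 0.0, None, 0, "constant rate: r^2 undefined, reported 0"
        )
    fit = stats.linregress(rate, nlp)
    return RateDistortionRegression(
        chromosome=chromosome,
        n=len(anchored),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        slope_sign=int(np.sign(fit.slope)),
    )
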
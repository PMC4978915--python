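"""Per-locus chi-square tests of 1:1 and 1:2:1 segregation.

Counts are ordered (homozygous, heterozygous) for 1:1 loci and
(hh, hk, kk) for 1:2:1 loci.  Tests are plain Pearson chi-square with no
continuity correction; df = classes - 1.  The distortion ratio is
larger/smaller over the two classes of a 1:1 locus and over the two
homozygous classes of a 1:2:1 locus (heterozygotes are origin-ambiguous).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import BIPARENTAL, LEGAL_CODES, MISSING, GenotypeMatrix, MarkerLocus

RATIO_1TO1 = (1, 1)
RATIO_1TO2TO1 = (1, 2, 1)


@dataclass
class DistortionConfig:
    alpha_levels: tuple[float, ...] = (0.05, 0.01, 0.001, 0.00001)
    ratio_threshold_1to1: float = 10.0
    ratio_threshold_1to2to1: tuple[float, float] = (5.0, 5.0)

    def __post_init__(self) -> None:
        if list(self.alpha_levels) != sorted(self.alpha_levels, reverse=True):
            raise ValueError("alpha_levels must be strictly decreasing")
        if len(set(self.alpha_levels)) != len(self.alpha_levels):
            raise ValueError("alpha_levels must be strictly decreasing")
        if self.ratio_threshold_1to1 <= 1 or min(self.ratio_threshold_1to2to1) <= 1:
            raise ValueError("ratio thresholds must exceed 1")


@dataclass
class DistortionResult:
    locus: MarkerLocus
    observed_counts: tuple[int, ...]
    expected_ratio: tuple[int, ...]
    chi2: float
    df: int
    p_value: float
    neg_log10_p: float
    distortion_ratio: float
    favored_class: str
    significance_level: Optional[float]

    @property
    def n(self) -> int:
        return int(sum(self.observed_counts))


def _expected(counts: Sequence[float], ratio: Sequence[int]) -> np.ndarray:
    n = float(sum(counts))
    r = np.asarray(ratio, dtype=float)
    return n * r / r.sum()


def chi_square_segregation(
    counts: Sequence[int], expected_ratio: Sequence[int]
) -> tuple[float, int, float, float]:
    """Pearson chi-square of observed class counts against a fixed ratio.

    Returns (chi2, df, p_value, neg_log10_p).  ``neg_log10_p`` is computed
    from the log survival function, so it stays finite and accurate far in
    the tail where ``p_value`` underflows.
    """
    counts = [float(c) for c in counts]
    if len(counts) != len(expected_ratio):
        raise ValueError("counts and ratio have different lengths")
    if any(c < 0 for c in counts):
        raise ValueError("negative class count")
    n = sum(counts)
    if n == 0:
        raise ValueError("no observations")
    exp = _expected(counts, expected_ratio)
    chi2 = float(np.sum((np.asarray(counts) - exp) ** 2 / exp))
    df = len(counts) - 1
    p = float(stats.chi2.sf(chi2, df))
    neg_log10_p = float(-stats.chi2.logsf(chi2, df) / math.log(10))
    return chi2, df, p, neg_log10_p


def distortion_ratio(
    counts: Sequence[int], expected_ratio: Sequence[int]
) -> tuple[float, str]:
    """Ratio of over- to under-represented class and the favored class label.

    For 1:1 loci the two genotype classes are compared; for 1:2:1 loci the
    two homozygous classes (first and last counts) are compared.  A zero
    smaller count yields an infinite ratio.
    """
    if tuple(expected_ratio) == RATIO_1TO1:
        a, b = float(counts[0]), float(counts[1])
        labels = ("class1", "class2")
    elif tuple(expected_ratio) == RATIO_1TO2TO1:
        a, b = float(counts[0]), float(counts[2])
        labels = ("hom1", "hom2")
    else:
        raise ValueError(f"unsupported ratio {expected_ratio}")
    hi, lo = (a, b) if a >= b else (b, a)
    favored = labels[0] if a >= b else labels[1]
    ratio = math.inf if lo == 0 else hi / lo
    if a == b:
        favored = "none"
    return ratio, favored


def ratio_threshold_filter(result: "DistortionResult", config: DistortionConfig) -> bool:
    """True = keep the locus, False = drop it as too distorted to map.

    1:1 loci are dropped when larger/smaller exceeds the 1:10 threshold;
    1:2:1 loci when either homozygote is more than 5x under-represented
    relative to the other homozygote.
    """
    if result.expected_ratio == RATIO_1TO1:
        return result.distortion_ratio <= config.ratio_threshold_1to1
    hom_ratio, _ = distortion_ratio(result.observed_counts, RATIO_1TO2TO1)
    return hom_ratio <= max(config.ratio_threshold_1to2to1)


def significance_level(p: float, alpha_levels: Sequence[float]) -> Optional[float]:
    """Most stringent alpha with p < alpha, or None."""
    hit = None
    for a in alpha_levels:  # decreasing
        if p < a:
            hit = a
    return hit


def _favored_label(locus: MarkerLocus, favored: str) -> str:
    codes = LEGAL_CODES[locus.seg_class]
    if favored == "none":
        return "none"
    if locus.seg_class == BIPARENTAL:
        return {"hom1": "hh", "hom2": "kk"}[favored]
    return {"class1": codes[0], "class2": codes[1]}[favored]


def analyze_locus(
    locus: MarkerLocus, column: np.ndarray, config: Optional[DistortionConfig] = None
) -> DistortionResult:
    config = config or DistortionConfig()
    codes = LEGAL_CODES[locus.seg_class]
    counts = tuple(int(np.sum(column == c)) for c in codes)
    ratio = RATIO_1TO2TO1 if locus.seg_class == BIPARENTAL else RATIO_1TO1
    chi2, df, p, nlp = chi_square_segregation(counts, ratio)
    dratio, favored = distortion_ratio(counts, ratio)
    return DistortionResult(
        locus=locus,
        observed_counts=counts,
        expected_ratio=ratio,
        chi2=chi2,
        df=df,
        p_value=p,
        neg_log10_p=nlp,
        distortion_ratio=dratio,
        favored_class=_favored_label(locus, favored),
        significance_level=significance_level(p, config.alpha_levels),
    )


def analyze(g: GenotypeMatrix, config: Optional[DistortionConfig] = None) -> list[DistortionResult]:
    """Run the segregation test on every locus (map order preserved).

    Loci with any missing codes are excluded (mirroring source-level
    exclusion of markers with missing data).  Tail probabilities are
    computed vectorized per segregation-class group; results are identical
    to per-locus :func:`analyze_locus` calls.
    """
    config = config or DistortionConfig()
    arr = g.codes.to_numpy()
    missing = (arr == MISSING).any(axis=0)
    groups: dict[str, list[int]] = {}
    for j, locus in enumerate(g.loci):
        if not missing[j]:
            groups.setdefault(locus.seg_class, []).append(j)

    out: list[Optional[DistortionResult]] = [None] * g.n_loci
    for seg, idx in groups.items():
        legal = LEGAL_CODES[seg]
        sub = arr[:, idx]
        counts = np.stack([(sub == c).sum(axis=0) for c in legal], axis=1)
        ratio = RATIO_1TO2TO1 if seg == BIPARENTAL else RATIO_1TO1
        r = np.asarray(ratio, dtype=float)
        n = counts.sum(axis=1)
        exp = n[:, None] * r[None, :] / r.sum()
        chi2v = ((counts - exp) ** 2 / exp).sum(axis=1)
        df = len(ratio) - 1
        pv = stats.chi2.sf(chi2v, df)
        nlpv = -stats.chi2.logsf(chi2v, df) / math.log(10)
        for k, j in enumerate(idx):
            locus = g.loci[j]
            cts = tuple(int(x) for x in counts[k])
            dratio, favored = distortion_ratio(cts, ratio)
            out[j] = DistortionResult(
                locus=locus,
                observed_counts=cts,
                expected_ratio=tuple(ratio),
                chi2=float(chi2v[k]),
                df=df,
                p_value=float(pv[k]),
                neg_log10_p=float(nlpv[k]),
                distortion_ratio=dratio,
                favored_class=_favored_label(locus, favored),
                significance_level=significance_level(float(pv[k]), config.alpha_levels),
            )
    return [res for res in out if res is not None]


def summarize_distortion(
    results: Sequence[DistortionResult], config: Optional[DistortionConfig] = None
) -> pd.DataFrame:
    """Proportions of distorted loci per alpha level.

    One row per (chromosome, seg_class) group plus ``ALL`` margins; levels
    are nested (a locus significant at 0.001 is counted at 0.05 too).
    """
    config = config or DistortionConfig()
    if not results:
        raise ValueError("no results to summarize")
    df = pd.DataFrame(
        {
            "chromosome": [r.locus.chromosome for r in results],
            "seg_class": [r.locus.seg_class for r in results],
            "p_value": [r.p_value for r in results],
        }
    )
    rows = []
    groups: list[tuple[str, str, pd.DataFrame]] = [("ALL", "ALL", df)]
    for c, sub in df.groupby("chromosome", sort=True):
        groups.append((str(c), "ALL", sub))
    for s, sub in df.groupby("seg_class", sort=True):
        groups.append(("ALL", str(s), sub))
    for (c, s), sub in df.groupby(["chromosome", "seg_class"], sort=True):
        groups.append((str(c), str(s), sub))
    for chrom, seg, sub in groups:
        row = {"chromosome": chrom, "seg_class": seg, "n_loci": len(sub)}
        for a in config.alpha_levels:
            row[f"prop_p<{a:g}"] = float((sub["p_value"] < a).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def results_table(results: Sequence[DistortionResult]) -> pd.DataFrame:
    """Per-locus TSV-ready table of test results."""
    return pd.DataFrame(
        {
            "marker_id": [r.locus.marker_id for r in results],
            "chromosome": [r.locus.chromosome for r in results],
            "cM": [r.locus.genetic_pos for r in results],
            "Mb": [r.locus.physical_pos for r in results],
            "seg_class": [r.locus.seg_class for r in results],
            "counts": ["/".join(str(c) for c in r.observed_counts) for r in results],
            "chi2": [r.chi2 for r in results],
            "df": [r.df for r in results],
            "p_value": [r.p_value for r in results],
            "neg_log10_p": [r.neg_log10_p for r in results],
            "distortion_ratio": [r.distortion_ratio for r in results],
            "favored_class": [r.favored_class for r in results],
            "significance_level": [r.significance_level for r in results],
        }
    )
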
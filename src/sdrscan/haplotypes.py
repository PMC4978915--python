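"""Parental haplotype transmission profiles and crossover counting.

A parent's two chromosome haplotypes are reconstructed from linkage phases
at its 1:1 loci: a progeny carrying the heterozygous-class code (lm/np)
received the homolog carrying the marked allele, i.e. homolog ``phase + 1``;
a progeny carrying the homozygous code received the other homolog.
Biparental <hkxhk> loci are excluded from single-parent profiles (the hk
class is origin-ambiguous); biparental distortion is instead examined
through four-way maternal x paternal combination tests on nearby 1:1 loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io import (
    HET_CODE,
    MATERNAL,
    MISSING,
    PATERNAL,
    GenotypeMatrix,
    MarkerLocus,
)
from .distortion import chi_square_segregation
from .simulate import TruthRecord


@dataclass
class HaplotypeProfile:
    chromosome: str
    parent: str
    loci: list[MarkerLocus]
    freq_homolog1: np.ndarray
    n_informative: np.ndarray
    p_values: np.ndarray

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": [l.marker_id for l in self.loci],
                "chromosome": self.chromosome,
                "parent": self.parent,
                "cM": [l.genetic_pos for l in self.loci],
                "Mb": [l.physical_pos for l in self.loci],
                "freq_homolog1": self.freq_homolog1,
                "freq_homolog2": 1.0 - self.freq_homolog1,
                "n_informative": self.n_informative,
                "p_value": self.p_values,
            }
        )


@dataclass
class CombinationRecord:
    chromosome: str
    maternal_locus: MarkerLocus
    paternal_locus: MarkerLocus
    counts: tuple[int, int, int, int]  # M1P1, M1P2, M2P1, M2P2
    chi2: float
    p_value: float
    significant: bool


@dataclass
class CombinationProfile:
    records: list[CombinationRecord]
    alpha: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": [r.chromosome for r in self.records],
                "maternal_marker": [r.maternal_locus.marker_id for r in self.records],
                "paternal_marker": [r.paternal_locus.marker_id for r in self.records],
                "cM": [r.maternal_locus.genetic_pos for r in self.records],
                "M1P1": [r.counts[0] for r in self.records],
                "M1P2": [r.counts[1] for r in self.records],
                "M2P1": [r.counts[2] for r in self.records],
                "M2P2": [r.counts[3] for r in self.records],
                "chi2": [r.chi2 for r in self.records],
                "p_value": [r.p_value for r in self.records],
                "significant": [r.significant for r in self.records],
            }
        )


def _phase_of(locus: MarkerLocus, parent: str) -> Optional[int]:
    return locus.phase_maternal if parent == MATERNAL else locus.phase_paternal


def homolog_indicators(
    g: GenotypeMatrix, parent: str, chromosome: str
) -> tuple[list[MarkerLocus], np.ndarray]:
    """Transmitted-homolog calls (1/2, 0 = missing) at a parent's 1:1 loci."""
    loci = [l for l in g.loci_for(parent, chromosome) if _phase_of(l, parent) is not None]
    het = HET_CODE[parent]
    out = np.zeros((g.n_progeny, len(loci)), dtype=np.int8)
    for j, l in enumerate(loci):
        col = g.column(l.marker_id)
        phase = _phase_of(l, parent)
        is_het = col == het
        hom = np.where(is_het, phase + 1, 2 - phase)
        hom[col == MISSING] = 0
        out[:, j] = hom
    return loci, out


def transmission_profile(g: GenotypeMatrix, parent: str) -> list[HaplotypeProfile]:
    """Per-chromosome homolog-1 transmission frequency profile for a parent."""
    if parent not in (MATERNAL, PATERNAL):
        raise ValueError("parent must be maternal or paternal")
    profiles = []
    for chrom in g.chromosomes:
        loci, hom = homolog_indicators(g, parent, chrom)
        if not loci:
            continue
        n1 = (hom == 1).sum(axis=0)
        n2 = (hom == 2).sum(axis=0)
        n_inf = n1 + n2
        freqs = np.divide(n1, n_inf, out=np.full(len(loci), np.nan), where=n_inf > 0)
        pvals = np.array(
            [
                chi_square_segregation((int(a), int(b)), (1, 1))[2] if a + b > 0 else np.nan
                for a, b in zip(n1, n2)
            ]
        )
        profiles.append(
            HaplotypeProfile(
                chromosome=chrom,
                parent=parent,
                loci=loci,
                freq_homolog1=freqs,
                n_informative=n_inf,
                p_values=pvals,
            )
        )
    return profiles


def combination_profile(
    g: GenotypeMatrix, window_cM: float = 1.0, alpha: float = 0.001
) -> CombinationProfile:
    """Four-way maternal x paternal haplotype combination counts.

    Each maternal 1:1 locus is paired with the nearest paternal 1:1 locus
    within ``window_cM`` on the same chromosome; the four joint transmissions
    are counted over progeny informative at both loci and tested against
    1:1:1:1 (df = 3).
    """
    records = []
    for chrom in g.chromosomes:
        mat_loci, mat_hom = homolog_indicators(g, MATERNAL, chrom)
        pat_loci, pat_hom = homolog_indicators(g, PATERNAL, chrom)
        if not mat_loci or not pat_loci:
            continue
        pat_pos = np.array([l.genetic_pos for l in pat_loci])
        for j, ml in enumerate(mat_loci):
            d = np.abs(pat_pos - ml.genetic_pos)
            k = int(np.argmin(d))
            if d[k] > window_cM:
                continue
            m = mat_hom[:, j]
            p = pat_hom[:, k]
            ok = (m > 0) & (p > 0)
            combo = 2 * (m[ok] - 1) + (p[ok] - 1)
            counts = tuple(int(np.sum(combo == c)) for c in range(4))
            chi2, _, pval, _ = chi_square_segregation(counts, (1, 1, 1, 1))
            records.append(
                CombinationRecord(
                    chromosome=chrom,
                    maternal_locus=ml,
                    paternal_locus=pat_loci[k],
                    counts=counts,
                    chi2=chi2,
                    p_value=pval,
                    significant=pval < alpha,
                )
            )
    return CombinationProfile(records=records, alpha=alpha)


def _count_transitions(ind: np.ndarray) -> np.ndarray:
    """Transitions per row of a homolog-indicator matrix, skipping zeros."""
    n, m = ind.shape
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        seq = ind[i][ind[i] > 0]
        if seq.size > 1:
            counts[i] = int(np.sum(seq[1:] != seq[:-1]))
    return counts


def count_crossovers(
    source: Union[GenotypeMatrix, TruthRecord],
    chromosomes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Detected crossover counts per progeny, chromosome, and parent.

    From a :class:`GenotypeMatrix`, the transmitted-homolog indicator is
    reconstructed from phased 1:1 loci and transitions along the map are
    counted (double crossovers between adjacent markers are invisible).
    From a :class:`TruthRecord`, the recorded indicator sequences are used
    directly.
    """
    rows = []
    if isinstance(source, TruthRecord):
        keys = sorted(source.indicators)
        for chrom, parent in keys:
            if chromosomes is not None and chrom not in chromosomes:
                continue
            counts = _count_transitions(source.indicators[(chrom, parent)])
            for i, c in enumerate(counts):
                rows.append(
                    {"progeny": i, "chromosome": chrom, "parent": parent, "crossovers": int(c)}
                )
    else:
        g = source
        for chrom in chromosomes if chromosomes is not None else g.chromosomes:
            for parent in (MATERNAL, PATERNAL):
                loci, hom = homolog_indicators(g, parent, chrom)
                if not loci:
                    continue
                counts = _count_transitions(hom)
                for i, c in enumerate(counts):
                    rows.append(
                        {
                            "progeny": g.progeny_ids[i],
                            "chromosome": chrom,
                            "parent": parent,
                            "crossovers": int(c),
                        }
                    )
    return pd.DataFrame(rows)


def crossover_summary(counts: pd.DataFrame, n_progeny: int) -> pd.DataFrame:
    """Population totals and per-plant means, per parent and overall."""
    rows = []
    for parent, sub in counts.groupby("parent"):
        total = int(sub["crossovers"].sum())
        rows.append({"parent": parent, "total_events": total, "mean_per_plant": total / n_progeny})
    total = int(counts["crossovers"].sum())
    rows.append({"parent": "both", "total_events": total, "mean_per_plant": total / n_progeny})
    return pd.DataFrame(rows)
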
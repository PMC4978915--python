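"""Two-locus r² interaction scan between unlinked loci.

Per-progeny allele codes are reconstructed at bin-representative loci from
linkage phases: 1:1 loci give the transmitted-homolog indicator of the
informative parent, <hkxhk> loci give the marked-allele dosage 0/1/2.
For a pair of code vectors r² is the squared Pearson correlation and the
p-value comes from the chi-square approximation n*r² ~ chi²(1); for binary
vectors n*r² equals the Pearson chi-square of the 2x2 contingency table
exactly.  A permutation mode gives an exact-null alternative.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import BIPARENTAL, MATERNAL, MISSING, PATERNAL, GenotypeMatrix, MarkerBin, MarkerLocus
from .haplotypes import _phase_of
from .io import HET_CODE

logger = logging.getLogger(__name__)


@dataclass
class EpistasisConfig:
    p_threshold: float = 0.005
    linked_cutoff_cM: float = 50.0
    permutations: int = 0  # 0 = asymptotic chi-square p-values

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0,1)")
        if self.linked_cutoff_cM <= 0:
            raise ValueError("linked_cutoff_cM must be positive")


@dataclass
class EpistasisHit:
    locus_a: MarkerLocus
    locus_b: MarkerLocus
    r_squared: float
    p_value: float

    @property
    def chromosome_pair(self) -> tuple[str, str]:
        return tuple(sorted((self.locus_a.chromosome, self.locus_b.chromosome)))


def phase_encode(
    g: GenotypeMatrix, bins: Optional[Sequence[MarkerBin]] = None
) -> tuple[list[MarkerLocus], np.ndarray]:
    """Numeric allele codes per progeny at bin-representative loci.

    Returns the encoded loci and a float matrix (progeny x loci) with NaN
    for missing codes.  1:1 loci encode the transmitted homolog (1/2) of
    the heterozygous parent; biparental loci encode marked-allele dosage.
    Loci without the needed phase are skipped with a warning.
    """
    loci = [b.representative for b in bins] if bins is not None else list(g.loci)
    out_loci: list[MarkerLocus] = []
    cols: list[np.ndarray] = []
    for l in loci:
        col = g.column(l.marker_id)
        enc = np.full(g.n_progeny, np.nan)
        if l.seg_class == BIPARENTAL:
            if l.phase_maternal is None or l.phase_paternal is None:
                logger.warning("skipping %s: missing phase", l.marker_id)
                continue
            for code, dose in (("hh", 0.0), ("hk", 1.0), ("kk", 2.0)):
                enc[col == code] = dose
        else:
            parent = MATERNAL if l.seg_class == MATERNAL else PATERNAL
            phase = _phase_of(l, parent)
            if phase is None:
                logger.warning("skipping %s: missing phase", l.marker_id)
                continue
            het = HET_CODE[parent]
            enc[col == het] = phase + 1
            enc[(col != het) & (col != MISSING)] = 2 - phase
        out_loci.append(l)
        cols.append(enc)
    codes = np.column_stack(cols) if cols else np.empty((g.n_progeny, 0))
    return out_loci, codes


def pairwise_r2(
    codes_a: np.ndarray,
    codes_b: np.ndarray,
    permutations: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> Optional[tuple[float, float]]:
    """(r², p) for two code vectors, or None when either has no variance.

    Entries missing (NaN) in either vector are dropped pairwise.  With
    ``permutations > 0`` the p-value is the permutation tail probability of
    r² instead of the chi-square approximation.
    """
    a = np.asarray(codes_a, dtype=float)
    b = np.asarray(codes_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("code vectors differ in length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    n = a.size
    if n < 2 or np.all(a == a[0]) or np.all(b == b[0]):
        return None
    r = np.corrcoef(a, b)[0, 1]
    r2 = float(r * r)
    if permutations > 0:
        rng = rng or np.random.default_rng()
        hits = 1  # add-one permutation p-value
        for _ in range(permutations):
            rp = np.corrcoef(rng.permutation(a), b)[0, 1]
            if rp * rp >= r2 - 1e-12:
                hits += 1
        p = hits / (permutations + 1)
    else:
        p = float(stats.chi2.sf(n * r2, 1))
    return r2, p


def _unlinked(a: MarkerLocus, b: MarkerLocus, cutoff_cM: float) -> bool:
    if a.chromosome != b.chromosome:
        return True
    return abs(a.genetic_pos - b.genetic_pos) >= cutoff_cM


def scan(
    g: GenotypeMatrix,
    bins: Optional[Sequence[MarkerBin]] = None,
    config: Optional[EpistasisConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[EpistasisHit], pd.DataFrame]:
    """Test all unlinked bin pairs; return hits and a chromosome-pair summary.

    Unlinked means different chromosomes, or at least ``linked_cutoff_cM``
    apart on the same chromosome.
    """
    config = config or EpistasisConfig()
    loci, codes = phase_encode(g, bins)
    hits: list[EpistasisHit] = []
    for i, j in itertools.combinations(range(len(loci)), 2):
        if not _unlinked(loci[i], loci[j], config.linked_cutoff_cM):
            continue
        res = pairwise_r2(codes[:, i], codes[:, j], permutations=config.permutations, rng=rng)
        if res is None:
            continue
        r2, p = res
        if p < config.p_threshold:
            hits.append(EpistasisHit(locus_a=loci[i], locus_b=loci[j], r_squared=r2, p_value=p))
    pair_counts: dict[tuple[str, str], int] = {}
    for h in hits:
        pair_counts[h.chromosome_pair] = pair_counts.get(h.chromosome_pair, 0) + 1
    summary = pd.DataFrame(
        {
            "chromosome_a": [k[0] for k in sorted(pair_counts)],
            "chromosome_b": [k[1] for k in sorted(pair_counts)],
            "n_hits": [pair_counts[k] for k in sorted(pair_counts)],
        }
    )
    return hits, summary


def hits_table(hits: Sequence[EpistasisHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "marker_a": [h.locus_a.marker_id for h in hits],
            "chromosome_a": [h.locus_a.chromosome for h in hits],
            "marker_b": [h.locus_b.marker_id for h in hits],
            "chromosome_b": [h.locus_b.chromosome for h in hits],
            "r_squared": [h.r_squared for h in hits],
            "p_value": [h.p_value for h in hits],
        }
    )
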
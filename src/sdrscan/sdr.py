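"""Segregation-distortion-region calling.

Within each chromosome and parent stream (maternal, paternal, biparental
loci are called separately), consecutive significant loci are chained while
the gap between them is at most ``max_gap_cM``; chains with at least
``min_markers`` members become SDRs.  Non-significant loci interleaved in a
chain neither break it nor count as members.  An optional minimum-span rule
(``min_span_cM``) covers the alternative reading of the clustering
distance; it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .io import MarkerLocus
from .distortion import DistortionResult


@dataclass
class SDRConfig:
    alpha: float = 0.001
    min_markers: int = 6
    max_gap_cM: float = 5.0
    min_span_cM: Optional[float] = None

    def __post_init__(self) -> None:
        if self.min_markers < 2:
            raise ValueError("min_markers must be >= 2")
        if self.max_gap_cM <= 0:
            raise ValueError("max_gap_cM must be positive")


@dataclass
class SDR:
    chromosome: str
    parent_of_origin: str
    start_cM: float
    end_cM: float
    start_Mb: Optional[float]
    end_Mb: Optional[float]
    members: list[DistortionResult]
    peak: DistortionResult

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def peak_locus(self) -> MarkerLocus:
        return self.peak.locus

    @property
    def peak_ratio(self) -> float:
        return self.peak.distortion_ratio


def _check_sorted(results: Sequence[DistortionResult]) -> None:
    seen: list[str] = []
    last_pos = 0.0
    for r in results:
        c = r.locus.chromosome
        if seen and seen[-1] == c:
            if r.locus.genetic_pos < last_pos:
                raise ValueError(f"results not sorted by genetic_pos on {c}")
        elif c in seen:
            raise ValueError("results not sorted: chromosome blocks are interleaved")
        else:
            seen.append(c)
        last_pos = r.locus.genetic_pos


def _make_sdr(chain: list[DistortionResult]) -> SDR:
    mbs = [r.locus.physical_pos for r in chain]
    anchored = all(m is not None for m in mbs)
    peak = max(chain, key=lambda r: r.neg_log10_p)
    return SDR(
        chromosome=chain[0].locus.chromosome,
        parent_of_origin=chain[0].locus.seg_class,
        start_cM=min(r.locus.genetic_pos for r in chain),
        end_cM=max(r.locus.genetic_pos for r in chain),
        start_Mb=min(mbs) if anchored else None,
        end_Mb=max(mbs) if anchored else None,
        members=list(chain),
        peak=peak,
    )


def call_sdrs(
    results: Sequence[DistortionResult], config: Optional[SDRConfig] = None
) -> list[SDR]:
    """Cluster significantly distorted loci into SDRs.

    ``results`` must be ordered along the map (chromosome blocks, ascending
    genetic position within each).
    """
    config = config or SDRConfig()
    _check_sorted(results)

    streams: dict[tuple[str, str], list[DistortionResult]] = {}
    for r in results:
        if r.p_value < config.alpha:
            streams.setdefault((r.locus.chromosome, r.locus.seg_class), []).append(r)

    sdrs: list[SDR] = []
    for key in streams:
        sig = streams[key]
        chain: list[DistortionResult] = [sig[0]]
        chains: list[list[DistortionResult]] = []
        for r in sig[1:]:
            if r.locus.genetic_pos - chain[-1].locus.genetic_pos <= config.max_gap_cM:
                chain.append(r)
            else:
                chains.append(chain)
                chain = [r]
        chains.append(chain)
        for chain in chains:
            if len(chain) < config.min_markers:
                continue
            span = chain[-1].locus.genetic_pos - chain[0].locus.genetic_pos
            if config.min_span_cM is not None and span < config.min_span_cM:
                continue
            sdrs.append(_make_sdr(chain))
    sdrs.sort(key=lambda s: (s.chromosome, s.start_cM, s.parent_of_origin))
    return sdrs


def sdr_report(sdrs: Sequence[SDR]) -> pd.DataFrame:
    """One row per SDR: extents, membership, and peak."""
    return pd.DataFrame(
        {
            "chromosome": [s.chromosome for s in sdrs],
            "parent_of_origin": [s.parent_of_origin for s in sdrs],
            "start_cM": [s.start_cM for s in sdrs],
            "end_cM": [s.end_cM for s in sdrs],
            "start_Mb": [s.start_Mb for s in sdrs],
            "end_Mb": [s.end_Mb for s in sdrs],
            "n_members": [s.n_members for s in sdrs],
            "peak_marker": [s.peak_locus.marker_id for s in sdrs],
            "peak_cM": [s.peak_locus.genetic_pos for s in sdrs],
            "peak_Mb": [s.peak_locus.physical_pos for s in sdrs],
            "peak_neg_log10_p": [s.peak.neg_log10_p for s in sdrs],
            "peak_ratio": [s.peak_ratio for s in sdrs],
        }
    )
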
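"""Genotype/map file handling, marker binning, and map comparison.

File dialect
------------
Two plain TSV files describe a population:

* genotype file — one row per marker:
  ``marker_id  seg_class  phase  <progeny codes...>``, where ``phase`` is a
  two-character string (maternal then paternal phase, ``-`` when the parent
  is homozygous, e.g. ``0-``, ``-1``, ``01``).
* map file — one row per marker:
  ``marker_id  chromosome  cM  Mb  phase_maternal  phase_paternal`` with
  ``-`` for unanchored Mb or absent phases.

Legal genotype codes depend on the segregation class: ``ll``/``lm`` for
maternal (<lmxll>) markers, ``nn``/``np`` for paternal (<nnxnp>), and
``hh``/``hk``/``kk`` for biparental (<hkxhk>).  ``--`` is the missing
sentinel.  By default markers containing any missing code are dropped on
read (and logged); pass ``keep_missing=True`` to retain them.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MATERNAL = "maternal"
PATERNAL = "paternal"
BIPARENTAL = "biparental"

SEG_CLASSES = (MATERNAL, PATERNAL, BIPARENTAL)

#: JoinMap-style cross-type tags for each segregation class.
SEG_CLASS_TAGS = {MATERNAL: "<lmxll>", PATERNAL: "<nnxnp>", BIPARENTAL: "<hkxhk>"}
TAG_TO_CLASS = {v: k for k, v in SEG_CLASS_TAGS.items()}

MISSING = "--"

LEGAL_CODES = {
    MATERNAL: ("ll", "lm"),
    PATERNAL: ("nn", "np"),
    BIPARENTAL: ("hh", "hk", "kk"),
}

#: heterozygous code carrying the parent's segregating ("marked") allele
HET_CODE = {MATERNAL: "lm", PATERNAL: "np"}
HOM_CODE = {MATERNAL: "ll", PATERNAL: "nn"}


class ParseError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass(frozen=True)
class MarkerLocus:
    """One mapped SNP marker.

    ``phase_maternal``/``phase_paternal`` follow the convention that the
    parent's homolog ``phase + 1`` carries the marked allele (m, p, or k);
    a phase is present iff that parent is heterozygous at the locus.
    """

    marker_id: str
    chromosome: str
    genetic_pos: float
    seg_class: str
    physical_pos: Optional[float] = None
    phase_maternal: Optional[int] = None
    phase_paternal: Optional[int] = None

    def __post_init__(self) -> None:
        if self.seg_class not in SEG_CLASSES:
            raise ValueError(f"unknown seg_class {self.seg_class!r}")
        if self.genetic_pos < 0:
            raise ValueError(f"{self.marker_id}: negative genetic position")
        mother_het = self.seg_class in (MATERNAL, BIPARENTAL)
        father_het = self.seg_class in (PATERNAL, BIPARENTAL)
        if mother_het != (self.phase_maternal is not None):
            raise ValueError(
                f"{self.marker_id}: phase_maternal must be present iff the "
                f"mother is heterozygous ({self.seg_class})"
            )
        if father_het != (self.phase_paternal is not None):
            raise ValueError(
                f"{self.marker_id}: phase_paternal must be present iff the "
                f"father is heterozygous ({self.seg_class})"
            )
        for phase in (self.phase_maternal, self.phase_paternal):
            if phase is not None and phase not in (0, 1):
                raise ValueError(f"{self.marker_id}: phase must be 0 or 1")

    @property
    def legal_codes(self) -> tuple[str, ...]:
        return LEGAL_CODES[self.seg_class]


@dataclass
class GenotypeMatrix:
    """Progeny x marker table of CP genotype codes, in map order."""

    progeny_ids: list[str]
    loci: list[MarkerLocus]
    codes: pd.DataFrame  # index: progeny_ids, columns: marker_ids

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n_progeny(self) -> int:
        return len(self.progeny_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def marker_ids(self) -> list[str]:
        return [l.marker_id for l in self.loci]

    def locus(self, marker_id: str) -> MarkerLocus:
        return self._locus_index[marker_id]

    def column(self, marker_id: str) -> np.ndarray:
        return self.codes[marker_id].to_numpy()

    def loci_for(self, seg_class: str, chromosome: Optional[str] = None) -> list[MarkerLocus]:
        out = [l for l in self.loci if l.seg_class == seg_class]
        if chromosome is not None:
            out = [l for l in out if l.chromosome == chromosome]
        return out

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for l in self.loci:
            seen.setdefault(l.chromosome, None)
        return list(seen)

    def subset_loci(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        keep = set(marker_ids)
        loci = [l for l in self.loci if l.marker_id in keep]
        return GenotypeMatrix(
            progeny_ids=list(self.progeny_ids),
            loci=loci,
            codes=self.codes[[l.marker_id for l in loci]],
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        ids = [l.marker_id for l in self.loci]
        if len(set(ids)) != len(ids):
            dup = next(m for m in ids if ids.count(m) > 1)
            raise ParseError(f"duplicate marker_id {dup!r}")
        if list(self.codes.columns) != ids:
            raise ParseError("codes columns do not match loci order")
        if list(self.codes.index) != list(self.progeny_ids):
            raise ParseError("codes index does not match progeny_ids")
        arr = self.codes.to_numpy()
        for j, loc in enumerate(self.loci):
            legal = set(loc.legal_codes) | {MISSING}
            bad = set(arr[:, j]) - legal
            if bad:
                i = int(np.nonzero(~np.isin(arr[:, j], list(legal)))[0][0])
                raise ParseError(
                    f"illegal code {arr[i, j]!r} for {loc.seg_class} marker "
                    f"{loc.marker_id!r} (progeny {self.progeny_ids[i]!r})"
                )
        # column order must follow the map
        key = [(l.chromosome, l.genetic_pos) for l in self.loci]
        chrom_first = {c: i for i, c in enumerate(dict.fromkeys(k[0] for k in key))}
        ordered = sorted(range(len(key)), key=lambda i: (chrom_first[key[i][0]], key[i][1]))
        if [key[i] for i in ordered] != key:
            raise ParseError("loci are not sorted by (chromosome, genetic_pos)")
        self._locus_index = {l.marker_id: l for l in self.loci}


@dataclass
class MarkerBin:
    """A set of markers with identical genotype columns."""

    bin_id: str
    representative: MarkerLocus
    members: list[str]


@dataclass
class MapComparison:
    shared_count_per_chromosome: pd.DataFrame
    discordant_chromosome_assignments: int
    order_concordance: Optional[float]
    n_shared: int


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _parse_phase(token: str, marker_id: str) -> Optional[int]:
    if token in ("-", "", "."):
        return None
    if token in ("0", "1"):
        return int(token)
    raise ParseError(f"{marker_id}: bad phase token {token!r}")


def _fmt_phase(phase: Optional[int]) -> str:
    return "-" if phase is None else str(phase)


def read_map(map_path: str | Path) -> list[MarkerLocus]:
    """Read a marker map TSV into loci sorted by (chromosome, cM, Mb, id)."""
    df = pd.read_csv(map_path, sep="\t", dtype=str)
    required = ["marker_id", "chromosome", "cM", "Mb", "phase_maternal", "phase_paternal"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{map_path}: missing columns {missing_cols}")
    loci = []
    for row in df.itertuples(index=False):
        mb = None if row.Mb in ("-", "", ".", None) else float(row.Mb)
        pm = _parse_phase(row.phase_maternal, row.marker_id)
        pp = _parse_phase(row.phase_paternal, row.marker_id)
        if pm is not None and pp is not None:
            seg = BIPARENTAL
        elif pm is not None:
            seg = MATERNAL
        elif pp is not None:
            seg = PATERNAL
        else:
            raise ParseError(f"{row.marker_id}: no phase given for either parent")
        loci.append(
            MarkerLocus(
                marker_id=row.marker_id,
                chromosome=row.chromosome,
                genetic_pos=float(row.cM),
                physical_pos=mb,
                seg_class=seg,
                phase_maternal=pm,
                phase_paternal=pp,
            )
        )
    ids = [l.marker_id for l in loci]
    if len(set(ids)) != len(ids):
        dup = next(m for m in ids if ids.count(m) > 1)
        raise ParseError(f"{map_path}: duplicate marker_id {dup!r}")
    return sort_loci(loci)


def sort_loci(loci: Iterable[MarkerLocus]) -> list[MarkerLocus]:
    """Stable sort by (chromosome, cM, Mb, marker_id)."""
    return sorted(
        loci,
        key=lambda l: (
            l.chromosome,
            l.genetic_pos,
            l.physical_pos if l.physical_pos is not None else float("inf"),
            l.marker_id,
        ),
    )


def read_genotypes(
    genotype_path: str | Path,
    map_path: str | Path,
    keep_missing: bool = False,
) -> GenotypeMatrix:
    """Read the genotype/map TSV pair into a validated :class:`GenotypeMatrix`.

    Markers must appear in both files.  Markers with missing codes are
    dropped (with a log message) unless ``keep_missing`` is set.
    """
    loci = read_map(map_path)
    by_id = {l.marker_id: l for l in loci}

    df = pd.read_csv(genotype_path, sep="\t", dtype=str)
    for col in ("marker_id", "seg_class", "phase"):
        if col not in df.columns:
            raise ParseError(f"{genotype_path}: missing column {col!r}")
    progeny_ids = [c for c in df.columns if c not in ("marker_id", "seg_class", "phase")]
    gids = list(df["marker_id"])
    if len(set(gids)) != len(gids):
        dup = next(m for m in gids if gids.count(m) > 1)
        raise ParseError(f"{genotype_path}: duplicate marker_id {dup!r}")

    only_geno = set(gids) - set(by_id)
    only_map = set(by_id) - set(gids)
    if only_geno or only_map:
        raise ParseError(
            f"markers present in only one file: genotype-only={sorted(only_geno)[:5]}, "
            f"map-only={sorted(only_map)[:5]}"
        )

    col_idx = {c: i for i, c in enumerate(df.columns)}
    prog_idx = [col_idx[p] for p in progeny_ids]
    rows = {}
    for vals in df.to_numpy(dtype=object):
        marker_id = vals[col_idx["marker_id"]]
        seg_tag = vals[col_idx["seg_class"]]
        loc = by_id[marker_id]
        tag = TAG_TO_CLASS.get(seg_tag, seg_tag)
        if tag != loc.seg_class:
            raise ParseError(
                f"{marker_id}: seg_class {seg_tag!r} disagrees with map ({loc.seg_class})"
            )
        phase_str = _fmt_phase(loc.phase_maternal) + _fmt_phase(loc.phase_paternal)
        if str(vals[col_idx["phase"]]) != phase_str:
            raise ParseError(
                f"{marker_id}: phase {vals[col_idx['phase']]!r} disagrees with map ({phase_str!r})"
            )
        rows[marker_id] = [vals[i] for i in prog_idx]

    data = {l.marker_id: rows[l.marker_id] for l in loci}
    codes = pd.DataFrame(data, index=progeny_ids, dtype=object)

    if not keep_missing:
        has_missing = [m for m in codes.columns if (codes[m] == MISSING).any()]
        if has_missing:
            logger.info("dropping %d markers with missing codes: %s%s",
                        len(has_missing), has_missing[:5],
                        "..." if len(has_missing) > 5 else "")
            loci = [l for l in loci if l.marker_id not in set(has_missing)]
            codes = codes[[l.marker_id for l in loci]]

    return GenotypeMatrix(progeny_ids=progeny_ids, loci=loci, codes=codes)


def write_map(loci: Sequence[MarkerLocus], map_path: str | Path) -> None:
    rows = [
        {
            "marker_id": l.marker_id,
            "chromosome": l.chromosome,
            "cM": repr(float(l.genetic_pos)),
            "Mb": "-" if l.physical_pos is None else repr(float(l.physical_pos)),
            "phase_maternal": _fmt_phase(l.phase_maternal),
            "phase_paternal": _fmt_phase(l.phase_paternal),
        }
        for l in loci
    ]
    pd.DataFrame(rows).to_csv(map_path, sep="\t", index=False)


def write_genotypes(g: GenotypeMatrix, genotype_path: str | Path, map_path: str | Path) -> None:
    """Write the genotype/map TSV pair (inverse of :func:`read_genotypes`)."""
    write_map(g.loci, map_path)
    cols: dict[str, list] = {"marker_id": [], "seg_class": [], "phase": []}
    for pid in g.progeny_ids:
        cols[pid] = []
    arr = g.codes.to_numpy()
    for j, l in enumerate(g.loci):
        cols["marker_id"].append(l.marker_id)
        cols["seg_class"].append(SEG_CLASS_TAGS[l.seg_class])
        cols["phase"].append(_fmt_phase(l.phase_maternal) + _fmt_phase(l.phase_paternal))
        for i, pid in enumerate(g.progeny_ids):
            cols[pid].append(arr[i, j])
    pd.DataFrame(cols).to_csv(genotype_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bin collapse
# ---------------------------------------------------------------------------

def collapse_bins(
    g: GenotypeMatrix, max_missing_mismatch: int = 0
) -> tuple[GenotypeMatrix, list[MarkerBin]]:
    """Collapse markers with identical genotype columns into bins.

    The representative is the member with the smallest genetic position,
    ties broken lexicographically by marker_id.  When
    ``max_missing_mismatch > 0``, columns are merged into an existing bin
    if they differ from its representative column only at positions where
    either entry is missing, at no more than that many positions.
    """
    arr = g.codes.to_numpy()
    bins: list[list[int]] = []
    exact: dict[tuple, int] = {}
    for j in range(g.n_loci):
        key = tuple(arr[:, j])
        if key in exact:
            bins[exact[key]].append(j)
            continue
        placed = False
        if max_missing_mismatch > 0:
            col = arr[:, j]
            for b_idx, members in enumerate(bins):
                rep = arr[:, members[0]]
                differ = (col != rep)
                missing = (col == MISSING) | (rep == MISSING)
                if not np.any(differ & ~missing) and int(np.sum(differ & missing)) <= max_missing_mismatch:
                    members.append(j)
                    placed = True
                    break
        if not placed:
            exact[key] = len(bins)
            bins.append([j])

    out_bins: list[MarkerBin] = []
    keep_ids: list[str] = []
    for k, members in enumerate(bins):
        loci = [g.loci[j] for j in members]
        rep = min(loci, key=lambda l: (l.genetic_pos, l.marker_id))
        out_bins.append(
            MarkerBin(
                bin_id=f"bin{k + 1:05d}",
                representative=rep,
                members=sorted(l.marker_id for l in loci),
            )
        )
        keep_ids.append(rep.marker_id)
    collapsed = g.subset_loci(keep_ids)
    return collapsed, out_bins


# ---------------------------------------------------------------------------
# map comparison
# ---------------------------------------------------------------------------

def compare_maps(a: Sequence[MarkerLocus], b: Sequence[MarkerLocus]) -> MapComparison:
    """Compare two maps on their shared markers.

    Shared markers on the same chromosome in both maps are counted per
    chromosome; markers assigned to different chromosomes are counted as
    discordant.  Order concordance is the fraction of within-chromosome
    shared-marker pairs whose relative genetic order agrees (ties in both
    maps count as agreeing).
    """
    a_by = {l.marker_id: l for l in a}
    b_by = {l.marker_id: l for l in b}
    shared = sorted(set(a_by) & set(b_by))

    discordant = 0
    per_chrom: dict[str, int] = {}
    same_chrom: dict[str, list[str]] = {}
    for m in shared:
        if a_by[m].chromosome != b_by[m].chromosome:
            discordant += 1
            continue
        c = a_by[m].chromosome
        per_chrom[c] = per_chrom.get(c, 0) + 1
        same_chrom.setdefault(c, []).append(m)

    n_pairs = 0
    n_concordant = 0
    for c, markers in same_chrom.items():
        for m1, m2 in itertools.combinations(markers, 2):
            da = a_by[m1].genetic_pos - a_by[m2].genetic_pos
            db = b_by[m1].genetic_pos - b_by[m2].genetic_pos
            n_pairs += 1
            if np.sign(da) == np.sign(db):
                n_concordant += 1

    table = pd.DataFrame(
        {"chromosome": sorted(per_chrom), "n_shared": [per_chrom[c] for c in sorted(per_chrom)]}
    )
    return MapComparison(
        shared_count_per_chromosome=table,
        discordant_chromosome_assignments=discordant,
        order_concordance=(n_concordant / n_pairs) if n_pairs else None,
        n_shared=len(shared),
    )
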
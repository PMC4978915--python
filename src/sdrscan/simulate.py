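"""Synthetic F1 outbred (CP) populations with known truth.

Meiosis follows a no-interference model consistent with the centimorgan
definition: per gamete the crossover count is Poisson(L/100) with positions
i.i.d. uniform on [0, L] cM, and the transmitted homolog at a marker is the
starting homolog flipped once per crossover to its left.

Selection is by rejection sampling so that linkage structure around the
selected locus stays exact:

* gametic — accepted gametes of the chosen parent carry homolog 1 at the
  selected position with probability ``t``;
* zygotic — zygotes survive with probability ``w(combo)`` where combo is the
  (maternal homolog, paternal homolog) pair at the selected position, keyed
  ``"M1P1"``, ``"M1P2"``, ``"M2P1"``, ``"M2P2"``.

Genotype codes are emitted under the phase convention of :mod:`sdrscan.io`:
the parental homolog ``phase + 1`` carries the marked allele (m/p/k).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import (
    BIPARENTAL,
    MATERNAL,
    PATERNAL,
    SEG_CLASSES,
    GenotypeMatrix,
    MarkerLocus,
)

COMBO_KEYS = ("M1P1", "M1P2", "M2P1", "M2P2")


class ConfigError(ValueError):
    """Invalid simulation design."""


@dataclass
class ChromosomeMap:
    chromosome: str
    length_cM: float
    length_Mb: float
    marker_cM: np.ndarray
    marker_Mb: np.ndarray

    def __post_init__(self) -> None:
        self.marker_cM = np.asarray(self.marker_cM, dtype=float)
        self.marker_Mb = np.asarray(self.marker_Mb, dtype=float)
        if self.length_cM < 0 or self.length_Mb < 0:
            raise ConfigError(f"{self.chromosome}: negative length")
        if np.any(np.diff(self.marker_cM) < 0):
            raise ConfigError(f"{self.chromosome}: marker cM not non-decreasing")
        if self.marker_cM.size and (
            self.marker_cM[-1] > self.length_cM + 1e-9 or self.marker_cM[0] < 0
        ):
            raise ConfigError(f"{self.chromosome}: marker cM outside [0, L]")

    @property
    def n_markers(self) -> int:
        return int(self.marker_cM.size)


def uniform_chromosome(
    name: str, length_cM: float, length_Mb: float, spacing_cM: float = 1.0
) -> ChromosomeMap:
    """Markers every ``spacing_cM`` from 0 to L, Mb proportional to cM."""
    if length_cM == 0:
        cs = np.array([0.0])
    else:
        cs = np.arange(0.0, length_cM + 1e-9, spacing_cM)
    mbs = cs / length_cM * length_Mb if length_cM > 0 else np.zeros_like(cs)
    return ChromosomeMap(name, length_cM, length_Mb, cs, mbs)


@dataclass
class SelectionSpec:
    """One selection pressure.

    ``gametic`` — rejection on the chosen parent's gamete at one position.
    ``zygotic`` — viability on the (maternal, paternal) homolog combo at
    one position.  ``zygotic_pair`` — viability on the maternal homolog at
    (chromosome, position_cM) crossed with the paternal homolog at
    (chromosome_b, position_cM_b), modelling a two-locus incompatibility.
    """

    kind: str  # "gametic" | "zygotic" | "zygotic_pair"
    chromosome: str
    position_cM: float
    parent: Optional[str] = None  # gametic: "maternal" | "paternal"
    t: Optional[float] = None  # gametic: P(homolog 1 transmitted)
    viability: Optional[dict[str, float]] = None  # zygotic: combo -> weight
    chromosome_b: Optional[str] = None  # zygotic_pair: paternal-side locus
    position_cM_b: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("gametic", "zygotic", "zygotic_pair"):
            raise ConfigError(f"unknown selection kind {self.kind!r}")
        if self.kind == "gametic":
            if self.parent not in (MATERNAL, PATERNAL):
                raise ConfigError("gametic selection needs parent maternal/paternal")
            if self.t is None or not (0.0 < self.t < 1.0):
                raise ConfigError("gametic transmission probability t must be in (0,1)")
            return
        if self.kind == "zygotic_pair" and (
            self.chromosome_b is None or self.position_cM_b is None
        ):
            raise ConfigError("zygotic_pair selection needs chromosome_b/position_cM_b")
        if not self.viability:
            raise ConfigError("zygotic selection needs viability weights")
        bad = set(self.viability) - set(COMBO_KEYS)
        if bad:
            raise ConfigError(f"unknown viability keys {sorted(bad)}")
        w = {k: float(self.viability.get(k, 1.0)) for k in COMBO_KEYS}
        if any(not (0.0 <= v <= 1.0) for v in w.values()):
            raise ConfigError("viability weights must be in [0,1]")
        if max(w.values()) == 0.0:
            raise ConfigError("impossible selection: all viability weights are 0")
        if max(w.values()) < 1.0:
            raise ConfigError("at least one viability weight must equal 1 (relative viability)")
        self.viability = w


@dataclass
class CrossDesign:
    maps: list[ChromosomeMap]
    n_progeny: int
    marker_classes: dict[str, list[str]]
    selections: list[SelectionSpec] = field(default_factory=list)
    seed: int = 0
    phase_policy: str = "zero"  # "zero" | "random"

    def __post_init__(self) -> None:
        if self.n_progeny <= 0:
            raise ConfigError("n_progeny must be positive")
        chroms = {m.chromosome for m in self.maps}
        for c, classes in self.marker_classes.items():
            cmap = self._map(c)
            if len(classes) != cmap.n_markers:
                raise ConfigError(f"{c}: {len(classes)} classes for {cmap.n_markers} markers")
            bad = set(classes) - set(SEG_CLASSES)
            if bad:
                raise ConfigError(f"{c}: unknown seg classes {sorted(bad)}")
        for s in self.selections:
            if s.chromosome not in chroms:
                raise ConfigError(f"selection references unknown chromosome {s.chromosome!r}")
            L = self._map(s.chromosome).length_cM
            if not (0.0 <= s.position_cM <= L):
                raise ConfigError(f"selection position {s.position_cM} outside [0, {L}]")
            if s.kind == "zygotic_pair":
                if s.chromosome_b not in chroms:
                    raise ConfigError(f"selection references unknown chromosome {s.chromosome_b!r}")
                Lb = self._map(s.chromosome_b).length_cM
                if not (0.0 <= s.position_cM_b <= Lb):
                    raise ConfigError(f"selection position {s.position_cM_b} outside [0, {Lb}]")

    def _map(self, chromosome: str) -> ChromosomeMap:
        for m in self.maps:
            if m.chromosome == chromosome:
                return m
        raise ConfigError(f"unknown chromosome {chromosome!r}")


def design_from_dict(cfg: dict) -> CrossDesign:
    """Build a design from a plain config mapping (the YAML CLI schema)."""
    maps, classes = [], {}
    for entry in cfg["chromosomes"]:
        name = entry["name"]
        cmap = uniform_chromosome(
            name,
            float(entry["length_cM"]),
            float(entry.get("length_Mb", entry["length_cM"])),
            float(entry.get("marker_spacing_cM", 1.0)),
        )
        maps.append(cmap)
        cls = entry.get("seg_class", "paternal")
        if isinstance(cls, str):
            if cls == "mixed":
                cycle = [MATERNAL, PATERNAL, BIPARENTAL]
                classes[name] = [cycle[i % 3] for i in range(cmap.n_markers)]
            else:
                classes[name] = [cls] * cmap.n_markers
        else:
            classes[name] = list(cls)
    selections = [
        SelectionSpec(
            kind=s["kind"],
            chromosome=s["chromosome"],
            position_cM=float(s["position_cM"]),
            parent=s.get("parent"),
            t=float(s["t"]) if "t" in s else None,
            viability={k: float(v) for k, v in s["viability"].items()}
            if "viability" in s
            else None,
            chromosome_b=s.get("chromosome_b"),
            position_cM_b=float(s["position_cM_b"]) if "position_cM_b" in s else None,
        )
        for s in cfg.get("selections", [])
    ]
    return CrossDesign(
        maps=maps,
        n_progeny=int(cfg["n_progeny"]),
        marker_classes=classes,
        selections=selections,
        seed=int(cfg.get("seed", 0)),
        phase_policy=cfg.get("phase_policy", "zero"),
    )


@dataclass
class TruthRecord:
    """Per-(chromosome, parent) transmitted-homolog indicators and crossovers.

    ``indicators[(chrom, parent)]`` is an (n_progeny, n_markers) array of
    1/2 homolog labels; ``crossovers[(chrom, parent)]`` is a list of sorted
    cM position arrays, one per progeny.
    """

    indicators: dict[tuple[str, str], np.ndarray]
    crossovers: dict[tuple[str, str], list[np.ndarray]]

    def homolog1_freq(self, chromosome: str, parent: str) -> np.ndarray:
        ind = self.indicators[(chromosome, parent)]
        return (ind == 1).mean(axis=0)

    def crossover_counts(self, chromosome: str, parent: str) -> np.ndarray:
        return np.array([len(x) for x in self.crossovers[(chromosome, parent)]])

    def total_crossovers(self) -> int:
        return int(sum(sum(len(x) for x in xs) for xs in self.crossovers.values()))

    def write(self, path: str | Path, progeny_ids: Sequence[str]) -> None:
        rows = []
        for (chrom, parent), ind in self.indicators.items():
            xos = self.crossovers[(chrom, parent)]
            for i, pid in enumerate(progeny_ids):
                rows.append(
                    {
                        "progeny_id": pid,
                        "chromosome": chrom,
                        "parent": parent,
                        "indicators": "".join(str(v) for v in ind[i]),
                        "crossovers_cM": ",".join(f"{x:.6g}" for x in xos[i]),
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gamete generation
# ---------------------------------------------------------------------------

def simulate_gametes(
    cmap: ChromosomeMap,
    n: int,
    rng: np.random.Generator,
    eval_cM: Optional[np.ndarray] = None,
):
    """Simulate ``n`` independent gametes for one chromosome.

    Returns ``(ind, eval_ind, crossovers)``: homolog indicators (1/2) at the
    chromosome's markers, indicators at the extra ``eval_cM`` positions (or
    None), and per-gamete sorted crossover positions.
    """
    L = cmap.length_cM
    k = rng.poisson(L / 100.0, n)
    kmax = int(k.max(initial=0))
    if kmax:
        pos = rng.uniform(0.0, L, size=(n, kmax))
        pos[np.arange(kmax)[None, :] >= k[:, None]] = np.inf
    else:
        pos = np.full((n, 0), np.inf)
    start = rng.integers(0, 2, size=n)

    def _ind_at(cs: np.ndarray) -> np.ndarray:
        if kmax:
            counts = (pos[:, :, None] < cs[None, None, :]).sum(axis=1)
        else:
            counts = np.zeros((n, cs.size), dtype=np.int64)
        return (1 + (start[:, None] + counts) % 2).astype(np.int8)

    ind = _ind_at(cmap.marker_cM)
    ev = _ind_at(np.asarray(eval_cM, dtype=float)) if eval_cM is not None else None
    crossovers = [np.sort(pos[i, : k[i]]) for i in range(n)]
    return ind, ev, crossovers


def simulate_gamete(cmap: ChromosomeMap, rng: np.random.Generator):
    """Single-gamete convenience wrapper: (indicator sequence, crossover cM)."""
    ind, _, xo = simulate_gametes(cmap, 1, rng)
    return ind[0], xo[0]


def gametic_acceptance_mask(
    hom_at_locus: np.ndarray, t: float, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sampling acceptance for gametic selection.

    Accepted gametes carry homolog 1 at the locus with probability ``t``.
    """
    if not (0.0 < t < 1.0):
        raise ConfigError("t must be in (0,1)")
    m = max(t, 1.0 - t)
    p = np.where(hom_at_locus == 1, t / m, (1.0 - t) / m)
    return rng.random(hom_at_locus.shape[0]) < p


def apply_gametic_selection(
    cmap: ChromosomeMap,
    n: int,
    spec: SelectionSpec,
    rng: np.random.Generator,
):
    """Generate ``n`` gametes subject to one gametic selection spec."""
    if spec.kind != "gametic":
        raise ConfigError("apply_gametic_selection needs a gametic spec")
    ind, _, xo = _selected_gametes(cmap, n, [spec], rng, eval_cM=None)
    return ind, xo


def _selected_gametes(
    cmap: ChromosomeMap,
    n: int,
    specs: Sequence[SelectionSpec],
    rng: np.random.Generator,
    eval_cM: Optional[np.ndarray] = None,
):
    """Generate exactly ``n`` gametes surviving the given gametic specs.

    With several specs on one chromosome the joint acceptance probability is
    the product of per-spec factors (each normalised by its max), so each
    spec's marginal holds exactly when the selected positions are unlinked
    and approximately otherwise.
    """
    n_eval = 0 if eval_cM is None else len(eval_cM)
    sel_cM = np.array([s.position_cM for s in specs], dtype=float)
    all_eval = np.concatenate([sel_cM, np.asarray(eval_cM, dtype=float) if n_eval else []])

    got_ind, got_ev, got_xo = [], [], []
    remaining = n
    while remaining > 0:
        batch = max(2 * remaining, 64)
        ind, ev, xo = simulate_gametes(cmap, batch, rng, eval_cM=all_eval)
        accept = np.ones(batch, dtype=bool)
        for i, s in enumerate(specs):
            accept &= gametic_acceptance_mask(ev[:, i], s.t, rng)
        idx = np.nonzero(accept)[0][:remaining]
        got_ind.append(ind[idx])
        got_ev.append(ev[idx, len(specs):])
        got_xo.extend(xo[i] for i in idx)
        remaining -= len(idx)
    ind = np.concatenate(got_ind, axis=0)
    ev = np.concatenate(got_ev, axis=0) if n_eval else None
    return ind, ev, got_xo


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------

def _codes_for_chromosome(
    classes: Sequence[str],
    phases_m: Sequence[Optional[int]],
    phases_p: Sequence[Optional[int]],
    mat_ind: np.ndarray,
    pat_ind: np.ndarray,
) -> np.ndarray:
    n = mat_ind.shape[0]
    out = np.empty((n, len(classes)), dtype="<U2")
    bip = np.array(["hh", "hk", "kk"])
    for j, cls in enumerate(classes):
        if cls == MATERNAL:
            out[:, j] = np.where(mat_ind[:, j] == phases_m[j] + 1, "lm", "ll")
        elif cls == PATERNAL:
            out[:, j] = np.where(pat_ind[:, j] == phases_p[j] + 1, "np", "nn")
        else:
            nk = (mat_ind[:, j] == phases_m[j] + 1).astype(int) + (
                pat_ind[:, j] == phases_p[j] + 1
            ).astype(int)
            out[:, j] = bip[nk]
    return out


def simulate_population(design: CrossDesign) -> tuple[GenotypeMatrix, TruthRecord]:
    """Simulate a full F1 population; reproducible for a fixed seed."""
    rng = np.random.default_rng(design.seed)

    # assign phases per chromosome/marker
    phases: dict[str, tuple[list, list]] = {}
    for cmap in design.maps:
        classes = design.marker_classes[cmap.chromosome]
        if design.phase_policy == "random":
            pm_draw = rng.integers(0, 2, cmap.n_markers)
            pp_draw = rng.integers(0, 2, cmap.n_markers)
        elif design.phase_policy == "zero":
            pm_draw = np.zeros(cmap.n_markers, dtype=int)
            pp_draw = np.zeros(cmap.n_markers, dtype=int)
        else:
            raise ConfigError(f"unknown phase_policy {design.phase_policy!r}")
        pm = [int(pm_draw[j]) if classes[j] in (MATERNAL, BIPARENTAL) else None
              for j in range(cmap.n_markers)]
        pp = [int(pp_draw[j]) if classes[j] in (PATERNAL, BIPARENTAL) else None
              for j in range(cmap.n_markers)]
        phases[cmap.chromosome] = (pm, pp)

    gametic = {
        (p, c): [s for s in design.selections
                 if s.kind == "gametic" and s.parent == p and s.chromosome == c]
        for p in (MATERNAL, PATERNAL)
        for c in (m.chromosome for m in design.maps)
    }
    zygotic = [s for s in design.selections if s.kind in ("zygotic", "zygotic_pair")]
    # registry of extra cM positions to evaluate per chromosome, and for each
    # zygotic spec the (chrom, index) of its maternal- and paternal-side locus
    eval_positions: dict[str, list[float]] = {}

    def _register(chrom: str, pos: float) -> int:
        lst = eval_positions.setdefault(chrom, [])
        lst.append(pos)
        return len(lst) - 1

    zyg_idx: list[tuple[str, int, str, int]] = []
    for s in zygotic:
        ia = _register(s.chromosome, s.position_cM)
        if s.kind == "zygotic":
            zyg_idx.append((s.chromosome, ia, s.chromosome, ia))
        else:
            ib = _register(s.chromosome_b, s.position_cM_b)
            zyg_idx.append((s.chromosome, ia, s.chromosome_b, ib))

    n = design.n_progeny
    acc_ind: dict[tuple[str, str], list[np.ndarray]] = {}
    acc_xo: dict[tuple[str, str], list[np.ndarray]] = {}
    for cmap in design.maps:
        for parent in (MATERNAL, PATERNAL):
            acc_ind[(cmap.chromosome, parent)] = []
            acc_xo[(cmap.chromosome, parent)] = []

    remaining = n
    while remaining > 0:
        batch = remaining if not zygotic else max(2 * remaining, 64)
        cand_ind: dict[tuple[str, str], np.ndarray] = {}
        cand_xo: dict[tuple[str, str], list[np.ndarray]] = {}
        zyg_ev: dict[tuple[str, str], np.ndarray] = {}
        for cmap in design.maps:
            extra = eval_positions.get(cmap.chromosome)
            eval_cM = np.array(extra) if extra else None
            for parent in (MATERNAL, PATERNAL):
                specs = gametic[(parent, cmap.chromosome)]
                if specs:
                    ind, ev, xo = _selected_gametes(cmap, batch, specs, rng, eval_cM=eval_cM)
                else:
                    ind, ev, xo = simulate_gametes(cmap, batch, rng, eval_cM=eval_cM)
                cand_ind[(cmap.chromosome, parent)] = ind
                cand_xo[(cmap.chromosome, parent)] = xo
                if extra:
                    zyg_ev[(cmap.chromosome, parent)] = ev

        if zygotic:
            surv = np.ones(batch, dtype=float)
            for s, (ca, ia, cb, ib) in zip(zygotic, zyg_idx):
                mat_ev = zyg_ev[(ca, MATERNAL)][:, ia]
                pat_ev = zyg_ev[(cb, PATERNAL)][:, ib]
                combo_idx = 2 * (mat_ev - 1) + (pat_ev - 1)
                w = np.array([s.viability[k] for k in COMBO_KEYS])
                surv *= w[combo_idx]
            keep = np.nonzero(rng.random(batch) < surv)[0][:remaining]
        else:
            keep = np.arange(batch)

        for key, ind in cand_ind.items():
            acc_ind[key].append(ind[keep])
            acc_xo[key].extend(cand_xo[key][i] for i in keep)
        remaining -= len(keep)

    indicators = {key: np.concatenate(chunks, axis=0) for key, chunks in acc_ind.items()}
    truth = TruthRecord(indicators=indicators, crossovers=acc_xo)

    # emit loci and genotype codes
    progeny_ids = [f"P{i + 1:04d}" for i in range(n)]
    loci: list[MarkerLocus] = []
    code_blocks: list[np.ndarray] = []
    for cmap in design.maps:
        classes = design.marker_classes[cmap.chromosome]
        pm, pp = phases[cmap.chromosome]
        for j in range(cmap.n_markers):
            loci.append(
                MarkerLocus(
                    marker_id=f"{cmap.chromosome}_m{j + 1:04d}",
                    chromosome=cmap.chromosome,
                    genetic_pos=float(cmap.marker_cM[j]),
                    physical_pos=float(cmap.marker_Mb[j]),
                    seg_class=classes[j],
                    phase_maternal=pm[j],
                    phase_paternal=pp[j],
                )
            )
        code_blocks.append(
            _codes_for_chromosome(
                classes, pm, pp,
                indicators[(cmap.chromosome, MATERNAL)],
                indicators[(cmap.chromosome, PATERNAL)],
            )
        )
    codes = pd.DataFrame(
        np.concatenate(code_blocks, axis=1).astype(object),
        index=progeny_ids,
        columns=[l.marker_id for l in loci],
    )
    matrix = GenotypeMatrix(progeny_ids=progeny_ids, loci=loci, codes=codes)
    return matrix, truth
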
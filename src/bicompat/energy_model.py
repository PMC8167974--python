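"""Pluggable loop-based energy models and a minimum-free-energy folder.

Three models are provided:

* ``zero`` -- every loop contributes 0 kcal/mol; partition functions reduce
  to counts of bicompatible sequences.
* ``arcpair`` -- a sequence-dependent toy model: a loop contributes a single
  term for its maximal arc, eps(GC) = -3.0, eps(AU) = -2.0, eps(GU) = -1.0
  kcal/mol; exterior loops contribute 0.
* ``turner`` -- a nearest-neighbor model read from the bundled plain-text
  parameter table: hairpin initiation by size plus terminal mismatch,
  stacking, bulge/interior initiation by size with mismatches and an
  asymmetry penalty, and an affine multiloop term a + b*branches +
  c*unpaired.  No dangling ends, no coaxial stacking, no tetraloop bonuses.

The thermal energy KT is fixed at 0.61633 kcal/mol (gas constant times
310.15 K).  All loop energies are finite for canonical assignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping, Sequence

from bicompat.bistructure_core import (
    CANONICAL_PAIRS,
    Loop,
    SecondaryStructure,
    _layer_loops,
)

KT = 0.61633  # kcal/mol at 310.15 K

#: interior/bulge loops larger than this are not considered by the mfe folder
MAX_TWOLOOP_UNPAIRED = 30

ARCPAIR_EPS = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}


class EnergyError(ValueError):
    """Non-canonical pair or missing assignment in an energy evaluation."""


@dataclass(frozen=True)
class EnergyResult:
    """Energies of a sequence against both layers; eta_B = (eta_R + eta_S)/2."""

    eta_R: float
    eta_S: float

    @property
    def eta_B(self) -> float:
        return 0.5 * (self.eta_R + self.eta_S)


def _pair(assignment: Mapping[int, str], i: int, j: int) -> tuple[str, str]:
    try:
        p = (assignment[i], assignment[j])
    except KeyError as exc:
        raise EnergyError(f"missing assignment for arc ({i}, {j})") from exc
    if p not in CANONICAL_PAIRS:
        raise EnergyError(f"non-canonical pair {p[0]}-{p[1]} on arc ({i}, {j})")
    return p


class EnergyModel:
    """Base class; subclasses define per-loop energies and their support.

    ``support(loop)`` lists the (real, 1-based) positions whose nucleotides
    the loop energy actually depends on; the dynamic program sums energy
    factors over exactly these positions.
    """

    name: str = "base"
    KT: float = KT

    def support(self, loop: Loop) -> tuple[int, ...]:
        raise NotImplementedError

    def loop_energy(self, loop: Loop, assignment: Mapping[int, str]) -> float:
        raise NotImplementedError


class ZeroModel(EnergyModel):
    """All loops contribute zero: the partition function counts sequences."""

    name = "zero"

    def support(self, loop: Loop) -> tuple[int, ...]:
        return ()

    def loop_energy(self, loop: Loop, assignment: Mapping[int, str]) -> float:
        return 0.0


class ArcPairModel(EnergyModel):
    """Each loop contributes eps(pair) of its maximal arc; exterior loops 0."""

    name = "arcpair"

    def support(self, loop: Loop) -> tuple[int, ...]:
        if loop.maximal_arc.is_rainbow:
            return ()
        return loop.maximal_arc.span

    def loop_energy(self, loop: Loop, assignment: Mapping[int, str]) -> float:
        arc = loop.maximal_arc
        if arc.is_rainbow:
            return 0.0
        return ARCPAIR_EPS[_pair(assignment, arc.i, arc.j)]


class TurnerModel(EnergyModel):
    """Nearest-neighbor loop energies from the bundled parameter tables."""

    name = "turner"

    def __init__(self, tables: dict | None = None) -> None:
        self.tables = tables if tables is not None else load_parameter_tables()
        self.KT = self.tables["constants"]["kt"]

    # -- table lookups ------------------------------------------------------

    def _stack(self, outer: tuple[str, str], inner: tuple[str, str]) -> float:
        return self.tables["stack"][("".join(outer), "".join(inner))]

    def _initiation(self, table: str, size: int) -> float:
        tab = self.tables[table]
        if size in tab:
            return tab[size]
        # logarithmic extrapolation beyond the tabulated sizes
        largest = max(tab)
        coef = self.tables["constants"]["long_loop_coef"]
        return tab[largest] + coef * math.log(size / largest)

    def _mismatch(self, pair: tuple[str, str], x: str, y: str) -> float:
        return self.tables["terminal_mismatch"][("".join(pair), x, y)]

    # -- per-loop energies --------------------------------------------------

    def support(self, loop: Loop) -> tuple[int, ...]:
        arc = loop.maximal_arc
        if arc.is_rainbow or loop.loop_type == "multiloop":
            return ()
        i, j = arc.span
        if loop.loop_type == "hairpin":
            verts = {i, j}
            if j - i - 1 >= 2:
                verts |= {i + 1, j - 1}
            return tuple(sorted(verts))
        (k, l) = loop.interior_arcs[0].span
        verts = {i, j, k, l}
        if loop.loop_type == "interior":
            verts |= {i + 1, j - 1, k - 1, l + 1}
        return tuple(sorted(verts))

    def loop_energy(self, loop: Loop, assignment: Mapping[int, str]) -> float:
        arc = loop.maximal_arc
        if arc.is_rainbow:
            return 0.0
        kind = loop.loop_type
        if kind == "multiloop":
            c = self.tables["constants"]
            branches = len(loop.interior_arcs) + 1  # closing arc included
            return (
                c["ml_closing"]
                + c["ml_branch"] * branches
                + c["ml_unpaired"] * len(loop.unpaired)
            )
        i, j = arc.span
        closing = _pair(assignment, i, j)
        if kind == "hairpin":
            size = j - i - 1
            e = self._initiation("hairpin_initiation", size)
            if size >= 2:
                e += self._mismatch(closing, assignment[i + 1], assignment[j - 1])
            return e
        k, l = loop.interior_arcs[0].span
        inner = _pair(assignment, k, l)
        s1, s2 = k - i - 1, j - l - 1
        if kind == "stack":
            return self._stack(closing, inner)
        if kind == "bulge":
            size = s1 + s2
            e = self._initiation("bulge_initiation", size)
            if size == 1:
                e += self._stack(closing, inner)
            return e
        # interior loop: initiation + asymmetry + both terminal mismatches
        c = self.tables["constants"]
        e = self._initiation("interior_initiation", s1 + s2)
        e += min(
            c["interior_asymmetry"] * abs(s1 - s2), c["interior_asymmetry_max"]
        )
        e += self._mismatch(closing, assignment[i + 1], assignment[j - 1])
        e += self._mismatch((inner[1], inner[0]), assignment[l + 1], assignment[k - 1])
        return e


def load_parameter_tables(text: str | None = None) -> dict:
    """Parse the plain-text parameter grammar into lookup tables."""
    if text is None:
        text = (
            resources.files("bicompat.data").joinpath("turner_params.txt").read_text()
        )
    tables: dict = {}
    section = None
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1]
            tables[section] = {}
            continue
        cols = line.split()
        if section == "constants":
            tables[section][cols[0]] = float(cols[1])
        elif section == "stack":
            tables[section][(cols[0], cols[1])] = float(cols[2])
        elif section in ("hairpin_initiation", "bulge_initiation", "interior_initiation"):
            tables[section][int(cols[0])] = float(cols[1])
        elif section == "terminal_mismatch":
            tables[section][(cols[0], cols[1], cols[2])] = float(cols[3])
        else:
            raise ValueError(f"unknown section {section!r}")
    return tables


_MODELS = {"zero": ZeroModel, "arcpair": ArcPairModel, "turner": TurnerModel}


@lru_cache(maxsize=None)
def get_model(name: str) -> EnergyModel:
    try:
        return _MODELS[name]()
    except KeyError:
        raise ValueError(f"unknown model {name!r}; have {sorted(_MODELS)}") from None


# ---------------------------------------------------------------------------
# structure energies
# ---------------------------------------------------------------------------


def _assignment_from_seq(seq: str) -> dict[int, str]:
    return {i: b for i, b in enumerate(seq, start=1)}


@lru_cache(maxsize=512)
def _cached_loops(struct: SecondaryStructure) -> tuple[Loop, ...]:
    return tuple(_layer_loops(struct, "R"))


def structure_energy(
    seq: str, struct: SecondaryStructure, model: EnergyModel
) -> float:
    """eta(sigma, R): the sum of loop energies over R's loop decomposition."""
    seq = seq.strip().upper().replace("T", "U")
    if len(seq) != struct.n:
        raise ValueError("sequence/structure length mismatch")
    assignment = _assignment_from_seq(seq)
    return sum(model.loop_energy(lp, assignment) for lp in _cached_loops(struct))


def bistructure_energy(seq: str, B, model: EnergyModel) -> EnergyResult:
    """Energies of seq against both layers of a bistructure."""
    return EnergyResult(
        eta_R=structure_energy(seq, B.structure_R, model),
        eta_S=structure_energy(seq, B.structure_S, model),
    )


# ---------------------------------------------------------------------------
# mfe folding (generic Zuker-style DP over the active model)
# ---------------------------------------------------------------------------


def _ml_coefs(model: EnergyModel, closing: tuple[str, str]) -> tuple[float, float, float]:
    """(base, per-branch, per-unpaired) multiloop coefficients for a model."""
    if isinstance(model, TurnerModel):
        c = model.tables["constants"]
        return c["ml_closing"] + c["ml_branch"], c["ml_branch"], c["ml_unpaired"]
    if isinstance(model, ArcPairModel):
        return ARCPAIR_EPS[closing], 0.0, 0.0
    return 0.0, 0.0, 0.0


def _hairpin_e(model: EnergyModel, seq: str, i: int, j: int) -> float:
    if isinstance(model, ZeroModel):
        return 0.0
    if isinstance(model, ArcPairModel):
        return ARCPAIR_EPS[(seq[i - 1], seq[j - 1])]
    size = j - i - 1
    e = model._initiation("hairpin_initiation", size)
    if size >= 2:
        e += model._mismatch((seq[i - 1], seq[j - 1]), seq[i], seq[j - 2])
    return e


def _twoloop_e(model: EnergyModel, seq: str, i: int, j: int, k: int, l: int) -> float:
    """Energy of the loop closed by (i,j) with single interior arc (k,l)."""
    if isinstance(model, ZeroModel):
        return 0.0
    if isinstance(model, ArcPairModel):
        return ARCPAIR_EPS[(seq[i - 1], seq[j - 1])]
    closing = (seq[i - 1], seq[j - 1])
    inner = (seq[k - 1], seq[l - 1])
    s1, s2 = k - i - 1, j - l - 1
    if s1 == 0 and s2 == 0:
        return model._stack(closing, inner)
    if s1 == 0 or s2 == 0:
        e = model._initiation("bulge_initiation", s1 + s2)
        if s1 + s2 == 1:
            e += model._stack(closing, inner)
        return e
    c = model.tables["constants"]
    e = model._initiation("interior_initiation", s1 + s2)
    e += min(c["interior_asymmetry"] * abs(s1 - s2), c["interior_asymmetry_max"])
    e += model._mismatch(closing, seq[i], seq[j - 2])
    e += model._mismatch((inner[1], inner[0]), seq[l], seq[k - 2])
    return e


INF = float("inf")


def mfe_fold(
    seq: str,
    model: EnergyModel,
    min_hairpin: int = 3,
) -> tuple[SecondaryStructure, float]:
    """Fold seq to a structure minimizing the model's loop-based energy.

    Zuker-style dynamic program: V(i,j) is the optimum given (i,j) paired,
    WM handles multiloop segments, W the exterior.  Interior/bulge loops are
    capped at 30 unpaired positions.  The traceback is deterministic: at the
    leftmost undecided position a pairing is preferred over leaving the
    position unpaired, and the smallest co-optimal partner is chosen.
    """
    seq = seq.strip().upper().replace("T", "U")
    n = len(seq)

    def can_pair(i: int, j: int) -> bool:
        return (seq[i - 1], seq[j - 1]) in CANONICAL_PAIRS and j - i - 1 >= min_hairpin

    V = [[INF] * (n + 2) for _ in range(n + 2)]
    WM = [[INF] * (n + 2) for _ in range(n + 2)]

    for span in range(min_hairpin + 1, n):
        for i in range(1, n - span + 1):
            j = i + span
            # V(i, j)
            if can_pair(i, j):
                best = _hairpin_e(model, seq, i, j)
                for k in range(i + 1, min(j, i + 2 + MAX_TWOLOOP_UNPAIRED)):
                    for l in range(k + min_hairpin + 1, j):
                        if (k - i - 1) + (j - l - 1) > MAX_TWOLOOP_UNPAIRED:
                            continue
                        if V[k][l] < INF and can_pair(k, l):
                            best = min(best, _twoloop_e(model, seq, i, j, k, l) + V[k][l])
                ml_base, ml_b, ml_c = _ml_coefs(model, (seq[i - 1], seq[j - 1]))
                for k in range(i + 1, j - 1):
                    if WM[i + 1][k] < INF and WM[k + 1][j - 1] < INF:
                        best = min(best, ml_base + WM[i + 1][k] + WM[k + 1][j - 1])
                V[i][j] = best
            # WM(i, j): >= 1 branch inside a multiloop
            _, ml_b, ml_c = _ml_coefs(model, ("A", "U"))
            cand = INF
            if V[i][j] < INF:
                cand = min(cand, V[i][j] + ml_b)
            if WM[i + 1][j] < INF:
                cand = min(cand, WM[i + 1][j] + ml_c)
            if WM[i][j - 1] < INF:
                cand = min(cand, WM[i][j - 1] + ml_c)
            for k in range(i + 1, j):
                if WM[i][k - 1] < INF and WM[k][j] < INF:
                    cand = min(cand, WM[i][k - 1] + WM[k][j])
            WM[i][j] = cand

    W = [0.0] * (n + 2)
    for j in range(1, n + 1):
        best = W[j - 1]
        for i in range(1, j):
            if V[i][j] < INF:
                best = min(best, W[i - 1] + V[i][j])
        W[j] = best

    arcs: set[tuple[int, int]] = set()

    def trace_V(i: int, j: int) -> None:
        arcs.add((i, j))
        e = V[i][j]
        if _eq(e, _hairpin_e(model, seq, i, j)):
            return
        for k in range(i + 1, j):
            for l in range(k + min_hairpin + 1, j):
                if (k - i - 1) + (j - l - 1) > MAX_TWOLOOP_UNPAIRED:
                    continue
                if V[k][l] < INF and can_pair(k, l):
                    if _eq(e, _twoloop_e(model, seq, i, j, k, l) + V[k][l]):
                        trace_V(k, l)
                        return
        ml_base, _, _ = _ml_coefs(model, (seq[i - 1], seq[j - 1]))
        for k in range(i + 1, j - 1):
            if WM[i + 1][k] < INF and WM[k + 1][j - 1] < INF:
                if _eq(e, ml_base + WM[i + 1][k] + WM[k + 1][j - 1]):
                    trace_WM(i + 1, k)
                    trace_WM(k + 1, j - 1)
                    return
        raise AssertionError("traceback failed in V")

    def trace_WM(i: int, j: int) -> None:
        e = WM[i][j]
        _, ml_b, ml_c = _ml_coefs(model, ("A", "U"))
        if V[i][j] < INF and _eq(e, V[i][j] + ml_b):
            trace_V(i, j)
            return
        for k in range(i + 1, j):
            if WM[i][k - 1] < INF and WM[k][j] < INF:
                if _eq(e, WM[i][k - 1] + WM[k][j]):
                    trace_WM(i, k - 1)
                    trace_WM(k, j)
                    return
        if WM[i + 1][j] < INF and _eq(e, WM[i + 1][j] + ml_c):
            trace_WM(i + 1, j)
            return
        if WM[i][j - 1] < INF and _eq(e, WM[i][j - 1] + ml_c):
            trace_WM(i, j - 1)
            return
        raise AssertionError("traceback failed in WM")

    def trace_W(j: int) -> None:
        while j >= 1:
            # prefer pairing ('(' sorts before '.'): smallest co-optimal i
            hit = None
            for i in range(1, j):
                if V[i][j] < INF and _eq(W[j], W[i - 1] + V[i][j]):
                    hit = i
                    break
            if hit is not None:
                trace_V(hit, j)
                j = hit - 1
            else:
                j -= 1

    trace_W(n)
    struct = SecondaryStructure(n=n, arcs=frozenset(arcs), min_hairpin=min_hairpin)
    return struct, W[n]


def _eq(a: float, b: float, tol: float = 1e-9) -> bool:
    return abs(a - b) <= tol
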
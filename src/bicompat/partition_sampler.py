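"""Partition functions over bicompatible sequences and Boltzmann sampling.

The dynamic program follows a loop-removal order bottom-up.  For a
substructure X with exposed vertices E^X, the table Q(X, tau_X) is indexed by
nucleotide assignments tau over E^X (positions ascending, bases keyed
A < C < G < U).  Removing loop L from X with child components X_1..X_k gives

    Q(X, tau_X) = sum over assignments of (L ∪ ⋃ E^{X_i}) \\ E^X of
                  w(L) * prod_i Q(X_i, tau_{X_i}),

where w(L) is the loop's Boltzmann factor and every non-rainbow arc of L
contributes a canonical-pairing constraint.  Tables are kept as numpy arrays
with one axis of length 4 per exposed position, normalized per step with an
exactly tracked log-offset so large instances cannot overflow.

The sampler runs the same recursion top-down: each sample draws the free
positions of every step by inverse-CDF from the step's conditional
distribution, using one deterministic uniform stream per sample index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from bicompat.bistructure_core import (
    CANONICAL_PAIRS,
    RNA_ALPHABET,
    Bistructure,
    Loop,
)
from bicompat.energy_model import EnergyModel, bistructure_energy
from bicompat.scheduler import RemovalOrder, schedule_general

#: 4x4 indicator of canonical pairs, rows/cols in A < C < G < U order
CONSTRAINT = np.array(
    [
        [1.0 if (a, b) in CANONICAL_PAIRS else 0.0 for b in RNA_ALPHABET]
        for a in RNA_ALPHABET
    ]
)

_SELECTOR_WEIGHTS = {"avg": (0.5, 0.5), "R_only": (1.0, 0.0), "S_only": (0.0, 1.0)}
_SIGNS = {"boltzmann": -1.0, "paper": +1.0}


@dataclass
class PartitionTable:
    """The DP result: per-substructure tables plus the total partition function.

    ``mantissa`` and ``log_offset`` give Q = mantissa * exp(log_offset); use
    ``log_value`` to stay in the log domain.
    """

    bistructure: Bistructure
    order: RemovalOrder
    model: EnergyModel
    selector: str
    scaling: str
    sign: str
    mantissa: float
    log_offset: float
    tables: dict[frozenset, tuple[np.ndarray, float]] = field(
        repr=False, default_factory=dict
    )
    keys: dict[frozenset, tuple[int, ...]] = field(repr=False, default_factory=dict)
    free: frozenset[int] = frozenset()

    @property
    def log_value(self) -> float:
        return math.log(self.mantissa) + self.log_offset

    @property
    def value(self) -> float:
        return self.mantissa * math.exp(self.log_offset)


@dataclass(frozen=True)
class SampleRecord:
    """One Boltzmann-sampled bicompatible sequence with its energies."""

    sequence: str
    eta_R: float
    eta_S: float
    eta_B: float
    seed_stream: int


def _real(vertices, n: int) -> tuple[int, ...]:
    return tuple(sorted(v for v in vertices if 1 <= v <= n))


def _coef(model: EnergyModel, loop: Loop, selector: str, scaling: str, sign: str, n: int) -> float:
    w = _SELECTOR_WEIGHTS[selector][0 if loop.layer == "R" else 1]
    scale = 1.0 / n if scaling == "1/n" else 1.0
    return _SIGNS[sign] * w * scale / model.KT


def _energy_factor(model: EnergyModel, loop: Loop, coef: float):
    """Boltzmann factor of one loop over its support positions.

    Returns (support, array with one length-4 axis per support position);
    assignments violating a support arc are left at 1.0 (the separate
    constraint factors zero them).  A support-free loop gives a scalar.
    """
    supp = model.support(loop)
    if coef == 0.0:
        return (), np.float64(1.0)
    if not supp:
        return (), np.float64(math.exp(coef * model.loop_energy(loop, {})))
    supp_set = set(supp)
    arcs = [a for a in loop.arcs if not a.is_rainbow and {a.i, a.j} <= supp_set]
    arr = np.ones((4,) * len(supp))
    for idx in np.ndindex(arr.shape):
        assignment = {v: RNA_ALPHABET[b] for v, b in zip(supp, idx)}
        if all(
            (assignment[a.i], assignment[a.j]) in CANONICAL_PAIRS for a in arcs
        ):
            arr[idx] = math.exp(coef * model.loop_energy(loop, assignment))
    return supp, arr


def _broadcast(arr: np.ndarray, axes: Sequence[int], U: Sequence[int]) -> np.ndarray:
    """Reshape an array whose axes are `axes` (ascending) into the U axis frame."""
    pos = {v: k for k, v in enumerate(U)}
    shape = [1] * len(U)
    for v in axes:
        shape[pos[v]] = 4
    return arr.reshape(shape)


def _needed_vertices(model: EnergyModel, loop: Loop, n: int) -> frozenset[int]:
    """Real positions the loop's factors read: energy support + arc endpoints."""
    verts = set(model.support(loop))
    for a in loop.arcs:
        if not a.is_rainbow:
            verts.update(a.span)
    return frozenset(v for v in verts if 1 <= v <= n)


def _assign_keys(
    B: Bistructure, order: RemovalOrder, model: EnergyModel
) -> tuple[dict[frozenset, tuple[int, ...]], frozenset[int]]:
    """Table keys per substructure, plus the globally unconstrained positions.

    A table for substructure X is keyed by the positions of X still read by
    factors applied above X (the energy supports and pairing constraints of
    already-removed loops); everything else is summed as early as possible.
    Positions no loop ever reads contribute an exact factor of 4 each.
    """
    n = B.n
    keys: dict[frozenset, tuple[int, ...]] = {
        order.steps[0].substructure_before.loop_ids: ()
    }
    for step in order.steps:
        loop = B.loop_by_id[step.removed_loop_id]
        carried = set(keys[step.substructure_before.loop_ids]) | _needed_vertices(
            model, loop, n
        )
        for child in step.child_components:
            keys[child.loop_ids] = tuple(sorted(carried & child.vertex_set))
    touched = frozenset().union(
        *(_needed_vertices(model, lp, n) for lp in B.loops)
    )
    free = frozenset(range(1, n + 1)) - touched
    return keys, free


def _step_array(B, model, step, tables, keys, selector, scaling, sign):
    """Joint weight array over the step's live positions, before summation.

    Axes (ascending positions) carry the parent's key positions, the removed
    loop's needed positions and the child tables' key positions; the array is
    the product of the loop's Boltzmann factor, the pairing constraints of
    all its non-rainbow arcs, and the (normalized) child tables.
    """
    n = B.n
    loop = B.loop_by_id[step.removed_loop_id]
    K_X = keys[step.substructure_before.loop_ids]
    live = set(K_X) | _needed_vertices(model, loop, n)
    for child in step.child_components:
        live |= set(keys[child.loop_ids])
    U = tuple(sorted(live))
    arr = np.ones((4,) * len(U))
    child_log = 0.0
    for child in step.child_components:
        key_axes = keys[child.loop_ids]
        tbl, log_off = tables[child.loop_ids]
        arr = arr * _broadcast(tbl, key_axes, U)
        child_log += log_off
    for a in loop.arcs:
        if not a.is_rainbow:
            arr = arr * _broadcast(CONSTRAINT, (a.i, a.j), U)
    coef = _coef(model, loop, selector, scaling, sign, n)
    supp, factor = _energy_factor(model, loop, coef)
    if supp:
        arr = arr * _broadcast(factor, supp, U)
    else:
        arr = arr * factor
    return U, K_X, arr, child_log


def partition(
    B: Bistructure,
    order: RemovalOrder,
    model: EnergyModel,
    selector: str = "avg",
    scaling: str = "1",
    sign: str = "boltzmann",
) -> PartitionTable:
    """Compute the partition function over bicompatible sequences of B.

    ``selector`` weights the loop energies: 'avg' gives eta(sigma, B) =
    (eta_R + eta_S)/2, 'R_only'/'S_only' give Q(R)|_S and Q(S)|_R (the sum
    still runs over bicompatible sequences only).  ``scaling`` '1/n' divides
    energies by n (the scaled partition function); ``sign`` 'paper' flips the
    exponent's sign.  The result is strictly positive for every valid
    bistructure, since bicompatible sequences always exist.
    """
    if selector not in _SELECTOR_WEIGHTS:
        raise ValueError(f"unknown selector {selector!r}")
    n = B.n
    keys, free = _assign_keys(B, order, model)
    tables: dict[frozenset, tuple[np.ndarray, float]] = {}
    summed: set[int] = set()
    for step in reversed(order.steps):
        U, K_X, arr, child_log = _step_array(
            B, model, step, tables, keys, selector, scaling, sign
        )
        F = [v for v in U if v not in set(K_X)]
        if summed.intersection(F):
            raise AssertionError(f"positions summed twice: {sorted(summed & set(F))}")
        summed.update(F)
        sum_axes = tuple(k for k, v in enumerate(U) if v in set(F))
        tbl = arr.sum(axis=sum_axes) if sum_axes else arr
        peak = float(tbl.max()) if tbl.size else float(tbl)
        if peak <= 0.0:
            raise ArithmeticError("partition table vanished; invalid bistructure?")
        tbl = tbl / peak
        tables[step.substructure_before.loop_ids] = (tbl, math.log(peak) + child_log)
    if summed | free != set(range(1, n + 1)) or summed & free:
        raise AssertionError("positions not resolved exactly once")
    root_key = order.steps[0].substructure_before.loop_ids
    root_tbl, root_log = tables[root_key]
    return PartitionTable(
        bistructure=B,
        order=order,
        model=model,
        selector=selector,
        scaling=scaling,
        sign=sign,
        mantissa=float(root_tbl),
        log_offset=root_log + len(free) * math.log(4.0),
        tables=tables,
        keys=keys,
        free=free,
    )


def sample(
    B: Bistructure,
    order: RemovalOrder,
    table: PartitionTable,
    m: int,
    seed: int,
) -> list[SampleRecord]:
    """Draw m sequences with P(sigma) = exp(-eta(sigma)/KT) / Q by backtracking.

    One uniform variate per sample per step, taken from a per-sample-index
    substream, makes the output reproducible for a fixed seed regardless of
    evaluation order.  Linear time per sample in the number of steps.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    n = B.n
    model = table.model
    steps = order.steps
    rng = np.random.default_rng(seed)
    uniforms = rng.random((m, len(steps)))
    free = sorted(table.free)
    free_draws = rng.random((m, len(free)))
    codes = np.full((m, n + 2), -1, dtype=np.int8)
    for t, step in enumerate(steps):
        U, K_X, arr, _ = _step_array(
            B, model, step, table.tables, table.keys,
            table.selector, table.scaling, table.sign,
        )
        F = [v for v in U if v not in set(K_X)]
        if not F:
            continue
        # move key axes first, drawn axes last; flatten both groups
        perm = [U.index(v) for v in K_X] + [U.index(v) for v in F]
        flat = arr.transpose(perm).reshape(4 ** len(K_X), 4 ** len(F))
        if K_X:
            radix = 4 ** np.arange(len(K_X) - 1, -1, -1, dtype=np.int64)
            ctx = codes[:, list(K_X)].astype(np.int64) @ radix
        else:
            ctx = np.zeros(m, dtype=np.int64)
        draw = np.empty(m, dtype=np.int64)
        for key in np.unique(ctx):
            row = flat[key]
            total = row.sum()
            if total <= 0:
                raise ArithmeticError("conditional distribution vanished")
            cdf = np.cumsum(row) / total
            sel = ctx == key
            draw[sel] = np.searchsorted(cdf, uniforms[sel, t], side="right")
        digits = np.stack(np.unravel_index(draw, (4,) * len(F)), axis=1)
        codes[:, F] = digits.astype(np.int8)
    if free:
        codes[:, free] = np.minimum((free_draws * 4).astype(np.int8), 3)
    records = []
    lut = np.array(list(RNA_ALPHABET))
    for i in range(m):
        seq = "".join(lut[codes[i, 1 : n + 1]])
        e = bistructure_energy(seq, B, model)
        records.append(
            SampleRecord(
                sequence=seq,
                eta_R=e.eta_R,
                eta_S=e.eta_S,
                eta_B=e.eta_B,
                seed_stream=i,
            )
        )
    return records


def compute_partition(
    B: Bistructure,
    model: EnergyModel,
    selector: str = "avg",
    scaling: str = "1",
    sign: str = "boltzmann",
    kappa_cap: int = 20,
) -> PartitionTable:
    """Schedule B (overlap split + greedy spheres) and run the DP."""
    order = schedule_general(B, kappa_cap=kappa_cap)
    return partition(B, order, model, selector=selector, scaling=scaling, sign=sign)


def restricted_partitions(
    B: Bistructure,
    model: EnergyModel,
    scaling: str = "1",
    sign: str = "boltzmann",
    kappa_cap: int = 20,
) -> dict[str, PartitionTable]:
    """Q(R), Q(S) over single-structure compatible sequences, and the
    restrictions Q(R)|_S, Q(S)|_R over bicompatible sequences.

    Q(R) is computed on the single-layer bistructure (S replaced by the
    arc-free structure), so the sum runs over R-compatible sequences;
    Q(R)|_S <= Q(R) always holds since restriction shrinks the domain.
    """
    from bicompat.bistructure_core import SecondaryStructure, build_bistructure

    empty = SecondaryStructure(B.n, frozenset(), min_hairpin=0)
    B_R = build_bistructure(B.structure_R, empty)
    B_S = build_bistructure(empty, B.structure_S)
    kw = dict(scaling=scaling, sign=sign, kappa_cap=kappa_cap)
    return {
        "Q_R": compute_partition(B_R, model, selector="R_only", **kw),
        "Q_S": compute_partition(B_S, model, selector="S_only", **kw),
        "Q_R_given_S": compute_partition(B, model, selector="R_only", **kw),
        "Q_S_given_R": compute_partition(B, model, selector="S_only", **kw),
    }
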
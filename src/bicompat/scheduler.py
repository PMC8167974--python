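"""Loop-removal schedules for the partition-function dynamic program.

A decomposition removes loops one at a time; after each removal the remaining
loops fall apart into irreducible components.  The step cost
|L ∪ ⋃_i E^{X_i}| counts the positions whose nucleotides must be held
simultaneously, and kappa, the maximum step cost, governs the 4^kappa factor
in the DP complexity.

For crossing-free, overlap-free bistructures, removing the loop whose maximal
arc is maximal under the nesting order (rainbows on top, R before S on ties)
is provably kappa-optimal.  In the general case overlaps are split first and
crossing components ("spheres") are resolved by a greedy rule that removes
the cheapest loop of a crossing component at each step.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Sequence

from bicompat.bistructure_core import Arc, Bistructure, Substructure
from bicompat.loop_nerve import _overlaps, split_overlaps


class KappaExceeded(RuntimeError):
    """The schedule's kappa exceeds the configured cap: instance too hard."""


DEFAULT_KAPPA_CAP = 20


@dataclass(frozen=True)
class RemovalStep:
    removed_loop_id: str
    substructure_before: Substructure
    child_components: tuple[Substructure, ...]
    step_cost: int


@dataclass(frozen=True)
class RemovalOrder:
    """An ordered loop removal with per-step components and costs."""

    bistructure: Bistructure
    steps: tuple[RemovalStep, ...]

    @property
    def kappa(self) -> int:
        return max(s.step_cost for s in self.steps)

    @property
    def sequence(self) -> tuple[str, ...]:
        return tuple(s.removed_loop_id for s in self.steps)


def _components_of(
    ids: frozenset[str], vertices: dict[str, frozenset[int]]
) -> list[frozenset[str]]:
    """Finest partition of a loop-id set into vertex-disjoint parts."""
    ids_sorted = sorted(ids)
    parent = {i: i for i in ids_sorted}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, a in enumerate(ids_sorted):
        for b in ids_sorted[k + 1 :]:
            if vertices[a] & vertices[b]:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    groups: dict[str, set[str]] = {}
    for i in ids_sorted:
        groups.setdefault(find(i), set()).add(i)
    return sorted((frozenset(g) for g in groups.values()), key=min)


def _exposed_within(
    child: frozenset[str],
    parent: frozenset[str],
    vertices: dict[str, frozenset[int]],
) -> frozenset[int]:
    """Vertices of `child` shared with the rest of `parent`.

    Exposure is counted against the substructure currently being decomposed:
    loops already removed no longer hold any position, which is the
    accounting under which the nesting-order schedule is kappa-optimal.
    """
    v_child: set[int] = set()
    for i in child:
        v_child |= vertices[i]
    v_rest: set[int] = set()
    for i in parent - child:
        v_rest |= vertices[i]
    return frozenset(v_child & v_rest)


def _loop_tables(B: Bistructure):
    vertices = {lp.id: lp.vertices for lp in B.loops}
    containing: dict[int, set[str]] = {}
    for lp in B.loops:
        for v in lp.vertices:
            containing.setdefault(v, set()).add(lp.id)
    return vertices, {v: frozenset(s) for v, s in containing.items()}


def order_from_sequence(B: Bistructure, seq: Sequence[str]) -> RemovalOrder:
    """Replay an arbitrary removal sequence and account its per-step costs.

    Any permutation of the loop ids is a valid decomposition; at each step
    the next loop is removed from whichever component currently contains it.
    """
    vertices, _ = _loop_tables(B)
    all_ids = frozenset(vertices)
    if set(seq) != all_ids or len(seq) != len(all_ids):
        raise ValueError("sequence must remove every loop exactly once")
    comps = _components_of(all_ids, vertices)
    steps: list[RemovalStep] = []
    for lid in seq:
        X = next(c for c in comps if lid in c)
        children = _components_of(X - {lid}, vertices) if len(X) > 1 else []
        held = set(vertices[lid])
        for child in children:
            held |= _exposed_within(child, X, vertices)
        steps.append(
            RemovalStep(
                removed_loop_id=lid,
                substructure_before=Substructure(B, X),
                child_components=tuple(Substructure(B, c) for c in children),
                step_cost=len(held),
            )
        )
        comps.remove(X)
        comps.extend(children)
    return RemovalOrder(bistructure=B, steps=tuple(steps))


# ---------------------------------------------------------------------------
# the nesting order and the noncrossing schedule
# ---------------------------------------------------------------------------


def _covers(a: Arc, b: Arc) -> bool:
    """a strictly contains b; identical spans (the two rainbows) are incomparable."""
    if (a.i, a.j) == (b.i, b.j):
        return False
    return a.i <= b.i and b.j <= a.j


def _maximal_loop(
    B: Bistructure, ids: Iterable[str], rainbow_layer: str = "R"
) -> str:
    """Loop of the component whose maximal arc tops the nesting order.

    The only possible tie is between the two rainbows (identical spans);
    ``rainbow_layer`` picks which exterior loop wins it.
    """
    loops = [B.loop_by_id[i] for i in ids]
    tops = [
        lp
        for lp in loops
        if not any(
            _covers(other.maximal_arc, lp.maximal_arc)
            for other in loops
            if other.id != lp.id
        )
    ]
    order = (rainbow_layer, "S" if rainbow_layer == "R" else "R")
    tops.sort(
        key=lambda lp: (lp.maximal_arc.i, -lp.maximal_arc.j, order.index(lp.layer))
    )
    return tops[0].id


def _has_crossing(B: Bistructure, ids: frozenset[str]) -> bool:
    arcs = [B.loop_by_id[i].maximal_arc for i in ids]
    return any(
        a.crosses(b) for k, a in enumerate(arcs) for b in arcs[k + 1 :]
    )


def schedule_noncrossing(B: Bistructure) -> RemovalOrder:
    """The kappa-optimal removal order for crossing-free, overlap-free input.

    Recursively removes, within each irreducible component, the loop whose
    maximal arc is maximal under the nesting order.  The two rainbows share
    a span and are the single incomparable pair, so both resolutions of that
    tie are evaluated and the cheaper schedule kept (R first on kappa ties).
    """
    if _overlaps(B):
        raise ValueError("bistructure has overlaps; use schedule_general")
    arcs = B.nonrainbow_arcs
    if any(a.crosses(b) for k, a in enumerate(arcs) for b in arcs[k + 1 :]):
        raise ValueError("bistructure has crossing arcs; use schedule_general")
    vertices, _ = _loop_tables(B)

    def build(rainbow_layer: str) -> RemovalOrder:
        seq: list[str] = []

        def descend(ids: frozenset[str]) -> None:
            lid = _maximal_loop(B, ids, rainbow_layer)
            seq.append(lid)
            for child in _components_of(ids - {lid}, vertices):
                descend(child)

        for comp in _components_of(frozenset(vertices), vertices):
            descend(comp)
        return order_from_sequence(B, seq)

    order_r, order_s = build("R"), build("S")
    return order_r if order_r.kappa <= order_s.kappa else order_s


# ---------------------------------------------------------------------------
# general scheduling: overlap splitting + greedy sphere resolution
# ---------------------------------------------------------------------------


def _split_loop_correspondence(
    B: Bistructure, B_split: Bistructure, vertex_map: dict[int, tuple[int, ...]]
) -> dict[str, str]:
    """Map split-bistructure loop ids back to original loop ids."""
    back: dict[str, str] = {}
    for lp in B.loops:
        a = lp.maximal_arc
        if a.is_rainbow:
            img = next(
                sp
                for sp in B_split.loops
                if sp.layer == lp.layer and sp.maximal_arc.is_rainbow
            )
        else:
            cand_i, cand_j = vertex_map[a.i], vertex_map[a.j]
            img = next(
                sp
                for sp in B_split.loops
                if sp.layer == lp.layer
                and not sp.maximal_arc.is_rainbow
                and sp.maximal_arc.i in cand_i
                and sp.maximal_arc.j in cand_j
            )
        back[img.id] = lp.id
    return back


def schedule_general(
    B: Bistructure, kappa_cap: int = DEFAULT_KAPPA_CAP
) -> RemovalOrder:
    """Schedule any bistructure: split overlaps, then greedy sphere resolution.

    While a component still contains crossing maximal arcs, the loop of a
    crossing pair whose removal costs least is taken (ties: leftmost maximal
    arc, then layer R before S); crossing-free components fall back to the
    optimal nesting-order rule.  Raises :class:`KappaExceeded` when the
    resulting kappa exceeds ``kappa_cap``.
    """
    B2, vertex_map = split_overlaps(B)
    back = (
        _split_loop_correspondence(B, B2, vertex_map)
        if B2 is not B
        else {lp.id: lp.id for lp in B.loops}
    )
    vertices, _ = _loop_tables(B2)
    seq2: list[str] = []

    def crossing_loop_ids(ids: frozenset[str]) -> list[str]:
        loops = [B2.loop_by_id[i] for i in ids]
        out = set()
        for k, a in enumerate(loops):
            for b in loops[k + 1 :]:
                if a.maximal_arc.crosses(b.maximal_arc):
                    out.update((a.id, b.id))
        return sorted(out)

    def step_cost(ids: frozenset[str], lid: str) -> int:
        held = set(vertices[lid])
        for child in _components_of(ids - {lid}, vertices) if len(ids) > 1 else []:
            held |= _exposed_within(child, ids, vertices)
        return len(held)

    def descend(ids: frozenset[str]) -> None:
        in_crossings = crossing_loop_ids(ids)
        if in_crossings:
            lid = min(
                in_crossings,
                key=lambda i: (
                    step_cost(ids, i),
                    B2.loop_by_id[i].maximal_arc.span,
                    B2.loop_by_id[i].layer,
                ),
            )
        else:
            lid = _maximal_loop(B2, ids)
        seq2.append(lid)
        for child in _components_of(ids - {lid}, vertices):
            descend(child)

    for comp in _components_of(frozenset(vertices), vertices):
        descend(comp)
    order = order_from_sequence(B, [back[i] for i in seq2])
    if order.kappa > kappa_cap:
        raise KappaExceeded(
            f"kappa {order.kappa} exceeds cap {kappa_cap}; instance too hard"
        )
    return order


def exhaustive_min_kappa(B: Bistructure, max_loops: int = 8) -> int:
    """Brute-force minimum of kappa over all removal orders (test oracle)."""
    ids = sorted(lp.id for lp in B.loops)
    if len(ids) > max_loops:
        raise ValueError(f"{len(ids)} loops exceed limit {max_loops}")
    best = None
    for perm in permutations(ids):
        kappa = order_from_sequence(B, perm).kappa
        if best is None or kappa < best:
            best = kappa
    return best
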
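"""Brute-force oracles and fixture generators used to test every other module.

Nothing here is used on the production path: the enumeration, walk-count and
literal-sum routines are deliberately independent of the dynamic program they
validate.

Named fixtures (all built with min_hairpin=0 so formal hairpins are legal):

* ``WEX`` -- the small worked example: n=8, R-arcs (1,4),(2,3),(5,7) and
  S-arc (6,8); its two layers yield six loops and one crossing.
* ``P3`` -- n=3 with R-arc (1,2) and S-arc (2,3): a 3-vertex constraint path.
* ``C4`` -- n=4 with R-arcs (1,2),(3,4) and S-arcs (1,4),(2,3): a 4-cycle of
  pairing constraints in which every vertex is an overlap.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from bicompat.bistructure_core import (
    CANONICAL_PAIRS,
    RNA_ALPHABET,
    Bistructure,
    SecondaryStructure,
    StructureError,
    build_bistructure,
)

#: adjacency of the 6-edge nucleotide pairing graph on {A, C, G, U}
PAIRING_ADJACENCY = np.array(
    [[1 if (a, b) in CANONICAL_PAIRS else 0 for b in RNA_ALPHABET] for a in RNA_ALPHABET]
)


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    n: int
    arcs_R: frozenset[tuple[int, int]]
    arcs_S: frozenset[tuple[int, int]]
    notes: str = ""

    def build(self) -> Bistructure:
        R = SecondaryStructure(self.n, self.arcs_R, min_hairpin=0)
        S = SecondaryStructure(self.n, self.arcs_S, min_hairpin=0)
        return build_bistructure(R, S)


FIXTURES: dict[str, FixtureSpec] = {
    "WEX": FixtureSpec(
        "WEX",
        8,
        frozenset({(1, 4), (2, 3), (5, 7)}),
        frozenset({(6, 8)}),
        "six-loop worked example with a single crossing (5,7)_R x (6,8)_S",
    ),
    "P3": FixtureSpec(
        "P3",
        3,
        frozenset({(1, 2)}),
        frozenset({(2, 3)}),
        "three-vertex constraint path; 10 bicompatible sequences",
    ),
    "C4": FixtureSpec(
        "C4",
        4,
        frozenset({(1, 2), (3, 4)}),
        frozenset({(1, 4), (2, 3)}),
        "four-cycle of constraints, every vertex an overlap; 14 sequences",
    ),
}


def load_fixture(name: str) -> Bistructure:
    try:
        return FIXTURES[name].build()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; have {sorted(FIXTURES)}") from None


# ---------------------------------------------------------------------------
# bicompatible-sequence enumeration
# ---------------------------------------------------------------------------


def _constraint_components(B: Bistructure) -> list[tuple[list[int], bool]]:
    """Connected components of the pairing-constraint graph (positions 1..n).

    Arcs of both layers are edges (deduplicated when R and S impose the same
    pair).  Each vertex has degree <= 2, so components are paths or cycles.
    Returns (walk order along the component, is_cycle) pairs.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(1, B.n + 1))
    g.add_edges_from(a.span for a in B.nonrainbow_arcs)
    comps: list[tuple[list[int], bool]] = []
    for nodes in sorted(nx.connected_components(g), key=min):
        sub = g.subgraph(nodes)
        is_cycle = len(nodes) >= 3 and all(d == 2 for _, d in sub.degree())
        if is_cycle:
            start = min(nodes)
        else:
            start = min(v for v, d in sub.degree() if d <= 1)
        order = [start]
        prev = None
        while len(order) < len(nodes):
            nxt = [u for u in sub.neighbors(order[-1]) if u != prev]
            prev = order[-1]
            order.append(min(nxt))
        comps.append((order, is_cycle))
    return comps


def _component_assignments(order: list[int], is_cycle: bool) -> list[str]:
    """All base assignments along a path/cycle respecting pairing adjacency."""
    out: list[str] = []

    def extend(partial: str) -> None:
        k = len(partial)
        if k == len(order):
            if is_cycle and (partial[-1], partial[0]) not in CANONICAL_PAIRS:
                return
            out.append(partial)
            return
        for b in RNA_ALPHABET:
            if k == 0 or (partial[-1], b) in CANONICAL_PAIRS:
                extend(partial + b)

    # isolated vertices have no adjacency constraint at all
    if len(order) == 1:
        return list(RNA_ALPHABET)
    extend("")
    return out


def count_bicompatible_walks(B: Bistructure) -> int:
    """Count bicompatible sequences as a product of walk counts per component.

    Paths with k edges contribute 1^T P^k 1 and cycles of length k contribute
    tr(P^k), where P is the pairing-graph adjacency matrix.
    """
    total = 1
    for order, is_cycle in _constraint_components(B):
        if is_cycle:
            Pc = np.linalg.matrix_power(PAIRING_ADJACENCY, len(order))
            total *= int(np.trace(Pc))
        else:
            P = np.linalg.matrix_power(PAIRING_ADJACENCY, len(order) - 1)
            total *= int(P.sum())
    return total


def enumerate_bicompatible(
    B: Bistructure, limit_n: int = 12
) -> tuple[int, Iterator[str]]:
    """Count and lazily enumerate all bicompatible sequences of B.

    Raises if n exceeds ``limit_n``.  The count is the component-pruned walk
    count; the iterator assembles sequences component by component.
    """
    if B.n > limit_n:
        raise ValueError(f"n={B.n} exceeds enumeration limit {limit_n}")
    per_comp = [
        (order, _component_assignments(order, is_cycle))
        for order, is_cycle in _constraint_components(B)
    ]
    count = 1
    for _, assigns in per_comp:
        count *= len(assigns)

    def gen() -> Iterator[str]:
        for combo in itertools.product(*(a for _, a in per_comp)):
            chars = [""] * B.n
            for (order, _), assign in zip(per_comp, combo):
                for pos, base in zip(order, assign):
                    chars[pos - 1] = base
            yield "".join(chars)

    return count, gen()


def raw_scan_count(B: Bistructure) -> int:
    """Literal 4^n scan (n <= 8): the most naive possible bicompatibility count."""
    if B.n > 8:
        raise ValueError("raw scan capped at n <= 8")
    pairs = [(a.i - 1, a.j - 1) for a in B.nonrainbow_arcs]
    count = 0
    for seq in itertools.product(RNA_ALPHABET, repeat=B.n):
        if all((seq[i], seq[j]) in CANONICAL_PAIRS for i, j in pairs):
            count += 1
    return count


# ---------------------------------------------------------------------------
# literal partition-function sums
# ---------------------------------------------------------------------------


def brute_partition(
    B: Bistructure,
    model,
    selector: str = "avg",
    scaling: float = 1.0,
    sign: float = -1.0,
) -> float:
    """Literal sum over enumerated bicompatible sequences of exp(sign*scale*eta/KT).

    ``selector`` picks eta(sigma, B) (avg), eta(sigma, R) (R_only) or
    eta(sigma, S) (S_only).  Capped at n <= 10.
    """
    from bicompat.energy_model import structure_energy

    if B.n > 10:
        raise ValueError("brute-force partition capped at n <= 10")
    _, seqs = enumerate_bicompatible(B, limit_n=10)
    total = 0.0
    for seq in seqs:
        eta_R = structure_energy(seq, B.structure_R, model)
        eta_S = structure_energy(seq, B.structure_S, model)
        if selector == "avg":
            eta = 0.5 * (eta_R + eta_S)
        elif selector == "R_only":
            eta = eta_R
        elif selector == "S_only":
            eta = eta_S
        else:
            raise ValueError(f"unknown selector {selector!r}")
        total += math.exp(sign * scaling * eta / model.KT)
    return total


# ---------------------------------------------------------------------------
# random bistructures
# ---------------------------------------------------------------------------


def _random_layer(
    rng: np.random.Generator,
    n: int,
    max_arcs: int,
    min_hairpin: int,
    forbidden_endpoints: frozenset[int],
    existing: list[tuple[int, int]],
    allow_crossing: bool,
    tries: int = 200,
) -> frozenset[tuple[int, int]]:
    arcs: list[tuple[int, int]] = []
    paired: set[int] = set()
    target = int(rng.integers(0, max_arcs + 1))
    for _ in range(tries):
        if len(arcs) >= target:
            break
        i = int(rng.integers(1, n))
        j = int(rng.integers(i + 1, n + 1))
        if i in paired or j in paired:
            continue
        if i in forbidden_endpoints or j in forbidden_endpoints:
            continue
        if any(a < i < b < j or i < a < j < b for a, b in arcs):
            continue
        if not any(i < a and b < j for a, b in arcs) and j - i - 1 < min_hairpin:
            continue
        if not allow_crossing and any(
            a < i < b < j or i < a < j < b for a, b in existing
        ):
            continue
        arcs.append((i, j))
        paired.update((i, j))
    return frozenset(arcs)


def random_bistructure(
    n: int,
    seed: int,
    max_arcs: int | None = None,
    allow_crossing: bool = True,
    allow_overlap: bool = True,
    min_hairpin: int = 0,
    max_retries: int = 50,
) -> Bistructure:
    """Random valid structure pair honoring the crossing/overlap flags.

    Rejection sampling: arcs are inserted one at a time per layer, skipping
    candidates that violate noncrossing within the layer (always), crossing
    between layers (if disallowed), or endpoint sharing (if disallowed).
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if max_arcs is None:
        max_arcs = max(1, n // 3)
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        arcs_R = _random_layer(
            rng, n, max_arcs, min_hairpin, frozenset(), [], allow_crossing=True
        )
        forbidden = (
            frozenset(v for a in arcs_R for v in a)
            if not allow_overlap
            else frozenset()
        )
        arcs_S = _random_layer(
            rng,
            n,
            max_arcs,
            min_hairpin,
            forbidden,
            sorted(arcs_R),
            allow_crossing=allow_crossing,
        )
        try:
            R = SecondaryStructure(n, arcs_R, min_hairpin=min_hairpin)
            S = SecondaryStructure(n, arcs_S, min_hairpin=min_hairpin)
            return build_bistructure(R, S)
        except StructureError:
            continue
    raise RuntimeError("could not generate a valid bistructure under the flags")
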
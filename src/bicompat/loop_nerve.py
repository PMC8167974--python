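"""The simplicial loop nerve of a bistructure and its topological signatures.

Loops are 0-simplices; d+1 loops with nonempty mutual vertex-set intersection
form a d-simplex.  Because a position belongs to at most two loops per layer,
no vertex lies in more than four loops, so the nerve contains no simplex of
dimension greater than 3.  The rank of the second homology group, r2(B),
counts the crossing components of the (overlap-split) bistructure; it is
computed here both combinatorially and via exact boundary-matrix ranks.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import sympy

from bicompat.bistructure_core import (
    Arc,
    Bistructure,
    SecondaryStructure,
    build_bistructure,
)


@dataclass(frozen=True)
class Nerve:
    """Simplices of the loop nerve, by dimension, plus the *-graph.

    The *-graph has the 2-simplices (triangles) as vertices, with an edge
    whenever two triangles share a 1-simplex; for a crossing-free,
    overlap-free bistructure it is a forest.
    """

    simplices_by_dim: dict[int, tuple[tuple[str, ...], ...]]

    @property
    def star_graph(self) -> nx.Graph:
        g = nx.Graph()
        triangles = self.simplices_by_dim.get(2, ())
        g.add_nodes_from(triangles)
        for t1, t2 in combinations(triangles, 2):
            if len(set(t1) & set(t2)) == 2:
                g.add_edge(t1, t2)
        return g

    @property
    def max_dim(self) -> int:
        return max((d for d, s in self.simplices_by_dim.items() if s), default=-1)


@dataclass(frozen=True)
class CrossingComponent:
    """A maximal set of arcs connected under the crossing relation."""

    arcs: tuple[Arc, ...]

    @property
    def leftmost(self) -> tuple[int, int]:
        return min(a.span for a in self.arcs)


def build_nerve(B: Bistructure) -> Nerve:
    """Enumerate all simplices of the loop nerve by mutual intersection.

    A d-simplex requires a vertex common to all d+1 loops, so enumeration
    walks the loops containing each vertex.  Raises if five loops share a
    vertex, which cannot happen for a valid bistructure.
    """
    containing: dict[int, list[str]] = {}
    for lp in B.loops:
        for v in lp.vertices:
            containing.setdefault(v, []).append(lp.id)
    simplices: dict[int, set[tuple[str, ...]]] = {d: set() for d in range(4)}
    for v, ids in containing.items():
        if len(ids) > 4:
            raise AssertionError(
                f"vertex {v} lies in {len(ids)} loops; bistructure invariant violated"
            )
        ids = sorted(ids)
        for d in range(len(ids)):
            for combo in combinations(ids, d + 1):
                simplices[d].add(combo)
    return Nerve(
        simplices_by_dim={d: tuple(sorted(s)) for d, s in simplices.items()}
    )


def crossing_components(B: Bistructure) -> list[CrossingComponent]:
    """Connected components of the crossing relation over non-rainbow arcs.

    Only components containing at least one crossing qualify; isolated arcs
    are not crossing components.  Ordered by leftmost arc.
    """
    arcs = B.nonrainbow_arcs
    g = nx.Graph()
    g.add_nodes_from(range(len(arcs)))
    for a, b in combinations(range(len(arcs)), 2):
        if arcs[a].crosses(arcs[b]):
            g.add_edge(a, b)
    comps = []
    for nodes in nx.connected_components(g):
        if len(nodes) > 1:
            comps.append(
                CrossingComponent(tuple(sorted((arcs[i] for i in nodes), key=lambda a: a.span)))
            )
    comps.sort(key=lambda c: c.leftmost)
    return comps


# ---------------------------------------------------------------------------
# overlap splitting
# ---------------------------------------------------------------------------


def _overlaps(B: Bistructure) -> list[int]:
    r_ends = {v for a in B.nonrainbow_arcs if a.layer == "R" for v in a.span}
    s_ends = {v for a in B.nonrainbow_arcs if a.layer == "S" for v in a.span}
    return sorted(r_ends & s_ends)


def split_overlaps(
    B: Bistructure,
) -> tuple[Bistructure, dict[int, tuple[int, ...]]]:
    """Split every overlap vertex into two adjacent positions, inducing no crossing.

    An overlap is a vertex that is an endpoint of a non-rainbow arc in both
    layers (it lies in four loops, a 3-simplex of the nerve).  Each overlap x
    becomes (x1, x2); the two incident arcs are attached so that they nest or
    become disjoint, never cross: where both arcs open (or both close) at x,
    the wider arc stays outside; where one closes and the other opens, the
    closing arc takes the earlier copy.  Ties (identical spans in both
    layers) nest the R-arc outside.  r2 is unchanged by the split.  Energies
    are always evaluated on original coordinates; the split bistructure
    exists only for topology and scheduling.
    """
    overlaps = _overlaps(B)
    if not overlaps:
        return B, {v: (v,) for v in range(0, B.n + 2)}

    arcs_at: dict[int, dict[str, Arc]] = {x: {} for x in overlaps}
    for a in B.nonrainbow_arcs:
        for v in a.span:
            if v in arcs_at:
                arcs_at[v][a.layer] = a

    # new 1-based coordinates: each overlap occupies two consecutive slots
    new_pos: dict[int, tuple[int, ...]] = {}
    cursor = 1
    for v in range(1, B.n + 1):
        if v in arcs_at:
            new_pos[v] = (cursor, cursor + 1)
            cursor += 2
        else:
            new_pos[v] = (cursor,)
            cursor += 1
    n_new = cursor - 1
    vertex_map = {0: (0,), **new_pos, B.n + 1: (n_new + 1,)}

    def slot(arc: Arc, v: int) -> int:
        """Which copy of overlap v the endpoint of `arc` is attached to."""
        pair = arcs_at[v]
        other = pair["S" if arc.layer == "R" else "R"]
        first, second = new_pos[v]
        if arc.i == v and other.i == v:  # both open at v: wider arc outside
            if arc.j != other.j:
                mine_outside = arc.j > other.j
            else:
                mine_outside = arc.layer == "R"
            return first if mine_outside else second
        if arc.j == v and other.j == v:  # both close at v: wider arc outside
            if arc.i != other.i:
                mine_outside = arc.i < other.i
            else:
                mine_outside = arc.layer == "R"
            return second if mine_outside else first
        # one closes, one opens: closing arc takes the earlier copy
        return first if arc.j == v else second

    def remap(a: Arc) -> tuple[int, int]:
        ends = []
        for v in a.span:
            if v in arcs_at:
                ends.append(slot(a, v))
            else:
                ends.append(new_pos[v][0])
        return (ends[0], ends[1])

    arcs_R = frozenset(remap(a) for a in B.nonrainbow_arcs if a.layer == "R")
    arcs_S = frozenset(remap(a) for a in B.nonrainbow_arcs if a.layer == "S")
    R = SecondaryStructure(n_new, arcs_R, min_hairpin=0)
    S = SecondaryStructure(n_new, arcs_S, min_hairpin=0)
    return build_bistructure(R, S), vertex_map


# ---------------------------------------------------------------------------
# homology
# ---------------------------------------------------------------------------


def _boundary_matrix(
    faces: tuple[tuple[str, ...], ...], cells: tuple[tuple[str, ...], ...]
) -> sympy.Matrix:
    """Simplicial boundary operator from d-cells to (d-1)-faces (integer entries)."""
    index = {f: r for r, f in enumerate(faces)}
    mat = sympy.zeros(len(faces), max(len(cells), 1))
    for c, cell in enumerate(cells):
        for k in range(len(cell)):
            face = cell[:k] + cell[k + 1 :]
            mat[index[face], c] = (-1) ** k
    return mat


def homology_ranks(B: Bistructure) -> tuple[int, int, int]:
    """(rank H0, rank H1, rank H2) of the loop nerve, over the rationals.

    Exact integer/rational arithmetic avoids floating-point rank instability.
    """
    nerve = build_nerve(B)
    k0 = nerve.simplices_by_dim.get(0, ())
    k1 = nerve.simplices_by_dim.get(1, ())
    k2 = nerve.simplices_by_dim.get(2, ())
    k3 = nerve.simplices_by_dim.get(3, ())
    rank_d1 = _boundary_matrix(k0, k1).rank() if k1 else 0
    rank_d2 = _boundary_matrix(k1, k2).rank() if k2 else 0
    rank_d3 = _boundary_matrix(k2, k3).rank() if k3 else 0
    h0 = len(k0) - rank_d1
    h1 = (len(k1) - rank_d1) - rank_d2
    h2 = (len(k2) - rank_d2) - rank_d3
    return h0, h1, h2


def homology_rank_r2(B: Bistructure, method: str = "boundary_matrix") -> int:
    """Rank of the second homology group of the loop nerve.

    ``boundary_matrix`` computes dim ker(d2) - rank(d3) exactly;
    ``crossing_count`` counts the crossing components of the overlap-split
    bistructure.  The two agree for every valid bistructure.
    """
    if method == "boundary_matrix":
        return homology_ranks(B)[2]
    if method == "crossing_count":
        B_split, _ = split_overlaps(B)
        return len(crossing_components(B_split))
    raise ValueError(f"unknown method {method!r}")


def star_graph_is_tree(B: Bistructure) -> bool:
    """True iff the nerve's triangles glue in a tree-like way (no closed band).

    Acyclicity is tested on the bipartite incidence graph of triangles and
    their 1-simplex faces.  Several triangles may share one and the same
    edge (a "book", a branch point of the ribbon tree) without creating a
    closed band; the plain triangle-adjacency graph would report such books
    as cliques, so the incidence graph is the faithful cycle test.  For a
    crossing-free, overlap-free bistructure the verdict is always True; a
    sphere (crossing component) produces a closed cycle of triangles and is
    reported as-is.
    """
    triangles = build_nerve(B).simplices_by_dim.get(2, ())
    g = nx.Graph()
    for t in triangles:
        g.add_node(("triangle", t))
        for k in range(3):
            face = t[:k] + t[k + 1 :]
            g.add_edge(("triangle", t), ("face", face))
    if g.number_of_nodes() == 0:
        return True
    return nx.is_forest(g)


def nerve_to_json(B: Bistructure) -> dict:
    """JSON-ready summary: simplices, *-graph edges, crossing components, r2."""
    nerve = build_nerve(B)
    return {
        "simplices": {
            str(d): [list(s) for s in simps]
            for d, simps in sorted(nerve.simplices_by_dim.items())
        },
        "star_graph_edges": sorted(
            [sorted([list(a), list(b)]) for a, b in nerve.star_graph.edges]
        ),
        "crossing_components": [
            [[a.i, a.j, a.layer] for a in comp.arcs]
            for comp in crossing_components(B)
        ],
        "r2": homology_rank_r2(B, method="crossing_count"),
    }
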
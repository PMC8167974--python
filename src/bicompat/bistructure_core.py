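"""Secondary structures, bistructures, loops and the substructure algebra.

Positions are 1-based; the formal vertices 0 and n+1 carry no nucleotide and
bound the rainbow arc (0, n+1) that closes the exterior loop of each layer.
A bistructure B(R, S) is the set of loops of both layers; every non-rainbow
arc appears in exactly two loops of its layer and is maximal in exactly one,
so the loop count is |arcs(R)| + |arcs(S)| + 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator

RNA_ALPHABET = "ACGU"

#: Canonical Watson-Crick and wobble base pairs.
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)


class StructureError(ValueError):
    """Malformed structure input (unbalanced brackets, bad characters, ...)."""


@dataclass(frozen=True, order=True)
class Arc:
    """A base pair (i, j) with i < j, tagged by its layer R or S.

    The rainbow arc is exactly (0, n+1); it imposes no sequence constraint
    since the formal vertices 0 and n+1 carry no nucleotide.
    """

    i: int
    j: int
    layer: str = "R"
    is_rainbow: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.i < self.j):
            raise StructureError(f"invalid arc ({self.i}, {self.j})")
        if self.layer not in ("R", "S"):
            raise StructureError(f"invalid layer {self.layer!r}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.i, self.j)

    def crosses(self, other: "Arc") -> bool:
        """True iff the two arcs cross: i < r < j < s (in either order)."""
        a, b = sorted((self.span, other.span))
        return a[0] < b[0] < a[1] < b[1]


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free secondary structure on positions 1..n (one layer).

    ``arcs`` holds the non-rainbow base pairs as (i, j) tuples with i < j.
    """

    n: int
    arcs: frozenset[tuple[int, int]]
    min_hairpin: int = 3

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.arcs:
            if not (1 <= i < j <= self.n):
                raise StructureError(f"arc ({i}, {j}) outside 1..{self.n}")
            if i in seen or j in seen:
                raise StructureError(f"position in more than one arc: ({i}, {j})")
            seen.update((i, j))
        arcs = sorted(self.arcs)
        for a in arcs:
            for b in arcs:
                if a[0] < b[0] < a[1] < b[1]:
                    raise StructureError(f"crossing arcs {a} and {b}")
        for i, j in self.arcs:
            nested = any(i < r and s < j for r, s in self.arcs if (r, s) != (i, j))
            if not nested and j - i - 1 < self.min_hairpin:
                raise StructureError(
                    f"hairpin closed by ({i}, {j}) shorter than {self.min_hairpin}"
                )

    @property
    def paired(self) -> frozenset[int]:
        return frozenset(v for arc in self.arcs for v in arc)

    def to_dotbracket(self) -> str:
        chars = ["."] * self.n
        for i, j in self.arcs:
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return "".join(chars)


@dataclass(frozen=True)
class Loop:
    """A loop: the energy-bearing unit, a disjoint union of intervals.

    Uniquely represented by its maximal arc; the rainbow arc closes the
    exterior loop.  ``interior_arcs`` are the arcs directly nested below the
    maximal arc; ``unpaired`` are the loop's single-stranded positions.
    """

    id: str
    layer: str
    maximal_arc: Arc
    vertices: frozenset[int]
    interior_arcs: tuple[Arc, ...]
    unpaired: frozenset[int]
    loop_type: str

    @property
    def intervals(self) -> tuple[tuple[int, int], ...]:
        """The loop's vertex set as maximal contiguous intervals."""
        verts = sorted(self.vertices)
        out: list[tuple[int, int]] = []
        start = prev = verts[0]
        for v in verts[1:]:
            if v != prev + 1:
                out.append((start, prev))
                start = v
            prev = v
        out.append((start, prev))
        return tuple(out)

    @property
    def arcs(self) -> tuple[Arc, ...]:
        return (self.maximal_arc,) + self.interior_arcs


def parse_dotbracket(text: str, min_hairpin: int = 3) -> SecondaryStructure:
    """Parse Vienna dot-bracket notation into a :class:`SecondaryStructure`.

    Only '(', ')' and '.' are accepted: bracket layers used for pseudoknots
    are rejected, since only pseudoknot-free structures are supported.
    """
    text = text.strip()
    stack: list[int] = []
    arcs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(text, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            arcs.add((stack.pop(), pos))
        elif ch != ".":
            raise StructureError(f"illegal character {ch!r} at position {pos}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(n=len(text), arcs=frozenset(arcs), min_hairpin=min_hairpin)


def _classify(maximal: Arc, children: list[Arc], unpaired: set[int]) -> str:
    if maximal.is_rainbow:
        return "exterior"
    if not children:
        return "hairpin"
    if len(children) == 1:
        child = children[0]
        left = child.i - maximal.i - 1
        right = maximal.j - child.j - 1
        if left == 0 and right == 0:
            return "stack"
        if left == 0 or right == 0:
            return "bulge"
        return "interior"
    return "multiloop"


def _layer_loops(struct: SecondaryStructure, layer: str) -> list[Loop]:
    """Decompose one layer (rainbow added) into its loops."""
    n = struct.n
    rainbow = Arc(0, n + 1, layer=layer, is_rainbow=True)
    arcs = [Arc(i, j, layer=layer) for i, j in sorted(struct.arcs)]
    all_arcs = [rainbow] + arcs
    loops = []
    for arc in all_arcs:
        # direct children: arcs strictly inside `arc`, maximal among those
        inside = [c for c in arcs if arc.i < c.i and c.j < arc.j]
        children = [
            c
            for c in inside
            if not any(d.i < c.i and c.j < d.j for d in inside)
        ]
        covered = set()
        for c in children:
            covered.update(range(c.i + 1, c.j))
        vertices = {v for v in range(arc.i, arc.j + 1) if v not in covered}
        unpaired = vertices - {arc.i, arc.j} - {v for c in children for v in c.span}
        loops.append(
            Loop(
                id=f"{layer}({arc.i},{arc.j})",
                layer=layer,
                maximal_arc=arc,
                vertices=frozenset(vertices),
                interior_arcs=tuple(children),
                unpaired=frozenset(unpaired),
                loop_type=_classify(arc, children, unpaired),
            )
        )
    return loops


@dataclass(frozen=True)
class Bistructure:
    """Two same-length secondary structures viewed as a single set of loops."""

    n: int
    structure_R: SecondaryStructure
    structure_S: SecondaryStructure
    loops: tuple[Loop, ...]

    @property
    def vertex_universe(self) -> frozenset[int]:
        return frozenset(range(0, self.n + 2))

    @cached_property
    def loop_by_id(self) -> dict[str, Loop]:
        return {lp.id: lp for lp in self.loops}

    @cached_property
    def arcs(self) -> tuple[Arc, ...]:
        """All arcs of both layers, rainbows included."""
        out = []
        seen = set()
        for lp in self.loops:
            for arc in lp.arcs:
                key = (arc.layer, arc.span)
                if key not in seen:
                    seen.add(key)
                    out.append(arc)
        return tuple(sorted(out, key=lambda a: (a.layer, a.span)))

    @property
    def nonrainbow_arcs(self) -> tuple[Arc, ...]:
        return tuple(a for a in self.arcs if not a.is_rainbow)

    def substructure(self, loop_ids: Iterable[str]) -> "Substructure":
        return Substructure(parent=self, loop_ids=frozenset(loop_ids))

    def full_substructure(self) -> "Substructure":
        return self.substructure(lp.id for lp in self.loops)


def build_bistructure(
    R: SecondaryStructure, S: SecondaryStructure
) -> Bistructure:
    """Assemble the bistructure B(R, S): both layers' loops, rainbows added.

    The two rainbow arcs are distinct, layer-tagged objects, yielding the two
    exterior loops.
    """
    if R.n != S.n:
        raise StructureError(f"length mismatch: {R.n} vs {S.n}")
    loops = tuple(_layer_loops(R, "R") + _layer_loops(S, "S"))
    return Bistructure(n=R.n, structure_R=R, structure_S=S, loops=loops)


@dataclass(frozen=True)
class Substructure:
    """A subset X of a bistructure's loops with its exposed-vertex algebra.

    The exposed vertices E^X = V^X ∩ V^{X̄} are the positions whose
    nucleotides must be remembered by the dynamic program until every loop
    containing them has been processed.
    """

    parent: Bistructure
    loop_ids: frozenset[str]

    def __post_init__(self) -> None:
        unknown = self.loop_ids - set(self.parent.loop_by_id)
        if unknown:
            raise ValueError(f"unknown loop ids: {sorted(unknown)}")

    def __iter__(self) -> Iterator[Loop]:
        return (self.parent.loop_by_id[i] for i in sorted(self.loop_ids))

    def __len__(self) -> int:
        return len(self.loop_ids)

    @cached_property
    def vertex_set(self) -> frozenset[int]:
        out: set[int] = set()
        for lp in self:
            out |= lp.vertices
        return frozenset(out)

    @cached_property
    def complement(self) -> "Substructure":
        other = frozenset(lp.id for lp in self.parent.loops) - self.loop_ids
        return Substructure(self.parent, other)

    @cached_property
    def exposed(self) -> frozenset[int]:
        """E^X = V^X ∩ V^{X̄}."""
        return self.vertex_set & self.complement.vertex_set

    @cached_property
    def boundary(self) -> "Substructure":
        """X^C: complement loops with nontrivial intersection with X."""
        ids = frozenset(
            lp.id for lp in self.complement if lp.vertices & self.vertex_set
        )
        return Substructure(self.parent, ids)

    @cached_property
    def closure(self) -> "Substructure":
        """X̃ = X ∪ X^C."""
        return Substructure(self.parent, self.loop_ids | self.boundary.loop_ids)

    def components(self) -> list["Substructure"]:
        """Finest partition of X into parts with pairwise-disjoint vertex sets.

        A substructure with a single component is *irreducible*.
        """
        if not self.loop_ids:
            raise ValueError("empty substructure")
        ids = sorted(self.loop_ids)
        parent_of = {i: i for i in ids}

        def find(x: str) -> str:
            while parent_of[x] != x:
                parent_of[x] = parent_of[parent_of[x]]
                x = parent_of[x]
            return x

        loops = {i: self.parent.loop_by_id[i] for i in ids}
        for a in ids:
            for b in ids:
                if a < b and loops[a].vertices & loops[b].vertices:
                    parent_of[find(a)] = find(b)
        groups: dict[str, set[str]] = {}
        for i in ids:
            groups.setdefault(find(i), set()).add(i)
        comps = [Substructure(self.parent, frozenset(g)) for g in groups.values()]
        comps.sort(key=lambda c: min(c.loop_ids))
        return comps

    @property
    def is_irreducible(self) -> bool:
        return len(self.components()) == 1


def substructure_algebra(
    X: Substructure,
) -> tuple[frozenset[int], Substructure, Substructure, list[Substructure]]:
    """Convenience bundle: (exposed E^X, boundary X^C, closure X̃, components)."""
    if not X.loop_ids:
        raise ValueError("empty substructure")
    return (X.exposed, X.boundary, X.closure, X.components())


def _validate_sequence(seq: str, n: int) -> str:
    seq = seq.strip().upper().replace("T", "U")
    if len(seq) != n:
        raise ValueError(f"sequence length {len(seq)} != structure length {n}")
    bad = set(seq) - set(RNA_ALPHABET)
    if bad:
        raise ValueError(f"illegal letters {sorted(bad)}")
    return seq


def is_compatible(seq: str, struct: SecondaryStructure) -> bool:
    """True iff seq satisfies every base-pair constraint of one structure."""
    seq = _validate_sequence(seq, struct.n)
    return all((seq[i - 1], seq[j - 1]) in CANONICAL_PAIRS for i, j in struct.arcs)


def is_bicompatible(seq: str, B: Bistructure) -> bool:
    """True iff seq is canonically compatible with both layers of B.

    Rainbow arcs impose no constraint (formal endpoints carry no nucleotide).
    """
    seq = _validate_sequence(seq, B.n)
    return all(
        (seq[a.i - 1], seq[a.j - 1]) in CANONICAL_PAIRS for a in B.nonrainbow_arcs
    )
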
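"""Shared fixtures: named toy bistructures, models, and independent oracles."""

from __future__ import annotations

import pytest
from hypothesis import settings

from bicompat.bistructure_core import (
    CANONICAL_PAIRS,
    SecondaryStructure,
)
from bicompat.energy_model import get_model, structure_energy
from bicompat.oracle_fixtures import load_fixture, random_bistructure

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def wex():
    """The six-loop worked example (n=8, one crossing)."""
    return load_fixture("WEX")


@pytest.fixture(scope="session")
def p3():
    return load_fixture("P3")


@pytest.fixture(scope="session")
def c4():
    return load_fixture("C4")


@pytest.fixture(scope="session")
def zero_model():
    return get_model("zero")


@pytest.fixture(scope="session")
def arcpair_model():
    return get_model("arcpair")


@pytest.fixture(scope="session")
def turner_model():
    return get_model("turner")


@pytest.fixture(scope="session")
def random_suite():
    """A reusable batch of 200 random bistructures (crossings/overlaps allowed)."""
    return [
        random_bistructure(n=8 + (s % 18), seed=s, allow_crossing=True, allow_overlap=True)
        for s in range(200)
    ]


def enumerate_compatible_structures(seq: str, min_hairpin: int = 3):
    """All secondary structures whose arcs pair canonically in seq (oracle).

    Interval recursion independent of the folding DP: position lo is either
    unpaired or paired with any canonical partner j >= lo + min_hairpin + 1.
    """
    n = len(seq)

    def rec(lo: int, hi: int):
        if lo > hi:
            yield frozenset()
            return
        for rest in rec(lo + 1, hi):
            yield rest
        for j in range(lo + min_hairpin + 1, hi + 1):
            if (seq[lo - 1], seq[j - 1]) not in CANONICAL_PAIRS:
                continue
            for inner in rec(lo + 1, j - 1):
                for outer in rec(j + 1, hi):
                    yield frozenset({(lo, j)}) | inner | outer

    for arcs in rec(1, n):
        yield SecondaryStructure(n, arcs, min_hairpin=min_hairpin)


def brute_mfe(seq: str, model, min_hairpin: int = 3) -> float:
    """Exhaustive-enumeration mfe energy (oracle for the folding DP)."""
    return min(
        structure_energy(seq, s, model)
        for s in enumerate_compatible_structures(seq, min_hairpin)
    )
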
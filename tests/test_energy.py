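"""Energy models: per-loop values, structure sums, and the mfe folder."""

import math

import numpy as np
import pytest

from bicompat.bistructure_core import (
    SecondaryStructure,
    build_bistructure,
    parse_dotbracket,
    _layer_loops,
)
from bicompat.energy_model import (
    EnergyError,
    bistructure_energy,
    get_model,
    load_parameter_tables,
    mfe_fold,
    structure_energy,
)
from tests.conftest import brute_mfe, enumerate_compatible_structures


def _loop_of(struct, span):
    return next(
        lp for lp in _layer_loops(struct, "R") if lp.maximal_arc.span == span
    )


class TestLoopEnergies:
    def test_zero_model_everywhere(self, zero_model):
        struct = parse_dotbracket("((...))")
        for lp in _layer_loops(struct, "R"):
            assert zero_model.loop_energy(lp, dict(enumerate("GGAAACC", 1))) == 0.0

    def test_arcpair_hairpin_constant(self, arcpair_model):
        struct = parse_dotbracket("(...)")
        lp = _loop_of(struct, (1, 5))
        assert arcpair_model.loop_energy(lp, dict(enumerate("GAAAC", 1))) == -3.0
        assert arcpair_model.loop_energy(lp, dict(enumerate("AUUUU", 1))) == -2.0

    def test_noncanonical_pair_raises(self, arcpair_model):
        lp = _loop_of(parse_dotbracket("(...)"), (1, 5))
        with pytest.raises(EnergyError):
            arcpair_model.loop_energy(lp, dict(enumerate("GAAAG", 1)))

    def test_stack_lookup_matches_shipped_table(self, turner_model):
        """The stacking energy equals the value parsed independently from
        the bundled parameter file."""
        text = (
            __import__("importlib.resources", fromlist=["files"])
            .files("bicompat.data")
            .joinpath("turner_params.txt")
            .read_text()
        )
        in_stack = False
        expected = None
        for line in text.splitlines():
            line = line.split("#")[0].strip()
            if line == "[stack]":
                in_stack = True
            elif line.startswith("["):
                in_stack = False
            elif in_stack and line.startswith("GC CG"):
                expected = float(line.split()[2])
        struct = parse_dotbracket("((...))")
        lp = _loop_of(struct, (1, 7))
        got = turner_model.loop_energy(lp, dict(enumerate("GCAAAGC", 1)))
        assert got == expected


class TestStructureEnergy:
    def test_arc_free_is_zero(self, zero_model, arcpair_model, turner_model):
        struct = SecondaryStructure(6, frozenset(), 0)
        for model in (zero_model, arcpair_model, turner_model):
            assert structure_energy("ACGUAC", struct, model) == 0.0

    def test_arcpair_sums_over_arcs(self, arcpair_model):
        struct = SecondaryStructure(4, frozenset({(1, 4), (2, 3)}), min_hairpin=0)
        assert structure_energy("GGCC", struct, arcpair_model) == -6.0

    def test_turner_hand_computed_hairpin_stem(self, turner_model):
        """Manual table-walk: two stacks + hairpin initiation + mismatch."""
        t = turner_model.tables
        seq, db = "GCGAAACGC", "(((...)))"
        struct = parse_dotbracket(db)
        expected = (
            t["stack"][("GC", "CG")]
            + t["stack"][("CG", "GC")]
            + t["hairpin_initiation"][3]
            + t["terminal_mismatch"][("GC", "A", "A")]
        )
        assert structure_energy(seq, struct, turner_model) == pytest.approx(expected)

    def test_eta_b_is_the_average(self, wex, arcpair_model, turner_model):
        for model in (arcpair_model, turner_model):
            res = bistructure_energy("GCGCAGUC", wex, model)
            assert res.eta_B == pytest.approx(0.5 * (res.eta_R + res.eta_S))


class TestMfeFold:
    def test_unpairable_sequence_stays_open(self, arcpair_model):
        struct, e = mfe_fold("AAAAAAA", arcpair_model)
        assert struct.arcs == frozenset()
        assert e == 0.0

    @pytest.mark.parametrize("model_name", ["arcpair", "turner"])
    def test_matches_exhaustive_enumeration(self, model_name):
        model = get_model(model_name)
        rng = np.random.default_rng(11)
        for _ in range(12):
            n = int(rng.integers(5, 11))
            seq = "".join(rng.choice(list("ACGU"), size=n))
            struct, e = mfe_fold(seq, model)
            assert e == pytest.approx(brute_mfe(seq, model), abs=1e-9)
            # the traced structure realizes the reported energy
            assert structure_energy(seq, struct, model) == pytest.approx(e, abs=1e-9)

    def test_mfe_bounds_every_compatible_structure(self, arcpair_model):
        seq = "GGCAAAGCCAU"
        _, e = mfe_fold(seq, arcpair_model)
        for s in enumerate_compatible_structures(seq):
            assert e <= structure_energy(seq, s, arcpair_model) + 1e-9

    def test_deterministic(self, turner_model):
        seq = "GGGAAACCCAAGGGAAACCC"
        a = mfe_fold(seq, turner_model)
        b = mfe_fold(seq, turner_model)
        assert a[0].arcs == b[0].arcs and a[1] == b[1]


def test_kt_thermal_energy_constant(turner_model):
    assert turner_model.KT == pytest.approx(0.61633)
    assert math.isclose(
        load_parameter_tables()["constants"]["kt"], 0.61633
    )
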
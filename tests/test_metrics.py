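"""Spectra, mfe ranking, adaptability densities and random control pairs."""

import inspect
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bicompat.analysis_metrics import (
    DEFAULT_SAMPLE_SIZE,
    adaptability,
    random_structure_pair,
    ranking,
    spectrum,
)
from bicompat.bistructure_core import SecondaryStructure, build_bistructure
from bicompat.energy_model import structure_energy
from bicompat.oracle_fixtures import (
    brute_partition,
    enumerate_bicompatible,
    random_bistructure,
)
from bicompat.partition_sampler import SampleRecord, partition, sample
from bicompat.scheduler import schedule_general
from tests.conftest import brute_mfe


class TestSpectrum:
    def test_identical_values_single_bin(self):
        sp = spectrum([-4.2] * 10, delta=1.0)
        assert len(sp.masses) == 1
        assert sp.masses[0] == 1.0

    def test_half_open_boundary_convention(self):
        """-2.0 closes the bin (-3, -2]; -1.0 closes (-2, -1]."""
        sp = spectrum([-1.0, -2.0], delta=1.0, anchor=0.0)
        assert list(sp.bin_edges) == [-3.0, -2.0, -1.0]
        assert list(sp.masses) == [0.5, 0.5]

    def test_empty_and_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            spectrum([])
        with pytest.raises(ValueError):
            spectrum([1.0], delta=0.0)

    def test_default_sample_size_is_ten_thousand(self):
        assert DEFAULT_SAMPLE_SIZE == 10_000

    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=50),
        st.integers(-3, 3),
    )
    def test_masses_sum_to_one_and_anchor_shift_permutes(self, values, k):
        delta = 1.0
        sp1 = spectrum(values, delta=delta, anchor=0.0)
        assert float(sp1.masses.sum()) == pytest.approx(1.0, abs=1e-12)
        sp2 = spectrum(values, delta=delta, anchor=k * delta)
        assert sorted(sp1.masses[sp1.masses > 0]) == pytest.approx(
            sorted(sp2.masses[sp2.masses > 0])
        )


class TestRanking:
    def _samples(self, B, model, m=50, seed=2):
        order = schedule_general(B)
        table = partition(B, order, model)
        return sample(B, order, table, m, seed)

    def test_ratios_match_brute_force_mfe(self, arcpair_model):
        R = SecondaryStructure(10, frozenset({(1, 5), (6, 10)}), min_hairpin=3)
        S = SecondaryStructure(10, frozenset({(2, 9)}), min_hairpin=3)
        B = build_bistructure(R, S)
        samples = self._samples(B, arcpair_model, m=20)
        pairs = ranking(samples, arcpair_model)
        assert pairs
        for rec, rp in zip(samples, pairs):
            eta_mfe = brute_mfe(rec.sequence, arcpair_model)
            assert rp.r_R == pytest.approx(rec.eta_R / eta_mfe)
            assert rp.r_S == pytest.approx(rec.eta_S / eta_mfe)
            assert eta_mfe <= min(rec.eta_R, rec.eta_S) + 1e-9

    def test_sequence_whose_mfe_is_r_has_ratio_one(self, arcpair_model):
        # hairpin-only structures: GGGAAACCC folds exactly onto R
        R = SecondaryStructure(9, frozenset({(1, 9), (2, 8), (3, 7)}))
        S = SecondaryStructure(9, frozenset())
        B = build_bistructure(R, S)
        rec = SampleRecord(
            "GGGAAACCC",
            structure_energy("GGGAAACCC", R, arcpair_model),
            0.0,
            0.5 * structure_energy("GGGAAACCC", R, arcpair_model),
            0,
        )
        (rp,) = ranking([rec], arcpair_model)
        assert rp.r_R == pytest.approx(1.0)

    def test_zero_mfe_samples_excluded_with_warning(self, arcpair_model):
        rec = SampleRecord("AAAAAA", 0.0, 0.0, 0.0, 0)
        with pytest.warns(UserWarning):
            assert ranking([rec], arcpair_model) == []

    def test_external_mfe_adapter(self, arcpair_model):
        rec = SampleRecord("GGGAAACCC", -6.0, -3.0, -4.5, 0)
        (rp,) = ranking([rec], arcpair_model, mfe_energies={"GGGAAACCC": -9.0})
        assert rp.r_R == pytest.approx(-6.0 / -9.0)


class TestAdaptability:
    def test_arc_free_s_gives_ratio_one(self, arcpair_model):
        R = SecondaryStructure(8, frozenset({(1, 8), (2, 7)}), 0)
        S = SecondaryStructure(8, frozenset(), 0)
        res = adaptability(build_bistructure(R, S), arcpair_model)
        assert res.ratio_R == pytest.approx(1.0)
        assert res.log_R == pytest.approx(0.0, abs=1e-9)

    def test_p3_zero_model_counting_ratio(self, p3, zero_model):
        """With equal weights the density is a counting ratio: 10 bicompatible
        sequences out of 6*4 = 24 R-compatible ones."""
        res = adaptability(p3, zero_model)
        assert res.ratio_R == pytest.approx(10 / 24)
        assert res.ratio_S == pytest.approx(10 / 24)

    def test_ratios_in_unit_interval(self, arcpair_model):
        for seed in range(8):
            B = random_bistructure(n=8 + seed, seed=seed)
            res = adaptability(B, arcpair_model, kappa_cap=10**9)
            for ratio, log in ((res.ratio_R, res.log_R), (res.ratio_S, res.log_S)):
                assert 0 < ratio <= 1 + 1e-12
                assert log <= 1e-12
                assert ratio == pytest.approx(math.exp(log))

    def test_matches_brute_force_scaled_ratio(self, p3, arcpair_model):
        res = adaptability(p3, arcpair_model)
        num = brute_partition(p3, arcpair_model, selector="R_only", scaling=1 / p3.n)
        # denominator: all R-compatible sequences (S arc-free)
        R_only = build_bistructure(
            p3.structure_R, SecondaryStructure(p3.n, frozenset(), 0)
        )
        den = brute_partition(R_only, arcpair_model, selector="R_only", scaling=1 / p3.n)
        assert res.ratio_R == pytest.approx(num / den, rel=1e-9)


class TestRandomStructurePair:
    def test_default_length_matches_riboswitch_scale(self):
        sig = inspect.signature(random_structure_pair)
        assert sig.parameters["n"].default == 150

    def test_reproducible_and_valid(self, arcpair_model):
        a = random_structure_pair(n=30, seed=4, model=arcpair_model)
        b = random_structure_pair(n=30, seed=4, model=arcpair_model)
        assert a[0].arcs == b[0].arcs and a[1].arcs == b[1].arcs
        for struct in a:
            assert struct.min_hairpin == 3  # validated at construction

    def test_uniform_structure_method(self):
        R, S = random_structure_pair(n=20, seed=1, method="uniform_structure")
        assert R.n == S.n == 20

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            random_structure_pair(n=4, seed=0)


class TestSpectrumShiftPattern:
    def test_conflicting_pairs_shift_more_than_easy_pairs(self, arcpair_model):
        """Bicompatibility barely moves the R-energy distribution when the
        two structures' pairing constraints do not conflict, but shifts it
        for interleaved, conflict-heavy pairs (smoke check by enumeration)."""

        def mean_shift(B):
            def mean_eta_R(bi):
                _, seqs = enumerate_bicompatible(bi)
                vals = []
                for s in seqs:
                    eta = structure_energy(s, B.structure_R, arcpair_model)
                    vals.append((s, eta))
                w = [math.exp(-e / arcpair_model.KT) for _, e in vals]
                return sum(wi * e for wi, (_, e) in zip(w, vals)) / sum(w)

            R_only = build_bistructure(
                B.structure_R, SecondaryStructure(B.n, frozenset(), 0)
            )
            return abs(mean_eta_R(B) - mean_eta_R(R_only))

        easy = build_bistructure(
            SecondaryStructure(8, frozenset({(1, 4)}), 0),
            SecondaryStructure(8, frozenset({(5, 8)}), 0),
        )
        # S chains the R-arc endpoints together (4-5), coupling the pairs
        hard = build_bistructure(
            SecondaryStructure(8, frozenset({(1, 4), (5, 8)}), 0),
            SecondaryStructure(8, frozenset({(4, 5), (3, 6)}), 0),
        )
        assert mean_shift(easy) + 0.01 <= mean_shift(hard)
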
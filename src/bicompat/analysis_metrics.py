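"""Downstream statistics for structure pairs: spectra, ranking, adaptability.

Three measures quantify how easily sequences transit between the neutral
networks of two structures R and S:

* discretized *energy spectra* of Boltzmann-sampled sequences — for a
  riboswitch pair the spectrum of bicompatible sequences nearly coincides
  with that of singly-compatible sequences, while random pairs shift;
* the *(r_R, r_S) ranking* of each sampled sequence's energies against its
  own mfe structure, r_R = eta(sigma, R) / eta(sigma, M(sigma));
* the *adaptability densities* (w_R, w_S): ratios of scaled partition
  functions Q~(R)|_S / Q~(R), with energies divided by n so that pairs of
  different lengths are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from bicompat.bistructure_core import Bistructure, SecondaryStructure
from bicompat.energy_model import EnergyModel, get_model, mfe_fold, structure_energy
from bicompat.oracle_fixtures import _random_layer
from bicompat.partition_sampler import SampleRecord, restricted_partitions

#: defaults of the sampling studies: 10^4 sequences, 1 kcal/mol bins
DEFAULT_SAMPLE_SIZE = 10_000
DEFAULT_DELTA = 1.0
DEFAULT_PAIR_LENGTH = 150


@dataclass(frozen=True)
class Spectrum:
    """A discretized f-spectrum: masses over half-open bins (a_{s-1}, a_s]."""

    bin_edges: np.ndarray  # increasing, len = len(masses) + 1
    masses: np.ndarray

    def __post_init__(self) -> None:
        assert abs(float(self.masses.sum()) - 1.0) <= 1e-12


@dataclass(frozen=True)
class RankPair:
    r_R: float
    r_S: float
    eta_mfe: float


@dataclass(frozen=True)
class AdaptabilityResult:
    """w_R = Q~(R)|_S / Q~(R) and w_S analogously; logs are <= 0."""

    ratio_R: float
    ratio_S: float
    log_R: float
    log_S: float


def spectrum(
    values, delta: float = DEFAULT_DELTA, anchor: float = 0.0
) -> Spectrum:
    """Bin values into half-open bins (anchor+(s-1)*delta, anchor+s*delta].

    Masses are counts/m.  A value exactly on an edge belongs to the bin it
    closes (the half-open convention), so -2.0 with delta 1 and anchor 0
    falls in (-3, -2].
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("empty input")
    if delta <= 0:
        raise ValueError("delta must be positive")
    # s = ceil((v - anchor)/delta), with a tolerance so edge values stay put
    s = np.ceil((vals - anchor) / delta - 1e-9).astype(int)
    lo, hi = int(s.min()), int(s.max())
    counts = np.bincount(s - lo, minlength=hi - lo + 1)
    edges = anchor + delta * np.arange(lo - 1, hi + 1)
    return Spectrum(bin_edges=edges, masses=counts / vals.size)


def ranking(
    samples: list[SampleRecord],
    model: EnergyModel,
    mfe_energies: dict[str, float] | None = None,
) -> list[RankPair]:
    """Per-sample ratios of R/S energies to the sequence's own mfe energy.

    The mfe structure is folded under ``model`` (min_hairpin=3) unless
    ``mfe_energies`` supplies precomputed energies keyed by sequence — the
    adapter for plugging in an external folder.  Samples whose mfe energy is
    zero have undefined ratios and are excluded with a warning.
    """
    out: list[RankPair] = []
    skipped = 0
    for rec in samples:
        if mfe_energies is not None:
            eta_mfe = mfe_energies[rec.sequence]
        else:
            _, eta_mfe = mfe_fold(rec.sequence, model)
        if eta_mfe == 0.0:
            skipped += 1
            continue
        out.append(
            RankPair(
                r_R=rec.eta_R / eta_mfe, r_S=rec.eta_S / eta_mfe, eta_mfe=eta_mfe
            )
        )
    if skipped:
        warnings.warn(
            f"excluded {skipped} sample(s) with zero mfe energy (ratio undefined)",
            stacklevel=2,
        )
    return out


def adaptability(
    B: Bistructure,
    model: EnergyModel,
    sign: str = "boltzmann",
    kappa_cap: int = 20,
) -> AdaptabilityResult:
    """Densities (w_R, w_S) from scaled partition functions (energies / n).

    ratio_R = Q~(R)|_S / Q~(R) lies in (0, 1]: the weight of bicompatible
    sequences within all R-compatible sequences.  Both the raw ratio (the
    headline w value) and its log are returned.  ``sign='paper'`` flips the
    exponent convention.
    """
    parts = restricted_partitions(B, model, scaling="1/n", sign=sign, kappa_cap=kappa_cap)
    log_R = parts["Q_R_given_S"].log_value - parts["Q_R"].log_value
    log_S = parts["Q_S_given_R"].log_value - parts["Q_S"].log_value
    return AdaptabilityResult(
        ratio_R=float(np.exp(log_R)),
        ratio_S=float(np.exp(log_S)),
        log_R=log_R,
        log_S=log_S,
    )


def random_structure_pair(
    n: int = DEFAULT_PAIR_LENGTH,
    seed: int = 0,
    method: str = "fold_random_seq",
    model: EnergyModel | None = None,
) -> tuple[SecondaryStructure, SecondaryStructure]:
    """A control structure pair: two random structures of length n.

    ``fold_random_seq`` draws two uniform random sequences and mfe-folds each
    under ``model`` (default: the nearest-neighbor model), mirroring how
    non-riboswitch control pairs arise; ``uniform_structure`` samples valid
    structures directly (min_hairpin=3).  Reproducible by seed.
    """
    if n < 8:
        raise ValueError("n must be >= 8")
    rng = np.random.default_rng(seed)
    if method == "fold_random_seq":
        if model is None:
            model = get_model("turner")
        structs = []
        for _ in range(2):
            seq = "".join(rng.choice(list("ACGU"), size=n))
            struct, _ = mfe_fold(seq, model)
            structs.append(struct)
        return structs[0], structs[1]
    if method == "uniform_structure":
        out = []
        for _ in range(2):
            arcs = _random_layer(
                rng, n, max_arcs=max(1, n // 4), min_hairpin=3,
                forbidden_endpoints=frozenset(), existing=[], allow_crossing=True,
            )
            out.append(SecondaryStructure(n, arcs, min_hairpin=3))
        return out[0], out[1]
    raise ValueError(f"unknown method {method!r}")
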
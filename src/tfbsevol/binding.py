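"""Thermodynamic model of sequence-specific transcription factor binding.

A TF binds an ``n``-bp site with energy given by an additive energy matrix;
in the homogeneous "mismatch" approximation every non-consensus base pair
costs the same specificity penalty ``epsilon`` (k_B T), so a site ``k``
mismatches away from the consensus has energy ``E = k * epsilon``.  The
equilibrium binding probability (occupancy) follows a Fermi function of the
energy relative to the chemical potential ``mu`` (log free-TF concentration),
and fitness is proportional to occupancy (single site) or to a simple
aggregate of window occupancies in a longer regulatory sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

ALPHABET = "ACGT"
_BASE_INDEX = {c: i for i, c in enumerate(ALPHABET)}

__all__ = [
    "ALPHABET",
    "BindingModel",
    "CooperativityParams",
    "FitnessSpec",
    "BindingClasses",
    "encode_sequence",
    "decode_sequence",
    "site_energy",
    "occupancy",
    "occupancy_cooperative",
    "single_site_fitness",
    "promoter_fitness",
    "classify_binding",
    "window_mismatches",
    "cooperative_partner_mismatches",
]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array (A=0, C=1, G=2, T=3)."""
    try:
        return np.array([_BASE_INDEX[c] for c in seq], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"non-ACGT character in sequence: {exc.args[0]!r}") from None


def decode_sequence(arr: np.ndarray) -> str:
    return "".join(ALPHABET[int(b)] for b in np.asarray(arr))


@dataclass(frozen=True)
class BindingModel:
    """Biophysical parameters of a single TF.

    Parameters
    ----------
    n : int
        Binding site length in bp.
    epsilon : float
        Specificity: energy penalty per mismatch, in k_B T (> 0).
    mu : float
        Chemical potential in k_B T; sets the occupancy midpoint.
    beta : float
        Inverse temperature in 1/(k_B T); 1 by convention.
    energy_matrix : ndarray, optional
        4 x n matrix of per-base energies (k_B T).  Each column must have
        exactly one zero (the consensus base) and no negative entries.
        When absent the homogeneous mismatch approximation applies.
    consensus : str, optional
        Consensus sequence used in mismatch mode.  Defaults to ``"A" * n``.
        With an energy matrix the consensus is derived from the zero
        entries and this field must not disagree.
    """

    n: int
    epsilon: float = 2.0
    mu: float = 4.0
    beta: float = 1.0
    energy_matrix: Optional[np.ndarray] = None
    consensus: Optional[str] = None

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("site length n must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("specificity epsilon must be > 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.energy_matrix is not None:
            xi = np.asarray(self.energy_matrix, dtype=float)
            if xi.shape != (4, self.n):
                raise ValueError(f"energy matrix must be 4 x {self.n}, got {xi.shape}")
            if (xi < 0).any():
                raise ValueError("energy matrix entries must be nonnegative")
            if not np.all((xi == 0).sum(axis=0) == 1):
                raise ValueError("each energy-matrix column needs exactly one zero (consensus) entry")
            object.__setattr__(self, "energy_matrix", xi)
            derived = decode_sequence(np.argmin(xi, axis=0))
            if self.consensus is not None and self.consensus != derived:
                raise ValueError("consensus disagrees with energy-matrix zero entries")
            object.__setattr__(self, "consensus", derived)
        else:
            cons = self.consensus if self.consensus is not None else "A" * self.n
            if len(cons) != self.n:
                raise ValueError("consensus length must equal n")
            encode_sequence(cons)  # validates alphabet
            object.__setattr__(self, "consensus", cons)

    @property
    def consensus_array(self) -> np.ndarray:
        return encode_sequence(self.consensus)


@dataclass(frozen=True)
class CooperativityParams:
    """Pairwise TF-TF interaction: ``e_c`` (k_B T, negative = favorable)
    applies between TFs bound at sites within ``window`` bp of each other."""

    e_c: float = 0.0
    window: int = 3

    def __post_init__(self):
        if self.window < 0:
            raise ValueError("cooperativity window must be >= 0")


@dataclass(frozen=True)
class FitnessSpec:
    """Map from occupancy to fitness.

    ``s`` is the selective advantage of strongest over weakest binding.
    ``mode`` selects the promoter aggregation: ``additive`` (sum of window
    occupancies), ``strongest`` (max window occupancy), or
    ``synergistic_pair`` (joint occupancy of the two strongest windows).
    ``power_law_gamma`` replaces the thermodynamic tail beyond the strong
    class with a power-law decay of that exponent (``inf`` = step landscape);
    it applies to single-site mismatch landscapes only.
    """

    s: float = 0.1
    mode: str = "additive"
    power_law_gamma: Optional[float] = None

    def __post_init__(self):
        if self.mode not in ("additive", "strongest", "synergistic_pair"):
            raise ValueError(f"unknown fitness mode {self.mode!r}")
        if self.power_law_gamma is not None and self.power_law_gamma <= 0:
            raise ValueError("power_law_gamma must be > 0 (or inf)")


@dataclass(frozen=True)
class BindingClasses:
    """Discrete binding classes: strong (pi > 2/3) up to ``k_strong``, weak
    (pi < 1/3) from ``k_weak``; the presite is one mismatch past the strong
    boundary."""

    k_strong: int
    k_weak: int

    @property
    def presite_k(self) -> int:
        return self.k_strong + 1

    @property
    def strong(self) -> tuple:
        return tuple(range(self.k_strong + 1))

    def weak(self, n: int) -> tuple:
        return tuple(range(self.k_weak, n + 1))


def site_energy(seq_window: str | np.ndarray, model: BindingModel) -> float:
    """Binding energy (k_B T) of one length-n window under the additive model.

    In mismatch mode this is ``epsilon`` times the Hamming distance to the
    consensus; with an energy matrix it is the sum of the per-column entries.
    """
    arr = encode_sequence(seq_window) if isinstance(seq_window, str) else np.asarray(seq_window)
    if arr.shape != (model.n,):
        raise ValueError(f"window length {arr.shape} does not match site length n={model.n}")
    if model.energy_matrix is not None:
        return float(model.energy_matrix[arr, np.arange(model.n)].sum())
    k = int(np.count_nonzero(arr != model.consensus_array))
    return model.epsilon * k


def occupancy(k, model: BindingModel):
    """Thermodynamic occupancy ``(1 + exp(beta*(eps*k - mu)))**-1`` of a site
    with ``k`` mismatches.  Accepts scalars or arrays; strictly decreasing in
    ``k`` and increasing in ``mu``."""
    k_arr = np.asarray(k)
    if np.any((k_arr < 0) | (k_arr > model.n)):
        raise ValueError(f"mismatch count must lie in [0, {model.n}]")
    return _occupancy_of_energy(model.epsilon * np.asarray(k, dtype=float), model)


def _occupancy_of_energy(energy, model: BindingModel):
    x = model.beta * (np.asarray(energy, dtype=float) - model.mu)
    out = np.empty_like(x, dtype=float)
    pos = x > 0
    out[pos] = np.exp(-x[pos]) / (1.0 + np.exp(-x[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(x[~pos]))
    return out if out.ndim else float(out)


def occupancy_cooperative(k, k_c, model: BindingModel, coop: CooperativityParams):
    """Occupancy of the focal site with a cooperative partner.

    Two-site partition function with single-occupancy Boltzmann weights
    ``exp(-beta*(eps*k - mu))`` and ``exp(-beta*(eps*k_c - mu))`` and joint
    weight ``exp(-beta*(eps*k + eps*k_c + e_c - 2*mu))``, so a favorable
    (negative) ``e_c`` increases joint binding; the strong partner acts as a
    local upward shift of the chemical potential.  Reduces exactly to
    :func:`occupancy` at ``e_c = 0``.
    """
    k_arr = np.asarray(k, dtype=float)
    kc_arr = np.asarray(k_c, dtype=float)
    if np.any((k_arr < 0) | (k_arr > model.n)) or np.any((kc_arr < 0) | (kc_arr > model.n)):
        raise ValueError(f"mismatch counts must lie in [0, {model.n}]")
    b = model.beta
    eps, mu = model.epsilon, model.mu
    # log-weights, stabilised by the largest exponent
    g1 = -b * (eps * k_arr - mu)
    g2 = -b * (eps * kc_arr - mu)
    gj = -b * (eps * k_arr + eps * kc_arr + coop.e_c - 2.0 * mu)
    m = np.maximum.reduce([np.zeros_like(g1 + g2), g1, g2, gj])
    num = np.exp(g1 - m) + np.exp(gj - m)
    den = np.exp(-m) + np.exp(g1 - m) + np.exp(g2 - m) + np.exp(gj - m)
    out = num / den
    return out if out.ndim else float(out)


def classify_binding(model: BindingModel) -> BindingClasses:
    """Strong/weak class boundaries from the occupancy thresholds 2/3 and 1/3.

    ``k_strong`` is the largest k with pi(k) > 2/3 (strict), ``k_weak`` the
    smallest k with pi(k) < 1/3 (strict).
    """
    pi = occupancy(np.arange(model.n + 1), model)
    strong = np.nonzero(pi > 2.0 / 3.0)[0]
    weak = np.nonzero(pi < 1.0 / 3.0)[0]
    if strong.size == 0:
        raise ValueError(
            "TF cannot bind strongly at this mu/epsilon: no mismatch class has occupancy > 2/3"
        )
    if weak.size == 0:
        raise ValueError("no weak class: occupancy never falls below 1/3 (mu too high for this n)")
    return BindingClasses(k_strong=int(strong.max()), k_weak=int(weak.min()))


def _effective_pi_table(model: BindingModel, spec: FitnessSpec) -> np.ndarray:
    """Per-mismatch-class occupancy table with the optional power-law tail."""
    ks = np.arange(model.n + 1)
    pi = occupancy(ks, model)
    if spec.power_law_gamma is None:
        return pi
    k_s = classify_binding(model).k_strong
    gamma = spec.power_law_gamma
    tail = ks > k_s
    if math.isinf(gamma):
        pi[tail] = 0.0
    else:
        pi[tail] = pi[k_s] * (ks[tail] - k_s + 1.0) ** (-gamma)
    return pi


def single_site_fitness(k, spec: FitnessSpec, model: BindingModel):
    """Fitness ``s * pi(k)`` of an isolated site with ``k`` mismatches."""
    table = _effective_pi_table(model, spec)
    k_arr = np.asarray(k)
    if np.any((k_arr < 0) | (k_arr > model.n)):
        raise ValueError(f"mismatch count must lie in [0, {model.n}]")
    out = spec.s * table[k_arr]
    return out if np.ndim(k) else float(out)


def window_mismatches(seq: str | np.ndarray, model: BindingModel) -> np.ndarray:
    """Mismatch count of every length-n window of ``seq`` (starts 0..L-n)."""
    arr = encode_sequence(seq) if isinstance(seq, str) else np.asarray(seq)
    if arr.size < model.n:
        raise ValueError(f"sequence length {arr.size} shorter than site length n={model.n}")
    windows = sliding_window_view(arr, model.n)
    return (windows != model.consensus_array).sum(axis=1)


def cooperative_partner_mismatches(ks: np.ndarray, n: int, window: int) -> np.ndarray:
    """Minimal mismatch count of a cooperative partner for each window.

    Partners are non-overlapping windows whose start-to-end gap to the focal
    window is at most ``window`` bp, i.e. window-index offsets in
    ``[n, n + window]`` on either side; ties go to the leftmost candidate
    (irrelevant for the minimum).  Windows without a candidate get ``n + 1``
    as a sentinel (treated as "no partner").
    """
    ks = np.atleast_2d(ks)
    nwin = ks.shape[-1]
    sentinel = n + 1
    best = np.full_like(ks, sentinel)
    for off in range(n, n + window + 1):
        if off >= nwin:
            break
        # partner to the right at index +off
        best[..., : nwin - off] = np.minimum(best[..., : nwin - off], ks[..., off:])
        # partner to the left at index -off
        best[..., off:] = np.minimum(best[..., off:], ks[..., : nwin - off])
    return best if best.shape[0] > 1 else best[0]


def _window_occupancies(
    seq, model: BindingModel, spec: FitnessSpec, coop: Optional[CooperativityParams]
) -> np.ndarray:
    if model.energy_matrix is not None and spec.power_law_gamma is None and coop is None:
        arr = encode_sequence(seq) if isinstance(seq, str) else np.asarray(seq)
        windows = sliding_window_view(arr, model.n)
        energies = model.energy_matrix[windows, np.arange(model.n)].sum(axis=1)
        return _occupancy_of_energy(energies, model)
    ks = window_mismatches(seq, model)
    table = _effective_pi_table(model, spec)
    if coop is None or coop.e_c == 0.0:
        return table[ks]
    kc = cooperative_partner_mismatches(ks, model.n, coop.window)
    pi = np.where(
        kc > model.n,
        table[ks],
        occupancy_cooperative(ks, np.minimum(kc, model.n), model, coop),
    )
    return pi


def promoter_fitness(
    seq: str | np.ndarray,
    spec: FitnessSpec,
    model: BindingModel,
    coop: Optional[CooperativityParams] = None,
) -> float:
    """Fitness of a length-L regulatory sequence (L >= n).

    ``additive`` sums the occupancies of all L-n+1 windows; ``strongest``
    takes the maximum; ``synergistic_pair`` multiplies the two largest window
    occupancies (joint occupancy of the two strongest sites).  With
    cooperativity each window uses its strongest (lowest-k) partner within
    the allowed gap.
    """
    pi = _window_occupancies(seq, model, spec, coop)
    if spec.mode == "additive":
        return float(spec.s * pi.sum())
    if spec.mode == "strongest":
        return float(spec.s * pi.max())
    # synergistic pair: joint occupancy of the two strongest windows
    if pi.size == 1:
        return float(spec.s * pi[0])
    top = np.sort(pi)[-2:]
    return float(spec.s * top[0] * top[1])
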
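"""Closed-form accumulation of strong binding sites in an L-bp sequence.

The expected strong-site count z(t) obeys a linear gain-loss balance
``dz/dt = lambda_gain (z_max - z) - lambda_loss z`` whose solution relaxes
exponentially to ``B/A`` with ``A = lambda_gain + lambda_loss`` and
``B = z_max lambda_gain``.  The per-site gain rate is assembled from the
single-site hitting times of the fixed-state chain, either presite-limited
(early epoch, all L-n+1 overlapping positions available) or averaged over
all non-strong classes (late epoch, packed capacity ~ L/n).  An "ancient
site" — a formerly functional site decaying neutrally for a time t' —
biases one window's class distribution and accelerates later re-gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .binding import BindingModel, FitnessSpec, classify_binding
from .chain import (
    HittingTimeTable,
    MismatchDistribution,
    PopulationParams,
    RateMatrix,
    build_rate_matrix,
    hitting_times,
    propagate,
)
from .mutation import MutationModel, combined_rate_matrix

__all__ = [
    "PromoterTheoryParams",
    "AncientSiteSpec",
    "z_of_t",
    "newly_evolved",
    "newly_evolved_per_class",
    "gain_rate_presite",
    "gain_rate_all",
    "ancient_initial_distribution",
    "ancient_site_prediction",
]


@dataclass(frozen=True)
class PromoterTheoryParams:
    """Inputs of the z(t) model: sequence length ``L``, capacity ``z_max``
    (overlap-allowed ``L - n + 1`` or packed ``~ L/n``), per-site rates in
    units of u, the initial count ``z0``, the strong-class boundary
    ``k_strong`` and the initial per-window class distribution."""

    L: int
    z_max: float
    lambda_gain: float
    lambda_loss: float = 0.0
    z0: float = 0.0
    k_strong: Optional[int] = None
    psi_init: Optional[MismatchDistribution] = None

    def __post_init__(self):
        if self.lambda_gain < 0 or self.lambda_loss < 0:
            raise ValueError("rates must be nonnegative")
        if self.z0 > self.z_max:
            raise ValueError("z0 cannot exceed z_max")


@dataclass(frozen=True)
class AncientSiteSpec:
    """An ancient site of class ``k_ancient`` that decayed neutrally for
    ``t_prime`` (units 1/u) before the observation starts."""

    k_ancient: int
    t_prime: float

    def __post_init__(self):
        if self.k_ancient < 0:
            raise ValueError("k_ancient must be >= 0")
        if self.t_prime < 0:
            raise ValueError("t_prime must be >= 0")


def z_of_t(params: PromoterTheoryParams, t):
    """Expected strong-site count ``(z0 - B/A) e^{-A t} + B/A``; the A -> 0
    degenerate case reduces to linear growth ``z0 + (B - A z0) t``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    A = params.lambda_gain + params.lambda_loss
    B = params.z_max * params.lambda_gain
    if A < 1e-300:
        out = params.z0 + (B - A * params.z0) * t
    else:
        out = (params.z0 - B / A) * np.exp(-A * t) + B / A
    return out if out.ndim else float(out)


def _tail_mass(params: PromoterTheoryParams) -> float:
    if params.psi_init is None or params.k_strong is None:
        raise ValueError("newly_evolved needs psi_init and k_strong")
    return float(params.psi_init.psi[params.k_strong + 1 :].sum())


def newly_evolved(params: PromoterTheoryParams, t):
    """Strong-selection (negligible loss) count of newly evolved sites:
    ``(1 - e^{-lambda_gain t}) z_max sum_{k > k_strong} psi_k``."""
    t = np.asarray(t, dtype=float)
    out = -np.expm1(-params.lambda_gain * t) * params.z_max * _tail_mass(params)
    return out if out.ndim else float(out)


def newly_evolved_per_class(
    hitting: HittingTimeTable, psi: MismatchDistribution, z_max: float, t
):
    """Per-class refinement of the strong-selection accumulation curve: each
    non-strong window of class k converts independently at rate
    ``1 / <t>_{S<-k}``, giving
    ``z_max * sum_{k not in S} psi_k (1 - e^{-t / <t>_k})``."""
    t = np.asarray(t, dtype=float)[..., None]
    k_all = np.arange(psi.n + 1)
    outside = np.array([k not in hitting.target for k in k_all])
    times = hitting.times[outside]
    weights = psi.psi[outside]
    with np.errstate(divide="ignore"):
        rates = np.where(times > 0, 1.0 / times, np.inf)
    out = z_max * (weights * -np.expm1(-rates * t)).sum(axis=-1)
    return out if out.ndim else float(out)


def _non_strong_norm(hitting: HittingTimeTable, psi: MismatchDistribution) -> float:
    outside = [k for k in range(psi.n + 1) if k not in hitting.target]
    total = float(psi.psi[outside].sum())
    if total <= 0:
        raise ValueError("no probability mass outside the strong classes")
    return total


def gain_rate_presite(hitting: HittingTimeTable, psi: MismatchDistribution) -> float:
    """Presite-limited per-site gain rate (units of u):
    ``psi_{kS+1} / <t>_{S<-kS+1}`` normalised by the non-strong mass.
    Pairs with the overlap-allowed capacity ``z_max = L - n + 1``."""
    k_presite = max(hitting.target) + 1
    if k_presite > psi.n:
        raise ValueError("no presite class beyond the strong boundary")
    norm = _non_strong_norm(hitting, psi)
    mass = float(psi.psi[k_presite])
    if mass == 0.0:
        return 0.0
    return mass / float(hitting.times[k_presite]) / norm


def gain_rate_all(hitting: HittingTimeTable, psi: MismatchDistribution) -> float:
    """All-class per-site gain rate (units of u):
    ``sum_{k not in S} psi_k / <t>_{S<-k}`` normalised by the non-strong
    mass.  Pairs with the packed capacity ``z_max ~ L / n``."""
    norm = _non_strong_norm(hitting, psi)
    total = 0.0
    for k in range(psi.n + 1):
        if k in hitting.target or psi.psi[k] == 0.0:
            continue
        t = float(hitting.times[k])
        if np.isfinite(t) and t > 0:
            total += float(psi.psi[k]) / t
    return total / norm


def ancient_initial_distribution(
    ancient: AncientSiteSpec,
    L: int,
    binding: BindingModel,
    mut: MutationModel,
) -> MismatchDistribution:
    """Per-window class distribution of a length-L sequence containing one
    ancient site: a ``1/(L-n+1)`` mixture of the neutrally decayed ancient
    class with the binomial random background."""
    n = binding.n
    if ancient.k_ancient > n:
        raise ValueError("k_ancient cannot exceed n")
    nwin = L - n + 1
    if nwin < 1:
        raise ValueError("L must be >= n")
    U = combined_rate_matrix(n, mut)
    neutral = RateMatrix(U.matrix, n, metadata={"Ns": 0.0, "theta": mut.theta})
    psi_t = propagate(neutral, MismatchDistribution.delta(ancient.k_ancient, n), ancient.t_prime)
    background = MismatchDistribution.background(n, mut.alpha)
    mix = psi_t.psi / nwin + background.psi * (nwin - 1) / nwin
    return MismatchDistribution(mix, time_stamp=ancient.t_prime)


def ancient_site_prediction(
    ancient: Optional[AncientSiteSpec],
    L: int,
    binding: BindingModel,
    fitness: FitnessSpec,
    mut: MutationModel,
    pop: PopulationParams,
    t,
):
    """Expected newly evolved strong sites at time(s) ``t`` for a promoter
    whose background is biased by an ancient site (or unbiased when
    ``ancient`` is None), using the per-class decomposition of the gain rate
    with the overlap-allowed capacity."""
    classes = classify_binding(binding)
    R = build_rate_matrix(binding, fitness, mut, pop)
    ht = hitting_times(R, classes.strong)
    if ancient is None:
        psi = MismatchDistribution.background(binding.n, mut.alpha)
    else:
        psi = ancient_initial_distribution(ancient, L, binding, mut)
    z_max = L - binding.n + 1
    return newly_evolved_per_class(ht, psi, z_max, t)
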
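"""Origin–fixation (fixed-state) Markov chain over mismatch classes.

In the low-mutation limit the population is monomorphic almost always and
evolution reduces to a continuous-time Markov jump process on the mismatch
classes ``k = 0..n`` of a single binding site.  The transition rate from
class ``k`` to ``k'`` is the supply of mutations times their fixation
probability, ``R[k'][k] = 2N * U[k'][k] * P_fix(N, f(k') - f(k))``.  All
rates are expressed in units of the point mutation rate ``u`` and all times
in units of ``1/u``, matching how results are conventionally plotted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq
from scipy.stats import binom

from .binding import BindingModel, FitnessSpec, classify_binding, single_site_fitness
from .mutation import MutationModel, combined_rate_matrix

__all__ = [
    "PopulationParams",
    "MismatchDistribution",
    "RateMatrix",
    "HittingTimeTable",
    "fixation_probability",
    "build_rate_matrix",
    "stationary_distribution",
    "closed_form_stationary",
    "propagate",
    "convergence_rate",
    "hitting_times",
    "hitting_times_tridiagonal",
    "hitting_times_shortest_path",
    "ns_strong_selection_threshold",
    "bimodality_threshold",
    "kl_divergence",
]


@dataclass(frozen=True)
class PopulationParams:
    """Diploid population size ``N`` and selection strength ``s``; the
    product ``Ns`` governs the selection-drift balance."""

    N: int = 1000
    s: float = 0.1

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("population size N must be >= 1")

    @property
    def ns(self) -> float:
        return self.N * self.s

    @classmethod
    def from_ns(cls, ns: float, N: int = 1000) -> "PopulationParams":
        return cls(N=N, s=ns / N)

    def fixed_state_ok(self, u_beneficial: float, delta_f: float) -> bool:
        """Desai–Fisher check that a beneficial sweep completes before the
        next one arises: ``log(4N df)/df << 1/(4N U_b df)`` with ``U_b`` the
        beneficial mutation rate per individual per generation.  Emits a
        warning (not an error) when the establishment time exceeds half the
        waiting time."""
        if delta_f <= 0 or u_beneficial <= 0:
            return True
        x = 4.0 * self.N * delta_f
        if x <= 1.0:
            return True
        establish = np.log(x) / delta_f
        waiting = 1.0 / (4.0 * self.N * u_beneficial * delta_f)
        if establish > 0.5 * waiting:
            warnings.warn(
                f"fixed-state assumption questionable: establishment time {establish:.3g} "
                f"vs waiting time {waiting:.3g} generations",
                stacklevel=2,
            )
            return False
        return True


@dataclass
class MismatchDistribution:
    """Probability vector over mismatch classes ``k = 0..n``; ``time_stamp``
    (units 1/u) records the epoch it describes, if any."""

    psi: np.ndarray
    time_stamp: Optional[float] = None

    def __post_init__(self):
        p = np.asarray(self.psi, dtype=float)
        if p.ndim != 1:
            raise ValueError("psi must be a vector")
        if (p < -1e-12).any():
            raise ValueError("psi entries must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"psi must sum to 1, got {p.sum()!r}")
        self.psi = np.clip(p, 0.0, None)
        self.psi = self.psi / self.psi.sum()

    @property
    def n(self) -> int:
        return self.psi.size - 1

    @classmethod
    def delta(cls, k: int, n: int, time_stamp: float = 0.0) -> "MismatchDistribution":
        p = np.zeros(n + 1)
        p[k] = 1.0
        return cls(p, time_stamp)

    @classmethod
    def background(cls, n: int, alpha: float = 0.75) -> "MismatchDistribution":
        """Binomial mismatch distribution of a random background sequence."""
        return cls(binom.pmf(np.arange(n + 1), n, alpha))


@dataclass(frozen=True)
class RateMatrix:
    """Substitution-rate generator over mismatch classes, in units of ``u``."""

    R: np.ndarray
    n: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float)
        if R.shape != (self.n + 1, self.n + 1):
            raise ValueError("rate matrix shape must be (n+1, n+1)")
        off = R - np.diag(np.diag(R))
        if (off < -1e-12).any():
            raise ValueError("off-diagonal rates must be nonnegative")
        if np.abs(R.sum(axis=0)).max() > 1e-8 * max(1.0, np.abs(R).max()):
            raise ValueError("generator columns must sum to zero")
        object.__setattr__(self, "R", R)

    @property
    def is_tridiagonal(self) -> bool:
        mask = np.abs(np.arange(self.n + 1)[:, None] - np.arange(self.n + 1)[None, :]) > 1
        return not np.any(np.abs(self.R[mask]) > 1e-14 * max(1.0, np.abs(self.R).max()))


@dataclass(frozen=True)
class HittingTimeTable:
    """Mean first-hitting times (units 1/u) into ``target`` per starting class."""

    target: tuple
    times: np.ndarray
    method: str

    def rate(self, k: int) -> float:
        """Inverse hitting time from class ``k`` (inf inside the target)."""
        t = self.times[k]
        return float(np.inf) if t == 0 else 1.0 / float(t)


def fixation_probability(N: int, delta_f):
    """Kimura's diffusion-approximation fixation probability of a single new
    mutant with selection coefficient ``delta_f`` in ``N`` diploids:
    ``(1 - exp(-2 df)) / (1 - exp(-4 N df))``, with the neutral limit
    ``1/(2N)`` evaluated by series for ``|4 N df|`` below 1e-8."""
    if N < 1:
        raise ValueError("N must be >= 1")
    df = np.asarray(delta_f, dtype=float)
    out = np.empty_like(df)
    out[np.isposinf(df)] = 1.0
    out[np.isneginf(df)] = 0.0
    finite = np.isfinite(df)
    dff = df[finite]
    x = 4.0 * N * dff
    val = np.empty_like(dff)
    small = np.abs(x) < 1e-8
    # second-order series around df = 0
    val[small] = (1.0 / (2.0 * N)) * (1.0 + (2.0 * N - 1.0) * dff[small])
    mid = ~small & (x >= -700.0)
    val[mid] = -np.expm1(-2.0 * dff[mid]) / -np.expm1(-x[mid])
    # deep-deleterious branch in log space; log(expm1(y)) ~ y for large y
    deep = ~small & (x < -700.0)
    y = -2.0 * dff[deep]
    log_num = np.where(y > 50.0, y, np.log(np.expm1(np.minimum(y, 50.0))))
    val[deep] = np.exp(log_num + x[deep])
    out[finite] = val
    return out if out.ndim else float(out)


def _scaled_fixation_factor(N: int, delta_f: np.ndarray) -> np.ndarray:
    """``2N * P_fix(N, df)``, evaluated so that neutrality gives exactly 1
    (the substitution rate then reduces to the mutation rate bit-for-bit)."""
    df = np.asarray(delta_f, dtype=float)
    out = np.empty_like(df)
    small = np.abs(4.0 * N * df) < 1e-8
    out[small] = 1.0 + (2.0 * N - 1.0) * df[small]
    out[~small] = 2.0 * N * fixation_probability(N, df[~small])
    return out


def build_rate_matrix(
    binding: BindingModel,
    fitness: FitnessSpec,
    mut: MutationModel,
    pop: PopulationParams,
) -> RateMatrix:
    """Assemble the origin-fixation generator ``R`` (units of ``u``) from the
    mutation generator and the single-site fitness landscape."""
    n = binding.n
    U = combined_rate_matrix(n, mut).matrix
    f = single_site_fitness(np.arange(n + 1), fitness, binding)
    df = f[:, None] - f[None, :]  # df[k', k] = f(k') - f(k)
    R = U * _scaled_fixation_factor(pop.N, df)
    np.fill_diagonal(R, 0.0)
    np.fill_diagonal(R, -R.sum(axis=0))
    return RateMatrix(
        R,
        n,
        metadata={
            "epsilon": binding.epsilon,
            "mu": binding.mu,
            "Ns": pop.ns,
            "N": pop.N,
            "theta": mut.theta,
            "mode": fitness.mode,
        },
    )


def stationary_distribution(R: RateMatrix) -> MismatchDistribution:
    """Stationary distribution as the null vector of the generator.

    Uses the eigen-decomposition (eigenvalue nearest zero) with a fallback
    to a normalised linear solve; entries are clipped at round-off level and
    renormalized.  Raises if the chain is reducible (no unique null vector).
    """
    ev, V = np.linalg.eig(R.R)
    order = np.argsort(np.abs(ev))
    if len(ev) > 1 and np.abs(ev[order[1]]) < 1e-12:
        raise ValueError("reducible chain: zero eigenvalue is not simple")
    v = np.real(V[:, order[0]])
    if np.abs(np.sum(v)) < 1e-12 * np.abs(v).max():  # degenerate eigenvector; fall back
        A = np.vstack([R.R, np.ones(R.n + 1)])
        b = np.zeros(R.n + 2)
        b[-1] = 1.0
        v, *_ = np.linalg.lstsq(A, b, rcond=None)
    v = np.where(v < 0, np.where(v > -1e-12 * np.abs(v).max(), 0.0, v), v)
    if (v < 0).any() and (v > 0).any():
        v = -v if v.sum() < 0 else v
        v = np.clip(v, 0.0, None)
    return MismatchDistribution(v / v.sum())


def closed_form_stationary(
    binding: BindingModel,
    fitness: FitnessSpec,
    pop: PopulationParams,
    alpha: float = 0.75,
) -> MismatchDistribution:
    """Point-mutation-only closed form: ``psi_k ∝ exp(F + H)`` with the
    selection term ``F`` and the mutational entropy
    ``H = log phi_k(n, alpha)`` (log binomial redundancy).

    ``F = 2(2N - 1) f(k)`` is the exact detailed-balance exponent of the
    origin-fixation chain built on the diffusion fixation probability
    (the ratio of forward and backward fixation probabilities is
    ``exp((4N - 2) df)``); the conventional ``4 N f(k)`` is its N >> 1
    limit and differs only at relative order 1/(2N)."""
    n = binding.n
    ks = np.arange(n + 1)
    F = 2.0 * (2.0 * pop.N - 1.0) * single_site_fitness(ks, fitness, binding)
    H = binom.logpmf(ks, n, alpha)
    logw = F + H
    w = np.exp(logw - logw.max())
    return MismatchDistribution(w / w.sum())


def propagate(R: RateMatrix, psi0: MismatchDistribution, t: float) -> MismatchDistribution:
    """Evolve the class distribution for time ``t`` (units 1/u):
    ``psi(t) = expm(R t) psi(0)``."""
    if t < 0:
        raise ValueError("time must be nonnegative")
    psi = expm(R.R * t) @ psi0.psi
    psi = np.clip(psi, 0.0, None)
    base = psi0.time_stamp or 0.0
    return MismatchDistribution(psi / psi.sum(), time_stamp=base + t)


def convergence_rate(R: RateMatrix) -> float:
    """|lambda_2|: magnitude of the nonzero eigenvalue closest to zero, the
    asymptotic rate of convergence to stationarity (units of u)."""
    ev = np.linalg.eigvals(R.R)
    mags = np.sort(np.abs(ev))
    if mags[0] > 1e-8 * max(1.0, mags[-1]):
        warnings.warn("no numerically zero eigenvalue found; generator may be invalid")
    lam2 = mags[1]
    if len(mags) > 2 and abs(mags[2] - lam2) < 1e-12 * max(1.0, lam2):
        warnings.warn("degenerate subdominant spectrum: |lambda_2| is not isolated")
    return float(lam2)


def _as_target(target: Iterable[int], n: int) -> tuple:
    tgt = tuple(sorted(set(int(k) for k in target)))
    if not tgt:
        raise ValueError("target class set must be nonempty")
    if tgt[0] < 0 or tgt[-1] > n:
        raise ValueError("target classes out of range")
    if len(tgt) > n:
        raise ValueError("complement of target must be nonempty")
    return tgt


def hitting_times(R: RateMatrix, target: Iterable[int]) -> HittingTimeTable:
    """Mean first-hitting times into ``target`` from every class.

    Solves the standard linear system on the transient classes: with the
    generator restricted to the complement of the target, ``A^T t = -1``.
    Supports arbitrary targets, including single classes.
    """
    tgt = _as_target(target, R.n)
    trans = [k for k in range(R.n + 1) if k not in tgt]
    A = R.R[np.ix_(trans, trans)]
    try:
        t = np.linalg.solve(A.T, -np.ones(len(trans)))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular hitting-time system (target {tgt} unreachable from some class): {exc}"
        ) from exc
    if not np.all(np.isfinite(t)) or (t <= 0).any():
        raise ArithmeticError(
            "hitting-time system is numerically ill-conditioned (times overflow the "
            "floating-point range, e.g. loss under strong positive selection)"
        )
    times = np.zeros(R.n + 1)
    times[trans] = t
    return HittingTimeTable(tgt, times, "exact")


def _check_contiguous_boundary(tgt: tuple, n: int) -> str:
    """Gain targets are prefixes {0..kS}; loss targets suffixes {kW..n}."""
    if tgt == tuple(range(tgt[0], tgt[-1] + 1)):
        if tgt[0] == 0:
            return "gain"
        if tgt[-1] == n:
            return "loss"
    raise ValueError(
        "tridiagonal/shortest-path formulae need a contiguous boundary target "
        "(a prefix {0..kS} for gain or suffix {kW..n} for loss)"
    )


def _log_stationary_steps(R: RateMatrix) -> np.ndarray:
    """``lr[l] = log(psi_l / psi_{l-1})`` for l = 1..n from detailed balance,
    ``psi_l / psi_{l-1} = R[l, l-1] / R[l-1, l]``.  Stable where the
    stationary tail masses themselves underflow."""
    up = np.diag(R.R, -1)  # R[l, l-1], rates l-1 -> l
    down = np.diag(R.R, 1)  # R[l-1, l], rates l -> l-1
    if (up <= 0).any() or (down <= 0).any():
        raise ValueError("tridiagonal chain has a zero nearest-neighbour rate")
    return np.log(up) - np.log(down)


def hitting_times_tridiagonal(
    R: RateMatrix, psi_hat: Optional[MismatchDistribution], target: Iterable[int]
) -> HittingTimeTable:
    """Closed-form hitting times for the point-mutation-only (tridiagonal)
    chain, built from the cumulative stationary distribution Psi:

    gain:  t(k) = sum_{i=kS+1..k} (1/R[i-1,i]) (1 - Psi[i-1]) / psi[i]
    loss:  t(k) = sum_{i=k+1..kW} (1/R[i-1,i]) Psi[i-1] / psi[i]

    The stationary ratios are evaluated in log space through the
    detailed-balance identity psi_l/psi_{l-1} = R[l,l-1]/R[l-1,l], which
    stays finite where the tail masses of ``psi_hat`` underflow; the
    explicit ``psi_hat`` argument (when given) is only sanity-checked
    against the rate matrix.
    """
    if not R.is_tridiagonal:
        raise ValueError("chain is not tridiagonal (theta > 0?); use hitting_times")
    tgt = _as_target(target, R.n)
    kind = _check_contiguous_boundary(tgt, R.n)
    lr = _log_stationary_steps(R)
    cum = np.concatenate([[0.0], np.cumsum(lr)])  # cum[j] = log(psi_j / psi_0)
    if psi_hat is not None:
        # compare only well-resolved entries; underflowed tail masses carry
        # eigensolver noise rather than information
        ok = psi_hat.psi > 1e-8 * psi_hat.psi.max()
        if ok.sum() > 1:
            ref = np.log(psi_hat.psi[ok])
            if not np.allclose(np.diff(ref), np.diff(cum[ok]), atol=1e-6):
                warnings.warn("psi_hat is not the stationary distribution of R")
    times = np.zeros(R.n + 1)
    if kind == "gain":
        k_s = tgt[-1]
        acc = 0.0
        for k in range(k_s + 1, R.n + 1):
            # (1 - Psi[k-1]) / psi[k] = sum_{j >= k} exp(cum[j] - cum[k])
            tail = cum[k:] - cum[k]
            acc += (1.0 / R.R[k - 1, k]) * np.exp(tail).sum()
            times[k] = acc
    else:
        k_w = tgt[0]
        for k in range(k_w - 1, -1, -1):
            acc = 0.0
            for i in range(k + 1, k_w + 1):
                # Psi[i-1] / psi[i] = sum_{j < i} exp(cum[j] - cum[i])
                head = cum[:i] - cum[i]
                acc += (1.0 / R.R[i - 1, i]) * np.exp(head).sum()
            times[k] = acc
    return HittingTimeTable(tgt, times, "tridiagonal")


def hitting_times_shortest_path(R: RateMatrix, target: Iterable[int]) -> HittingTimeTable:
    """Strong-selection "shortest path" approximation: the sum of inverse
    forward rates along the monotone path into the target.

    gain:  t(k) ≈ sum_{i=kS+1..k} 1 / R[i-1, i]      (steps i -> i-1)
    loss:  t(k) ≈ sum_{i=k+1..kW} 1 / R[i, i-1]      (steps i-1 -> i)
    """
    tgt = _as_target(target, R.n)
    kind = _check_contiguous_boundary(tgt, R.n)
    times = np.zeros(R.n + 1)
    if kind == "gain":
        k_s = tgt[-1]
        acc = 0.0
        for k in range(k_s + 1, R.n + 1):
            r = R.R[k - 1, k]
            if r <= 0:
                raise ZeroDivisionError(f"zero rate on path at step {k}->{k-1}")
            acc += 1.0 / r
            times[k] = acc
    else:
        k_w = tgt[0]
        for k in range(k_w - 1, -1, -1):
            acc = 0.0
            for i in range(k + 1, k_w + 1):
                r = R.R[i, i - 1]
                if r <= 0:
                    raise ZeroDivisionError(f"zero rate on path at step {i-1}->{i}")
                acc += 1.0 / r
            times[k] = acc
    return HittingTimeTable(tgt, times, "shortest_path")


def ns_strong_selection_threshold(n: int, alpha: float = 0.75) -> dict:
    """Threshold ``Ns`` separating weak (bimodal stationary) from strong
    selection.  Returns the full expression
    ``(1/4)(n log 4 - (1/2) log(2 pi alpha (1-alpha) n))`` and the dominant
    linear approximation ``n log(2) / 2``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    full = 0.25 * (n * np.log(4.0) - 0.5 * np.log(2.0 * np.pi * alpha * (1.0 - alpha) * n))
    return {"full": float(full), "linear": float(n * np.log(2.0) / 2.0)}


def bimodality_threshold(
    binding: BindingModel,
    mut: MutationModel,
    ns_grid: Sequence[float],
    N: int = 1000,
    mass: float = 0.05,
    fitness_mode: str = "additive",
    gamma: Optional[float] = None,
) -> float:
    """Selection strength at which ``mass`` (default 5%) of the stationary
    weight sits outside the strong classes, located by bisection in Ns."""
    classes = classify_binding(binding)

    def non_strong_mass(ns: float) -> float:
        pop = PopulationParams.from_ns(ns, N)
        spec = FitnessSpec(s=pop.s, mode=fitness_mode, power_law_gamma=gamma)
        R = build_rate_matrix(binding, spec, mut, pop)
        psi = stationary_distribution(R).psi
        return float(psi[classes.k_strong + 1 :].sum())

    grid = np.asarray(sorted(ns_grid), dtype=float)
    vals = np.array([non_strong_mass(ns) for ns in grid])
    above = vals - mass
    if not (above[0] > 0 > above[-1]):
        raise ValueError(
            f"Ns grid does not bracket the {mass:.0%} threshold: masses {vals[0]:.3g}..{vals[-1]:.3g}"
        )
    i = int(np.nonzero(above > 0)[0][-1])
    return float(brentq(lambda ns: non_strong_mass(ns) - mass, grid[i], grid[i + 1], xtol=1e-3))


def kl_divergence(p: MismatchDistribution | np.ndarray, q: MismatchDistribution | np.ndarray) -> float:
    """Kullback-Leibler divergence D(p||q) in nats; zero-mass classes of p
    contribute 0 by continuity.  Reference masses that underflowed to zero
    (stiff strong-selection chains) are floored at the smallest positive
    normal float to keep the divergence finite."""
    pa = p.psi if isinstance(p, MismatchDistribution) else np.asarray(p, float)
    qa = q.psi if isinstance(q, MismatchDistribution) else np.asarray(q, float)
    mask = pa > 0
    qfloor = np.maximum(qa[mask], np.finfo(float).tiny)
    return float(np.sum(pa[mask] * (np.log(pa[mask]) - np.log(qfloor))))
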
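"""Forward Wright-Fisher simulation of regulatory sequence evolution.

``2N`` haplotypes of length ``L`` evolve by per-bp point and indel mutation
followed by fitness-proportional multinomial resampling (genic selection
with weights ``exp(f)``, no dominance — equivalent to a haploid population
of ``2N``).  The simulator validates the fixed-state (origin-fixation) chain
at low ``Nu`` and exercises regimes where that approximation degrades:
appreciable polymorphism (higher ``Nu``), cooperativity, and alternative
promoter fitness modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .binding import (
    BindingModel,
    CooperativityParams,
    FitnessSpec,
    _effective_pi_table,
    cooperative_partner_mismatches,
    encode_sequence,
    occupancy_cooperative,
)
from .chain import fixation_probability
from .mutation import MutationModel, apply_indel, apply_point_mutation

__all__ = [
    "Population",
    "Trajectory",
    "TrajectoryEnsemble",
    "GainLossResult",
    "StrongSiteCount",
    "wf_generation",
    "simulate_single_site",
    "simulate_promoter",
    "count_strong_sites",
]


@dataclass
class Population:
    """State of the simulated population: ``2N`` haplotype sequences (uint8
    codes, shape ``(2N, L)``), a generation counter, and cached fitnesses."""

    haplotypes: np.ndarray
    generation: int = 0
    fitness: Optional[np.ndarray] = None

    def __post_init__(self):
        h = np.asarray(self.haplotypes, dtype=np.uint8)
        if h.ndim != 2:
            raise ValueError("haplotypes must be a (2N, L) array")
        if h.shape[0] % 2:
            raise ValueError("haplotype count must be 2N (even)")
        self.haplotypes = h

    @property
    def size(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def L(self) -> int:
        return self.haplotypes.shape[1]

    @classmethod
    def monomorphic(cls, seq: str | np.ndarray, N: int) -> "Population":
        arr = encode_sequence(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.uint8)
        return cls(np.tile(arr, (2 * N, 1)))


@dataclass
class Trajectory:
    """One replicate: sampled times (units 1/u, strictly increasing) with the
    population-mean strong-site count, the modal-sequence raw/greedy counts,
    and mean fitness."""

    times: np.ndarray
    z_mean: np.ndarray
    z_modal: np.ndarray
    z_greedy: np.ndarray
    mean_fitness: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sampled times must be strictly increasing")


@dataclass
class TrajectoryEnsemble:
    """Replicate ensemble on a common time grid (units 1/u).  ``z0`` holds
    each replicate's strong-site count at t = 0 (the initial sequence)."""

    times: np.ndarray
    z_mean: np.ndarray  # (replicates, T) population-mean strong-site count
    z_modal: np.ndarray
    z_greedy: np.ndarray
    mean_fitness: np.ndarray
    z0: np.ndarray

    @property
    def new_sites(self) -> np.ndarray:
        """Newly evolved sites per replicate: z(t) - z(0)."""
        return self.z_mean - self.z0[:, None]

    def new_sites_mean_sem(self):
        ns = self.new_sites
        return ns.mean(axis=0), ns.std(axis=0, ddof=1) / np.sqrt(ns.shape[0])


@dataclass
class GainLossResult:
    """First-passage summary over replicates (times in 1/u; censored
    replicates carry NaN and are excluded from the mean)."""

    times: np.ndarray
    censored: int
    target: tuple

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.times))

    @property
    def sem(self) -> float:
        ok = self.times[~np.isnan(self.times)]
        return float(ok.std(ddof=1) / np.sqrt(ok.size)) if ok.size > 1 else float("nan")


@dataclass(frozen=True)
class StrongSiteCount:
    z: int
    z_greedy: int
    occupancies: np.ndarray


class _FitnessEngine:
    """Vectorised occupancy/fitness/strong-site evaluation for row batches.

    Precomputes per-class occupancy tables (with optional power-law tail and
    cooperativity) so that the per-generation cost is table lookups on
    window mismatch counts.
    """

    def __init__(
        self,
        binding: BindingModel,
        fitness: FitnessSpec,
        coop: Optional[CooperativityParams] = None,
    ):
        self.binding = binding
        self.fitness = fitness
        self.coop = coop if (coop is not None and coop.e_c != 0.0) else None
        self.cons = binding.consensus_array
        self.n = binding.n
        self.pi_table = _effective_pi_table(binding, fitness)
        if self.coop is not None:
            n = self.n
            kk, kc = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
            coop_tab = occupancy_cooperative(kk, kc, binding, self.coop)
            # extra column: "no partner" sentinel k_c = n+1 -> plain occupancy
            self.pi2 = np.column_stack([coop_tab, self.pi_table])
        else:
            self.pi2 = None

    def window_k(self, rows: np.ndarray) -> np.ndarray:
        w = sliding_window_view(rows, self.n, axis=1)
        return (w != self.cons).sum(axis=2)

    def window_pi(self, rows: np.ndarray) -> np.ndarray:
        ks = self.window_k(rows)
        if self.pi2 is None:
            return self.pi_table[ks]
        kc = cooperative_partner_mismatches(np.atleast_2d(ks), self.n, self.coop.window)
        return self.pi2[ks, kc]

    def __call__(self, rows: np.ndarray) -> np.ndarray:
        """Fitness of each row."""
        pi = self.window_pi(rows)
        s = self.fitness.s
        if self.fitness.mode == "additive":
            return s * pi.sum(axis=1)
        if self.fitness.mode == "strongest":
            return s * pi.max(axis=1)
        if pi.shape[1] == 1:
            return s * pi[:, 0]
        part = np.partition(pi, pi.shape[1] - 2, axis=1)
        return s * part[:, -1] * part[:, -2]

    def strong_counts(self, rows: np.ndarray) -> np.ndarray:
        return (self.window_pi(rows) > 2.0 / 3.0).sum(axis=1)

    def classes(self, rows: np.ndarray) -> np.ndarray:
        """Single-site mismatch class (valid when L == n)."""
        return (rows != self.cons).sum(axis=1)


def _mutate_population(
    seqs: np.ndarray, mut: MutationModel, rng: np.random.Generator
) -> np.ndarray:
    """Apply one generation of mutation in place; return indices of rows touched."""
    m, L = seqs.shape
    touched = []
    n_point = rng.binomial(m * L, mut.u)
    if n_point:
        rows = rng.integers(m, size=n_point)
        cols = rng.integers(L, size=n_point)
        seqs[rows, cols] = (seqs[rows, cols] + rng.integers(1, 4, size=n_point)) % 4
        touched.append(rows)
    if mut.theta > 0:
        n_indel = rng.binomial(m * L, mut.theta * mut.u)
        if n_indel:
            rows = rng.integers(m, size=n_indel)
            for r in rows:
                apply_indel(seqs[r], mut, rng)
            touched.append(rows)
    return np.unique(np.concatenate(touched)) if touched else np.empty(0, dtype=int)


def _resample(
    seqs: np.ndarray, fit: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    w = np.exp(fit - fit.max())
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("selection weights are all zero or non-finite")
    counts = rng.multinomial(seqs.shape[0], w / total)
    idx = np.repeat(np.arange(seqs.shape[0]), counts)
    return seqs[idx], fit[idx]


def wf_generation(
    pop: Population,
    binding: BindingModel,
    fitness: FitnessSpec,
    mut: MutationModel,
    rng: np.random.Generator,
    coop: Optional[CooperativityParams] = None,
    engine: Optional[_FitnessEngine] = None,
) -> Population:
    """Advance the population one generation: mutation, then
    fitness-proportional multinomial resampling at constant size."""
    eng = engine if engine is not None else _FitnessEngine(binding, fitness, coop)
    seqs = np.array(pop.haplotypes, copy=True)
    fit = pop.fitness.copy() if pop.fitness is not None else eng(seqs)
    touched = _mutate_population(seqs, mut, rng)
    if touched.size:
        fit[touched] = eng(seqs[touched])
    seqs, fit = _resample(seqs, fit, rng)
    return Population(seqs, pop.generation + 1, fit)


def _spawn_rngs(rng: np.random.Generator, k: int) -> list:
    return [np.random.Generator(np.random.PCG64(ss)) for ss in rng.bit_generator.seed_seq.spawn(k)]


def simulate_single_site(
    binding: BindingModel,
    fitness: FitnessSpec,
    mut: MutationModel,
    pop_params,
    k0: int,
    target: Iterable[int],
    replicates: int,
    rng: np.random.Generator,
    max_time: float = 10.0,
    majority: float = 0.5,
) -> GainLossResult:
    """First time the population-majority class enters ``target`` (units 1/u).

    The population starts monomorphic at ``k0`` mismatches (L = n); the
    event fires when more than ``majority`` of haplotypes carry a class in
    the target set.  Replicates still unresolved at ``max_time`` are
    censored (NaN).
    """
    n = binding.n
    target = tuple(sorted(set(int(t) for t in target)))
    in_target = np.zeros(n + 1, dtype=bool)
    in_target[list(target)] = True
    eng = _FitnessEngine(binding, fitness, None)
    fit_table = fitness.s * eng.pi_table  # class -> fitness at L == n
    N = pop_params.N
    m = 2 * N
    max_gens = int(np.ceil(max_time / mut.u))
    times = np.full(replicates, np.nan)
    censored = 0
    for rep, sub in enumerate(_spawn_rngs(rng, replicates)):
        if k0 in target:
            times[rep] = 0.0
            continue
        seq = binding.consensus_array.copy()
        pos = sub.choice(n, size=k0, replace=False)
        seq[pos] = (seq[pos] + sub.integers(1, 4, size=k0)) % 4
        seqs = np.tile(seq, (m, 1))
        ks = np.full(m, k0)
        fit = fit_table[ks]
        g = 0
        while g < max_gens:
            g += 1
            touched = _mutate_population(seqs, mut, sub)
            if touched.size:
                ks[touched] = (seqs[touched] != eng.cons).sum(axis=1)
                fit[touched] = fit_table[ks[touched]]
            w = np.exp(fit - fit.max())
            counts = sub.multinomial(m, w / w.sum())
            idx = np.repeat(np.arange(m), counts)
            seqs, ks, fit = seqs[idx], ks[idx], fit[idx]
            if in_target[ks].mean() > majority:
                times[rep] = g * mut.u
                break
        else:
            censored += 1
    return GainLossResult(times, censored, target)


def simulate_promoter(
    binding: BindingModel,
    fitness: FitnessSpec,
    mut: MutationModel,
    pop_params,
    L: int,
    t_grid: Sequence[float],
    replicates: int,
    rng: np.random.Generator,
    seq0: Optional[Callable[[np.random.Generator], np.ndarray]] = None,
    coop: Optional[CooperativityParams] = None,
    engine: str = "wright_fisher",
) -> TrajectoryEnsemble:
    """Ensemble of promoter trajectories sampled on ``t_grid`` (units 1/u).

    Each replicate starts monomorphic at a sequence drawn by ``seq0(rng)``
    (uniform random by default) and records the population-mean raw
    strong-site count, the modal sequence's raw and greedy counts, and mean
    fitness at each grid time.

    ``engine`` selects the simulator: ``"wright_fisher"`` evolves the full
    2N-haplotype population; ``"fixed_state"`` runs the origin-fixation
    jump process directly on a single sequence (mutations arise at rate
    ``2N L u (1 + theta)`` per generation and fix instantly with the
    diffusion-approximation probability).  The fixed-state engine has no
    sweep lag and is the natural comparator for the single-site chain
    theory; the Wright-Fisher engine additionally carries polymorphism.
    """
    if L < binding.n:
        raise ValueError("L must be >= n")
    if engine == "fixed_state":
        return _simulate_promoter_fixed_state(
            binding, fitness, mut, pop_params, L, t_grid, replicates, rng, seq0, coop
        )
    if engine != "wright_fisher":
        raise ValueError(f"unknown engine {engine!r}")
    t_grid = np.asarray(sorted(t_grid), dtype=float)
    sample_gens = np.unique(np.maximum(np.round(t_grid / mut.u).astype(int), 0))
    # map back: for each requested t use the nearest realised generation
    eng = _FitnessEngine(binding, fitness, coop)
    m = 2 * pop_params.N
    T = t_grid.size
    z_mean = np.empty((replicates, T))
    z_modal = np.empty((replicates, T), dtype=int)
    z_greedy = np.empty((replicates, T), dtype=int)
    mean_fit = np.empty((replicates, T))
    z0 = np.empty(replicates)
    for rep, sub in enumerate(_spawn_rngs(rng, replicates)):
        seq = seq0(sub) if seq0 is not None else sub.integers(0, 4, size=L).astype(np.uint8)
        seqs = np.tile(np.asarray(seq, dtype=np.uint8), (m, 1))
        fit = eng(seqs)
        z0[rep] = count_strong_sites(np.asarray(seq, dtype=np.uint8), binding, coop).z
        g = 0
        for j, t in enumerate(t_grid):
            gens_needed = int(round(t / mut.u))
            while g < gens_needed:
                g += 1
                touched = _mutate_population(seqs, mut, sub)
                if touched.size:
                    fit[touched] = eng(seqs[touched])
                w = np.exp(fit - fit.max())
                counts = sub.multinomial(m, w / w.sum())
                idx = np.repeat(np.arange(m), counts)
                seqs, fit = seqs[idx], fit[idx]
            z_mean[rep, j] = eng.strong_counts(seqs).mean()
            modal = _modal_row(seqs)
            sc = count_strong_sites(modal, binding, coop)
            z_modal[rep, j] = sc.z
            z_greedy[rep, j] = sc.z_greedy
            mean_fit[rep, j] = fit.mean()
    return TrajectoryEnsemble(t_grid, z_mean, z_modal, z_greedy, mean_fit, z0)


def _simulate_promoter_fixed_state(
    binding, fitness, mut, pop_params, L, t_grid, replicates, rng, seq0, coop
) -> TrajectoryEnsemble:
    """Origin-fixation jump process on a single L-bp sequence: candidate
    mutations arise as a Poisson process and each fixes with probability
    ``P_fix(N, delta_f)`` computed from the full promoter fitness."""
    t_grid = np.asarray(sorted(t_grid), dtype=float)
    eng = _FitnessEngine(binding, fitness, coop)
    N = pop_params.N
    arise_rate = 2.0 * N * L * (1.0 + mut.theta)  # candidate mutants per unit 1/u
    T = t_grid.size
    z_mean = np.empty((replicates, T))
    z_modal = np.empty((replicates, T), dtype=int)
    z_greedy = np.empty((replicates, T), dtype=int)
    mean_fit = np.empty((replicates, T))
    z0 = np.empty(replicates)
    p_indel = mut.theta / (1.0 + mut.theta)
    for rep, sub in enumerate(_spawn_rngs(rng, replicates)):
        seq = (
            np.asarray(seq0(sub), dtype=np.uint8)
            if seq0 is not None
            else sub.integers(0, 4, size=L).astype(np.uint8)
        )
        f = float(eng(seq[None, :])[0])
        z0[rep] = count_strong_sites(seq, binding, coop).z
        t = 0.0
        j = 0
        while j < T:
            t_next = t + sub.exponential(1.0 / arise_rate)
            while j < T and t_grid[j] < t_next:
                sc = count_strong_sites(seq, binding, coop)
                z_mean[rep, j] = sc.z
                z_modal[rep, j] = sc.z
                z_greedy[rep, j] = sc.z_greedy
                mean_fit[rep, j] = f
                j += 1
            t = t_next
            cand = seq.copy()
            if sub.random() < p_indel:
                apply_indel(cand, mut, sub)
            else:
                apply_point_mutation(cand, sub)
            f_cand = float(eng(cand[None, :])[0])
            if sub.random() < fixation_probability(N, f_cand - f):
                seq, f = cand, f_cand
    return TrajectoryEnsemble(t_grid, z_mean, z_modal, z_greedy, mean_fit, z0)


def _modal_row(seqs: np.ndarray) -> np.ndarray:
    uniq, counts = np.unique(seqs, axis=0, return_counts=True)
    return uniq[np.argmax(counts)]


def evolve_neutral(
    seq: np.ndarray,
    mut: MutationModel,
    t: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Neutral fixed-state evolution of a sequence for time ``t`` (units
    1/u): substitutions accrue as a Poisson process at rate ``L (1+theta)``
    per unit time (every arising mutation fixes with probability 1/2N,
    cancelling the 2N supply factor), each a random point or indel edit."""
    arr = np.array(seq, dtype=np.uint8, copy=True)
    n_events = rng.poisson(arr.size * (1.0 + mut.theta) * t)
    p_indel = mut.theta / (1.0 + mut.theta)
    for _ in range(n_events):
        if rng.random() < p_indel:
            apply_indel(arr, mut, rng)
        else:
            apply_point_mutation(arr, rng)
    return arr


def count_strong_sites(
    seq: str | np.ndarray,
    binding: BindingModel,
    coop: Optional[CooperativityParams] = None,
) -> StrongSiteCount:
    """Number of windows with (cooperativity-adjusted) occupancy above 2/3.

    The raw overlap-allowed count is primary (the additive fitness is
    overlap-blind); a greedy left-to-right non-overlapping count is also
    reported for comparability with packed-site bookkeeping.
    """
    eng = _FitnessEngine(binding, FitnessSpec(s=1.0), coop)
    arr = encode_sequence(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.uint8)
    pi = eng.window_pi(arr[None, :])[0]
    strong = pi > 2.0 / 3.0
    z = int(strong.sum())
    z_greedy = 0
    next_free = 0
    for start in np.nonzero(strong)[0]:
        if start >= next_free:
            z_greedy += 1
            next_free = start + binding.n
    return StrongSiteCount(z, z_greedy, pi)
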
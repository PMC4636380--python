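"""Synthetic input generators: random backgrounds, planted sites, decayed
ancient sites and Gaussian-perturbed energy matrices.  Everything is
reproducible from an explicit seeded generator."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import truncnorm

from .binding import ALPHABET, decode_sequence, encode_sequence

__all__ = [
    "FixtureSpec",
    "random_sequence",
    "plant_site",
    "gaussian_energy_matrix",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative recipe for a test input: a length-L background with
    optional planted sites (position, mismatch count) and an optional
    Gaussian energy matrix (mean specificity, sd)."""

    L: int
    n: int
    seed: int
    composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    plant: tuple = ()
    gaussian_matrix: Optional[tuple] = None  # (mean_eps, sd)

    def __post_init__(self):
        for pos, k in self.plant:
            if pos < 0 or pos + self.n > self.L:
                raise ValueError(f"planted site at {pos} does not fit in L={self.L}")
            if k > self.n:
                raise ValueError("planted mismatch count exceeds n")
        if self.gaussian_matrix is not None and self.gaussian_matrix[1] < 0:
            raise ValueError("sd must be >= 0")

    def realize(self, consensus: str):
        """Materialise (sequence, energy_matrix-or-None) from this recipe."""
        rng = np.random.default_rng(self.seed)
        seq = random_sequence(self.L, self.composition, rng)
        for pos, k in self.plant:
            seq = plant_site(seq, consensus, pos, k, rng)
        matrix = None
        if self.gaussian_matrix is not None:
            matrix = gaussian_energy_matrix(self.n, *self.gaussian_matrix, rng)
        return seq, matrix


def random_sequence(L: int, composition=None, rng: Optional[np.random.Generator] = None) -> str:
    """i.i.d. ACGT string of length L with the given base probabilities."""
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    if composition is None:
        p = np.full(4, 0.25)
    else:
        p = np.asarray(composition, dtype=float)
        if p.shape != (4,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("composition must be 4 nonnegative probabilities summing to 1")
    return decode_sequence(rng.choice(4, size=L, p=p))


def plant_site(
    seq: str,
    consensus: str,
    position: int,
    k: int,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Overwrite ``seq[position:position+n]`` with a site exactly ``k``
    mismatches from ``consensus`` (mismatch positions uniform without
    replacement, mismatched bases uniform among the three alternatives)."""
    n = len(consensus)
    if k > n:
        raise ValueError(f"k={k} exceeds site length n={n}")
    if position < 0 or position + n > len(seq):
        raise ValueError("planted site does not fit in the sequence")
    rng = rng if rng is not None else np.random.default_rng()
    site = encode_sequence(consensus)
    pos = rng.choice(n, size=k, replace=False)
    site[pos] = (site[pos] + rng.integers(1, 4, size=k)) % 4
    arr = encode_sequence(seq)
    arr[position : position + n] = site
    return decode_sequence(arr)


def gaussian_energy_matrix(
    n: int,
    mean_eps: float = 2.0,
    sd: float = 0.5,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """4 x n energy matrix with zero consensus entries (uniform random row
    per column) and non-consensus energies drawn from a Normal(mean, sd)
    truncated at zero — the consensus stays the minimum-energy base."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = rng if rng is not None else np.random.default_rng()
    xi = np.empty((4, n))
    if sd == 0:
        xi[:] = mean_eps
    else:
        a = (0.0 - mean_eps) / sd
        xi[:] = truncnorm.rvs(a, np.inf, loc=mean_eps, scale=sd, size=(4, n), random_state=rng)
    cons_rows = rng.integers(0, 4, size=n)
    xi[cons_rows, np.arange(n)] = 0.0
    return xi
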
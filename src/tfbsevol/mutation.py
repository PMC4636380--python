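"""Point and short-indel mutation processes on regulatory sequences.

Two complementary views are provided: per-mismatch-class kernels over the
classes ``k = 0..n`` of a single binding site, and explicit edits of an
end-anchored sequence.  The sequence is anchored at its final (rightmost)
position, so indels shift material relative to that anchor and random bases
flow in from the distal (index-1) end — a deletion pulls upstream background
in, an insertion pushes the proximal part of the sequence out.

The analytic indel kernel treats the preserved (un-shifted) segment as
binomially mismatched at rate ``k/n``; the exact composition for a site with
exactly ``k`` mismatches is hypergeometric and is available via
``indel_kernel(..., exact=True)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.stats import binom, hypergeom

from .binding import encode_sequence, decode_sequence

__all__ = [
    "MutationModel",
    "MismatchKernel",
    "MutationEvent",
    "point_kernel",
    "indel_kernel",
    "combined_rate_matrix",
    "mutate_sequence",
    "apply_point_mutation",
    "apply_indel",
]

_DEFAULT_INDEL_LENGTHS = {1: 0.45, 2: 0.18}


@dataclass(frozen=True)
class MutationModel:
    """Mutation rates and indel length spectrum.

    ``u`` is the point mutation rate per bp per generation; ``theta`` the
    indel-to-point rate ratio (0 disables indels; 0.15 is the empirically
    motivated admixture).  ``indel_lengths`` maps indel length (bp) to its
    relative frequency among modelled lengths; frequencies are renormalized
    internally (the literature values 0.45 and 0.18 for 1- and 2-bp indels
    are frequencies among all indel sizes).  ``alpha`` is the background
    per-position mismatch probability (3/4 for uniform base usage).
    """

    u: float = 1e-5
    theta: float = 0.0
    indel_lengths: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_INDEL_LENGTHS)
    )
    alpha: float = 0.75

    def __post_init__(self):
        if self.u <= 0:
            raise ValueError("point mutation rate u must be > 0")
        if self.theta < 0:
            raise ValueError("indel ratio theta must be >= 0")
        if not self.indel_lengths or any(v <= 0 for v in self.indel_lengths.values()):
            raise ValueError("indel length frequencies must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("background mismatch probability alpha must be in (0, 1)")

    @property
    def normalized_indel_lengths(self) -> tuple[np.ndarray, np.ndarray]:
        lengths = np.array(sorted(self.indel_lengths), dtype=int)
        freqs = np.array([self.indel_lengths[d] for d in lengths], dtype=float)
        return lengths, freqs / freqs.sum()


@dataclass(frozen=True)
class MismatchKernel:
    """(n+1) x (n+1) matrix over mismatch classes; columns index the source
    class.  Probability flavors (``point``, ``indel``) are column-stochastic;
    the ``rate`` flavor is a generator in units of ``u`` (columns sum to 0).
    """

    matrix: np.ndarray
    flavor: str

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("kernel must be square")
        object.__setattr__(self, "matrix", m)
        if self.flavor not in ("point", "indel", "rate"):
            raise ValueError(f"unknown kernel flavor {self.flavor!r}")
        colsum = m.sum(axis=0)
        if self.flavor == "rate":
            off = m - np.diag(np.diag(m))
            if (off < -1e-12).any():
                raise ValueError("rate kernel off-diagonals must be nonnegative")
            if np.abs(colsum).max() > 1e-9:
                raise ValueError("rate kernel columns must sum to 0")
        else:
            if (m < -1e-15).any():
                raise ValueError("probability kernel entries must be nonnegative")
            if np.abs(colsum - 1.0).max() > 1e-9:
                raise ValueError("probability kernel columns must sum to 1")

    @property
    def n(self) -> int:
        return self.matrix.shape[0] - 1

    def to_tsv(self, path) -> None:
        """Write the kernel as TSV with a header row/column of k indices."""
        import pandas as pd

        ks = list(range(self.n + 1))
        pd.DataFrame(self.matrix, index=ks, columns=ks).to_csv(
            path, sep="\t", index_label="k_to\\k_from"
        )


@dataclass(frozen=True)
class MutationEvent:
    """Record of one sequence edit (positions 0-based)."""

    kind: str  # "point" | "insertion" | "deletion"
    position: int
    length: int = 1
    old_base: Optional[int] = None
    new_base: Optional[int] = None


def point_kernel(n: int) -> MismatchKernel:
    """Class-change probabilities for a single point mutation.

    From class k the site moves up to k+1 with probability ``1 - k/n`` (a
    matching position mutates), down to k-1 with ``k/(3n)`` (a mismatched
    position reverts to consensus) and stays at k with ``2k/(3n)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    P = np.zeros((n + 1, n + 1))
    for k in range(n + 1):
        if k < n:
            P[k + 1, k] = 1.0 - k / n
        if k > 0:
            P[k - 1, k] = k / (3.0 * n)
        P[k, k] = 2.0 * k / (3.0 * n)
    return MismatchKernel(P, "point")


def indel_kernel(n: int, model: Optional[MutationModel] = None, exact: bool = False) -> MismatchKernel:
    """Class-change probabilities for a single indel in a fixed window.

    An indel at (uniform) position ``i`` of the site preserves the mismatch
    state of ``i - 1`` positions and randomizes the remaining ``n - i + 1``
    (shifted or newly inserted material is background-random, mismatching
    with probability ``alpha``).  The preserved part contributes
    ``X ~ Binomial(i-1, k/n)`` mismatches — the analytic approximation —
    or exactly ``X ~ Hypergeometric(n, k, i-1)`` when ``exact=True``.
    The kernel does not depend on the indel length.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    alpha = model.alpha if model is not None else 0.75
    ks = np.arange(n + 1)
    P = np.zeros((n + 1, n + 1))
    for k in range(n + 1):
        for i in range(1, n + 1):
            if exact:
                px = hypergeom.pmf(ks, n, k, i - 1)
            else:
                px = binom.pmf(ks, i - 1, k / n)
            py = binom.pmf(ks, n - i + 1, alpha)
            P[:, k] += np.convolve(px, py)[: n + 1] / n
    # guard tiny negative round-off, renormalize columns
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=0, keepdims=True)
    return MismatchKernel(P, "indel")


def combined_rate_matrix(n: int, model: MutationModel) -> MismatchKernel:
    """Mutation rate generator over mismatch classes, in units of ``u``.

    Off-diagonal entries are ``n * (P_point + theta * P_indel)``; the
    diagonal closes each column.  Multiply by ``u`` for absolute rates.
    """
    P = point_kernel(n).matrix + model.theta * indel_kernel(n, model).matrix
    U = n * P
    np.fill_diagonal(U, 0.0)
    np.fill_diagonal(U, -U.sum(axis=0))
    return MismatchKernel(U, "rate")


def apply_point_mutation(arr: np.ndarray, rng: np.random.Generator) -> MutationEvent:
    """Substitute one uniformly chosen position by a random different base (in place)."""
    pos = int(rng.integers(arr.size))
    old = int(arr[pos])
    arr[pos] = (old + int(rng.integers(1, 4))) % 4
    return MutationEvent("point", pos, 1, old_base=old, new_base=int(arr[pos]))


def apply_indel(arr: np.ndarray, model: MutationModel, rng: np.random.Generator) -> MutationEvent:
    """Apply one indel to an end-anchored sequence (in place), keeping length L.

    Insertion: ``d`` random bases enter after a uniform position ``j``
    (1..L); the first ``d`` bases fall off the distal end.  Deletion: a
    ``d``-bp window ending at uniform position ``j`` (1..L) is removed
    (windows reaching past the distal end are truncated there) and random
    background pads the distal end.  Both event types randomize ``j``
    distal-ward positions, uniformly in ``j`` — the structure the analytic
    kernel assumes.
    """
    L = arr.size
    lengths, freqs = model.normalized_indel_lengths
    d = int(rng.choice(lengths, p=freqs))
    if d >= L:
        raise ValueError(f"indel length {d} must be < sequence length {L}")
    j = int(rng.integers(1, L + 1))
    if rng.random() < 0.5:
        new = rng.integers(0, 4, size=d).astype(arr.dtype)
        res = np.concatenate([arr[:j], new, arr[j:]])[-L:]
        arr[:] = res
        return MutationEvent("insertion", j, d)
    lo = max(0, j - d)
    pad = rng.integers(0, 4, size=j - lo).astype(arr.dtype)
    arr[:] = np.concatenate([pad, arr[:lo], arr[j:]])
    return MutationEvent("deletion", j, d)


def mutate_sequence(
    seq: str | np.ndarray,
    model: MutationModel,
    rng: np.random.Generator,
    force: Optional[str] = None,
):
    """Apply one mutation event and return ``(new_seq, event)``.

    The event type is point with probability ``1/(1+theta)`` and indel with
    ``theta/(1+theta)``; ``force`` ("point" or "indel") overrides the draw.
    Strings in, strings out; arrays are edited on a copy.
    """
    is_str = isinstance(seq, str)
    arr = encode_sequence(seq) if is_str else np.array(seq, copy=True)
    kind = force
    if kind is None:
        kind = "indel" if rng.random() < model.theta / (1.0 + model.theta) else "point"
    if kind == "point":
        event = apply_point_mutation(arr, rng)
    elif kind == "indel":
        event = apply_indel(arr, model, rng)
    else:
        raise ValueError(f"unknown mutation kind {kind!r}")
    return (decode_sequence(arr) if is_str else arr), event
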
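"""First-order Markov model of gaze transitions between AOIs.

Adjacent fixation pairs of an AOI sequence are tallied into an s x s
count matrix ``n``, with ``n[i][j]`` the number of observed transitions
from AOI i to AOI j (self-transitions included: consecutive fixations
inside one AOI are real state occurrences, which is why observed count
matrices are strongly diagonal-dominant).  Row-normalising gives the
transition matrix P; the visit distribution pi comes either from the
empirical source-state frequencies (row sums over the total) or from
the stationary fixed point pi P = pi.

Both pi estimates are offered because with finite data they differ: the
empirical frequencies are what the data shows, the stationary solution
is what the fitted chain predicts in the long run.  The chosen mode is
recorded in the result so reports stay auditable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .aoi import AOISequence

__all__ = [
    "TransitionCounts",
    "TransitionMatrix",
    "StateDistribution",
    "ChainDiagnostics",
    "ReducibleChainError",
    "count_transitions",
    "pool_counts",
    "normalize_rows",
    "transition_matrix_from_probabilities",
    "empirical_distribution",
    "stationary_distribution",
    "chain_diagnostics",
]


class ReducibleChainError(ValueError):
    """Raised when a unique stationary distribution does not exist.

    Carries the communicating classes so the caller can inspect the
    structure; the empirical distribution remains available.
    """

    def __init__(self, classes: tuple[tuple[int, ...], ...]):
        self.classes = classes
        super().__init__(
            f"chain is reducible ({len(classes)} communicating classes: {classes}); "
            "the stationary distribution is not unique — use empirical_distribution instead"
        )


def _default_labels(s: int) -> tuple[str, ...]:
    return tuple(f"AOI{i}" for i in range(1, s + 1))


@dataclass(frozen=True)
class TransitionCounts:
    """Raw AOI-to-AOI transition tallies, poolable across trials."""

    labels: tuple[str, ...]
    n: np.ndarray
    n_sequences: int = 1

    def __post_init__(self) -> None:
        n = np.asarray(self.n)
        if n.ndim != 2 or n.shape[0] != n.shape[1]:
            raise ValueError(f"count matrix must be square, got shape {n.shape}")
        if n.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix size")
        if np.any(n < 0) or not np.allclose(n, np.round(n)):
            raise ValueError("transition counts must be nonnegative integers")
        object.__setattr__(self, "n", n.astype(np.int64))
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def s(self) -> int:
        return self.n.shape[0]

    @property
    def total(self) -> int:
        return int(self.n.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.n.sum(axis=1)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition matrix P with zero-row bookkeeping.

    ``zero_rows`` lists 1-based indices of states retained with an
    all-zero row (only under the ``keep_zero`` policy).
    """

    labels: tuple[str, ...]
    P: np.ndarray
    zero_rows: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError(f"transition matrix must be square, got shape {P.shape}")
        if P.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix size")
        if np.any(P < 0) or np.any(P > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        rs = P.sum(axis=1)
        for i, r in enumerate(rs, start=1):
            if i not in self.zero_rows and abs(r - 1.0) > 1e-9:
                raise ValueError(f"row {i} sums to {r}, not 1")
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "zero_rows", frozenset(self.zero_rows))

    @property
    def s(self) -> int:
        return self.P.shape[0]


@dataclass(frozen=True)
class StateDistribution:
    """Probability of being in each AOI; empirical or stationary."""

    labels: tuple[str, ...]
    pi: np.ndarray
    source: str = "empirical"

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.ndim != 1 or pi.shape[0] != len(self.labels):
            raise ValueError("pi must be a vector matching the labels")
        if np.any(pi < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError(f"pi sums to {pi.sum()}, not 1")
        if self.source not in ("empirical", "stationary", "given"):
            raise ValueError(f"unknown source {self.source!r}")
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "labels", tuple(self.labels))


@dataclass(frozen=True)
class ChainDiagnostics:
    irreducible: bool
    aperiodic: bool
    classes: tuple[tuple[int, ...], ...]
    periods: tuple[int, ...]


StatesLike = Union[AOISequence, Sequence[int]]


def _states_of(seq: StatesLike) -> Sequence[int]:
    return seq.states if isinstance(seq, AOISequence) else seq


def count_transitions(
    seq: StatesLike,
    s: int,
    labels: Sequence[str] | None = None,
) -> TransitionCounts:
    """Tally adjacent state pairs of one AOI sequence into an s x s matrix.

    The total count equals ``max(len(states) - 1, 0)``; sequences of
    length <= 1 yield an all-zero matrix.
    """
    states = _states_of(seq)
    if labels is None:
        labels = _default_labels(s)
    n = np.zeros((s, s), dtype=np.int64)
    for a, b in zip(states, states[1:]):
        if not (1 <= a <= s and 1 <= b <= s):
            raise ValueError(f"state out of range 1..{s}: transition ({a}, {b})")
    if states and not 1 <= states[-1] <= s:
        raise ValueError(f"state out of range 1..{s}: {states[-1]}")
    for a, b in zip(states, states[1:]):
        n[a - 1, b - 1] += 1
    return TransitionCounts(labels=tuple(labels), n=n, n_sequences=1)


def pool_counts(parts: Iterable[TransitionCounts]) -> TransitionCounts:
    """Accumulate transition counts across trials into a single matrix.

    All parts must carry identical labels; totals add entrywise, so the
    pooled matrix is the one a single concatenated tally would give.
    """
    parts = list(parts)
    if not parts:
        raise ValueError("nothing to pool")
    labels = parts[0].labels
    for p in parts[1:]:
        if p.labels != labels:
            raise ValueError(f"label mismatch: {p.labels} != {labels}")
    n = np.zeros_like(parts[0].n)
    for p in parts:
        n = n + p.n
    return TransitionCounts(labels=labels, n=n, n_sequences=sum(p.n_sequences for p in parts))


def normalize_rows(
    counts: TransitionCounts,
    zero_row_policy: str = "drop_state",
) -> TransitionMatrix:
    """Row-normalise counts to a transition matrix, p_ij = n_ij / sum_j n_ij.

    A state never seen as a transition source has an all-zero row;
    ``zero_row_policy`` decides its fate: ``drop_state`` removes the
    state (labels shrink, warning emitted), ``uniform`` fills the row
    with 1/s, ``keep_zero`` keeps the zero row and records its index.
    """
    if zero_row_policy not in ("drop_state", "uniform", "keep_zero"):
        raise ValueError(f"unknown zero-row policy {zero_row_policy!r}")
    n = counts.n.astype(float)
    row_sums = n.sum(axis=1)
    if counts.total == 0:
        raise ValueError("no transitions observed")
    zero = np.flatnonzero(row_sums == 0)
    if zero.size and zero_row_policy == "drop_state":
        dropped = [counts.labels[i] for i in zero]
        warnings.warn(
            f"dropping states with no outgoing transitions: {dropped}", stacklevel=2
        )
        keep = np.flatnonzero(row_sums > 0)
        n = n[np.ix_(keep, keep)]
        row_sums = n.sum(axis=1)
        if np.any(row_sums == 0):
            # dropping a state can orphan another; recurse until stable
            sub = TransitionCounts(
                labels=tuple(counts.labels[i] for i in keep),
                n=n.astype(np.int64),
                n_sequences=counts.n_sequences,
            )
            return normalize_rows(sub, zero_row_policy="drop_state")
        labels = tuple(counts.labels[i] for i in keep)
        return TransitionMatrix(labels=labels, P=n / row_sums[:, None])
    P = np.zeros_like(n)
    nz = row_sums > 0
    P[nz] = n[nz] / row_sums[nz, None]
    zero_rows: frozenset[int] = frozenset()
    if zero.size:
        if zero_row_policy == "uniform":
            P[~nz] = 1.0 / counts.s
        else:
            zero_rows = frozenset(int(i) + 1 for i in zero)
    return TransitionMatrix(labels=counts.labels, P=P, zero_rows=zero_rows)


def transition_matrix_from_probabilities(
    P: np.ndarray,
    labels: Sequence[str] | None = None,
    row_sum_tol: float = 0.01,
) -> TransitionMatrix:
    """Build a TransitionMatrix from already-normalised (possibly rounded) rows.

    Rows of matrices transcribed from rounded published tables rarely sum
    to exactly 1; rows whose sum lies within ``row_sum_tol`` of 1 are
    renormalised (logged via warning), anything further off is an error.
    """
    P = np.asarray(P, dtype=float)
    if labels is None:
        labels = _default_labels(P.shape[0])
    rs = P.sum(axis=1)
    bad = np.flatnonzero(np.abs(rs - 1.0) > row_sum_tol)
    if bad.size:
        raise ValueError(
            f"rows {list(bad + 1)} sum to {rs[bad]}, outside 1 +/- {row_sum_tol}"
        )
    adjusted = np.flatnonzero(np.abs(rs - 1.0) > 1e-9)
    if adjusted.size:
        warnings.warn(
            f"renormalising rows with rounded sums: {[int(i) + 1 for i in adjusted]} "
            f"(sums {np.round(rs[adjusted], 4)})",
            stacklevel=2,
        )
    return TransitionMatrix(labels=tuple(labels), P=P / rs[:, None])


def empirical_distribution(counts: TransitionCounts) -> StateDistribution:
    """Visit frequencies of each AOI as a transition source: row sums / total.

    The final fixation of each trajectory has no outgoing transition and
    is therefore not counted — an off-by-one relative to raw fixation
    tallies that vanishes as trajectories grow.
    """
    total = counts.total
    if total == 0:
        raise ValueError("no transitions observed; empirical distribution undefined")
    return StateDistribution(
        labels=counts.labels, pi=counts.row_sums / total, source="empirical"
    )


def stationary_distribution(P: TransitionMatrix, tol: float = 1e-10) -> StateDistribution:
    """Solve pi P = pi, sum(pi) = 1 for the unique stationary distribution.

    Solved as a least-squares problem on the stacked system
    ``[P^T - I; 1^T] pi = [0; 1]`` — deterministic, no iteration.
    Uniqueness requires a single communicating class; reducible chains
    raise :class:`ReducibleChainError` carrying the classes.
    """
    if P.zero_rows:
        raise ValueError(f"zero rows {sorted(P.zero_rows)} — not a stochastic matrix")
    diag = chain_diagnostics(P)
    if not diag.irreducible:
        raise ReducibleChainError(diag.classes)
    s = P.s
    A = np.vstack([P.P.T - np.eye(s), np.ones((1, s))])
    b = np.zeros(s + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    resid = np.max(np.abs(pi @ P.P - pi))
    if resid > tol:
        raise RuntimeError(f"stationary solve residual {resid} exceeds tol {tol}")
    return StateDistribution(labels=P.labels, pi=pi, source="stationary")


def _class_period(P: np.ndarray, members: np.ndarray) -> int:
    """Period of one communicating class: gcd of (d_u + 1 - d_v) over its edges."""
    inside = np.zeros(P.shape[0], dtype=bool)
    inside[members] = True
    root = int(members[0])
    dist = {root: 0}
    frontier = [root]
    while frontier:
        nxt = []
        for u in frontier:
            for v in np.flatnonzero(P[u] > 0):
                v = int(v)
                if inside[v] and v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    g = 0
    for u in members:
        u = int(u)
        for v in np.flatnonzero(P[u] > 0):
            v = int(v)
            if inside[v]:
                g = math.gcd(g, dist[u] + 1 - dist[v])
    return abs(g)


def chain_diagnostics(P: TransitionMatrix) -> ChainDiagnostics:
    """Communicating classes and periods of the positive-support digraph.

    ``irreducible`` means a single strongly connected class; ``aperiodic``
    means every class containing an edge has period 1 (a period of 0
    marks a transient singleton with no internal edge).
    """
    support = csr_matrix((P.P > 0).astype(np.int8))
    n_comp, assignment = connected_components(support, directed=True, connection="strong")
    classes = tuple(
        tuple(int(i) + 1 for i in np.flatnonzero(assignment == c)) for c in range(n_comp)
    )
    periods = []
    for c in range(n_comp):
        members = np.flatnonzero(assignment == c)
        periods.append(_class_period(P.P, members))
    aperiodic = all(p == 1 for p in periods if p > 0) and any(p > 0 for p in periods)
    return ChainDiagnostics(
        irreducible=(n_comp == 1),
        aperiodic=aperiodic,
        classes=classes,
        periods=tuple(periods),
    )
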
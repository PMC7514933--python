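"""The gaze information channel and its entropy / mutual-information metrics.

An irreducible, aperiodic Markov chain over AOIs is a discrete memoryless
channel X -> Y in which input and output are the current and next AOI:
both marginals equal the visit distribution pi, and the channel matrix is
the transition matrix P, p(j|i) = p_ij.  The metrics evaluated here:

* ``Hs = H(pi)`` — stationary (gaze) entropy: high when attention is
  spread evenly over the AOIs, low when a few AOIs dominate.
* ``H(Y|i)`` — row conditional entropy: uncertainty about the next AOI
  given the gaze is currently in AOI i.
* ``Ht = sum_i pi_i H(Y|i)`` — transition entropy: average next-AOI
  unpredictability.
* ``H(X,Y) = Hs + Ht`` — joint entropy of a transition, the channel's
  total uncertainty.
* ``I(i;Y) = sum_j p_ij log(p_ij / pi_j)`` — row mutual information: how
  sharply leaving AOI i pins down the destination relative to the
  overall visit frequencies.
* ``I(X;Y) = sum_i pi_i I(i;Y)`` — mutual information between current
  and next AOI; high values mean a structured, predictable scanning
  strategy.
* normalised MI ``rho = MI/Hs`` (or ``MI/H(X,Y)``) — a base-invariant
  correlation-like coefficient for comparing channels with different Hs.

Terms with p = 0 contribute zero throughout (the 0 log 0 = 0 convention).
The logarithm base is an explicit parameter everywhere and is stamped
into every result; ``"e"`` (nats) is the default.  When pi is exactly
stationary, MI = Hs - Ht holds identically; with an empirical pi the two
sides can differ, and both are reported rather than forced equal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np
from scipy.special import rel_entr, xlogy

from .markov import StateDistribution, TransitionMatrix

__all__ = [
    "GazeChannel",
    "ChannelMetrics",
    "entropy",
    "generic_measures",
    "row_conditional_entropy",
    "row_mutual_information",
    "channel_metrics",
    "normalized_mi",
]

LogBase = Union[str, int, float]


def _ln_base(base: LogBase) -> float:
    """Natural log of the base; divide nat-valued sums by this."""
    if base in ("e", math.e):
        return 1.0
    b = float(base)
    if b <= 1.0:
        raise ValueError(f"log base must be > 1, got {base!r}")
    return math.log(b)


def _as_prob_vector(dist, tol: float = 1e-6) -> np.ndarray:
    p = np.asarray(dist.pi if isinstance(dist, StateDistribution) else dist, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > tol:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1 +/- {tol}")
    return p


def _as_matrix(P) -> np.ndarray:
    return np.asarray(P.P if isinstance(P, TransitionMatrix) else P, dtype=float)


def entropy(dist, base: LogBase = "e") -> float:
    """Shannon entropy -sum p log p, with 0 log 0 = 0.

    ``dist`` is a probability vector or :class:`StateDistribution`;
    ``base`` selects the unit (2 -> bits, "e" -> nats, 10 -> hartleys).
    """
    p = _as_prob_vector(dist)
    return float(-xlogy(p, p).sum() / _ln_base(base))


def row_conditional_entropy(P, i: int, base: LogBase = "e") -> float:
    """Entropy H(Y|i) of row i (1-based) of the transition matrix."""
    M = _as_matrix(P)
    row = M[i - 1]
    return float(-xlogy(row, row).sum() / _ln_base(base))


def row_mutual_information(P, pi, i: int, base: LogBase = "e") -> float:
    """Row mutual information I(i;Y) = sum_j p_ij log(p_ij / pi_j).

    Undefined (raises) when row i puts mass on a destination j with
    pi_j = 0.
    """
    M = _as_matrix(P)
    p = _as_prob_vector(pi)
    row = M[i - 1]
    if np.any((row > 0) & (p == 0)):
        j = int(np.flatnonzero((row > 0) & (p == 0))[0]) + 1
        raise ValueError(
            f"I({i};Y) undefined: p[{i}][{j}] > 0 but pi[{j}] = 0"
        )
    return float(rel_entr(row, p).sum() / _ln_base(base))


@dataclass(frozen=True)
class GazeChannel:
    """A fitted gaze channel: transition matrix P, visit distribution pi, log base."""

    P: TransitionMatrix
    pi: StateDistribution
    log_base: LogBase = "e"

    def __post_init__(self) -> None:
        if self.P.labels != self.pi.labels:
            raise ValueError(
                f"channel labels disagree: {self.P.labels} vs {self.pi.labels}"
            )
        _ln_base(self.log_base)  # validate

    @property
    def labels(self) -> tuple[str, ...]:
        return self.P.labels

    @property
    def s(self) -> int:
        return self.P.s


@dataclass(frozen=True)
class ChannelMetrics:
    """All channel metrics of one trial, with the conventions stamped in."""

    labels: tuple[str, ...]
    log_base: LogBase
    pi: np.ndarray
    pi_source: str
    Hs: float
    Ht: float
    Hxy: float
    MI: float
    row_H: np.ndarray
    row_I: np.ndarray
    rho_Hs: float
    rho_Hxy: float

    def to_record(self) -> dict:
        """Flat JSON-serialisable dict (one report row)."""
        return {
            "labels": list(self.labels),
            "base": self.log_base if isinstance(self.log_base, str) else float(self.log_base),
            "pi": [float(v) for v in self.pi],
            "pi_source": self.pi_source,
            "Hs": self.Hs,
            "Ht": self.Ht,
            "Hxy": self.Hxy,
            "MI": self.MI,
            "row_H": [float(v) for v in self.row_H],
            "row_I": [float(v) for v in self.row_I],
            "rho_Hs": self.rho_Hs,
            "rho_Hxy": self.rho_Hxy,
        }


def channel_metrics(channel: GazeChannel) -> ChannelMetrics:
    """Evaluate every channel metric of a fitted gaze channel.

    ``Hxy`` is computed as ``Hs + Ht`` (the chain rule, exact by
    construction) and ``MI`` as the pi-weighted sum of the per-row
    mutual informations; with a stationary pi this MI also equals
    Hs - Ht.
    """
    P = _as_matrix(channel.P)
    pi = _as_prob_vector(channel.pi)
    ln_b = _ln_base(channel.log_base)
    if np.any((P > 0) & (pi[None, :] == 0) & (pi[:, None] > 0)):
        raise ValueError("transition mass on a destination AOI with pi = 0")
    Hs = float(-xlogy(pi, pi).sum() / ln_b)
    row_H = -xlogy(P, P).sum(axis=1) / ln_b
    Ht = float(pi @ row_H)
    # rows with pi_i = 0 never occur; their (possibly undefined) row_I must
    # not poison the weighted sum
    row_I = np.zeros(P.shape[0])
    for i in np.flatnonzero(pi > 0):
        row_I[i] = rel_entr(P[i], pi).sum() / ln_b
    MI = float(pi @ row_I)
    Hxy = Hs + Ht
    rho_Hs = MI / Hs if Hs > 0 else math.nan
    rho_Hxy = MI / Hxy if Hxy > 0 else math.nan
    return ChannelMetrics(
        labels=channel.labels,
        log_base=channel.log_base,
        pi=pi,
        pi_source=channel.pi.source,
        Hs=Hs,
        Ht=Ht,
        Hxy=Hxy,
        MI=MI,
        row_H=row_H,
        row_I=row_I,
        rho_Hs=rho_Hs,
        rho_Hxy=rho_Hxy,
    )


def generic_measures(joint: np.ndarray, base: LogBase = "e") -> Mapping[str, float]:
    """Entropies and MI of an arbitrary discrete joint distribution.

    Works directly from the joint matrix p(x, y): marginals by row/column
    sums, H(X), H(Y), H(X,Y), H(Y|X) = H(X,Y) - H(X), and
    MI = H(X) + H(Y) - H(X,Y).  Serves as the independent brute-force
    route against which the channel-form metrics are checked.
    """
    J = np.asarray(joint, dtype=float)
    if np.any(J < 0):
        raise ValueError("joint probabilities must be nonnegative")
    if abs(J.sum() - 1.0) > 1e-6:
        raise ValueError(f"joint distribution sums to {J.sum()}, not 1")
    ln_b = _ln_base(base)
    px = J.sum(axis=1)
    py = J.sum(axis=0)
    H_X = float(-xlogy(px, px).sum() / ln_b)
    H_Y = float(-xlogy(py, py).sum() / ln_b)
    H_XY = float(-xlogy(J, J).sum() / ln_b)
    return {
        "H_X": H_X,
        "H_Y": H_Y,
        "H_XY": H_XY,
        "H_Y_given_X": H_XY - H_X,
        "MI": H_X + H_Y - H_XY,
    }


def normalized_mi(metrics: ChannelMetrics, mode: str = "by_Hs") -> float:
    """Normalised mutual information: MI/Hs or MI/H(X,Y).

    Base-invariant, and in [0, 1] for a stationary pi.  A degenerate
    channel (single visited AOI, Hs = 0) has no defined ratio.
    """
    if mode == "by_Hs":
        denom = metrics.Hs
    elif mode == "by_Hxy":
        denom = metrics.Hxy
    else:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    if not denom > 0:
        raise ValueError("degenerate channel: normalising entropy is 0")
    return metrics.MI / denom
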
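"""Scikit-learn-style estimator front end for the gaze channel.

``GazeChannelAnalyzer`` fits a gaze information channel to AOI
sequences (or directly to a count / probability matrix) and exposes the
fitted transition matrix, visit distribution and channel metrics as
trailing-underscore attributes.  It follows the sklearn estimator
protocol (``get_params`` / ``set_params``, ``fit`` returning ``self``)
so it clones and composes with sklearn model-selection utilities;
``transform`` maps a collection of sequences to a per-trial metrics
table.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from sklearn.base import BaseEstimator

from .aoi import AOISequence
from .channel import GazeChannel, ChannelMetrics, channel_metrics, normalized_mi
from .markov import (
    StateDistribution,
    TransitionCounts,
    count_transitions,
    empirical_distribution,
    normalize_rows,
    pool_counts,
    stationary_distribution,
    transition_matrix_from_probabilities,
)

__all__ = ["GazeChannelAnalyzer"]

SequenceLike = Union[AOISequence, Sequence[int]]


class GazeChannelAnalyzer(BaseEstimator):
    """Fit a gaze information channel to AOI sequences and score its metrics.

    Parameters
    ----------
    log_base : {"e", 2, 10} or float, default "e"
        Unit of every entropy/MI value ("e" gives nats).
    pi_mode : {"empirical", "stationary"}, default "empirical"
        Visit-distribution estimate: empirical source frequencies when
        counts are available, or the stationary fixed point of the
        fitted transition matrix.  Matrix-only fits without counts force
        "stationary" unless an explicit pi is supplied.
    zero_row_policy : {"drop_state", "uniform", "keep_zero"}, default "drop_state"
        Handling of AOIs never seen as a transition source.

    Attributes
    ----------
    n_states_ : int
        Number of retained AOI states.
    labels_ : tuple of str
    counts_ : TransitionCounts or None
        Pooled transition counts (None for probability-matrix fits).
    transition_matrix_ : TransitionMatrix
    pi_ : StateDistribution
    channel_ : GazeChannel
    metrics_ : ChannelMetrics
        Hs, Ht, H(X,Y), MI, per-row H(Y|i) and I(i;Y), normalised MI.

    Examples
    --------
    >>> ana = GazeChannelAnalyzer().fit([[1, 1, 2, 2, 1, 3, 3]])
    >>> round(ana.metrics_.Hs, 3)
    1.011
    """

    def __init__(
        self,
        log_base="e",
        pi_mode: str = "empirical",
        zero_row_policy: str = "drop_state",
    ):
        self.log_base = log_base
        self.pi_mode = pi_mode
        self.zero_row_policy = zero_row_policy

    # ------------------------------------------------------------------ fit
    def fit(self, X, y=None, n_states: Optional[int] = None, labels=None):
        """Fit the channel to one or more AOI sequences.

        Parameters
        ----------
        X : iterable of AOISequence or of 1-based integer sequences,
            or a single TransitionCounts
            Trials pooled into one count matrix before normalisation.
        n_states : int, optional
            State-space size s; inferred as the largest state seen when
            omitted.
        labels : sequence of str, optional
        """
        if self.pi_mode not in ("empirical", "stationary"):
            raise ValueError(f"unknown pi_mode {self.pi_mode!r}")
        if isinstance(X, TransitionCounts):
            counts = X
        else:
            seqs = [x if isinstance(x, AOISequence) else AOISequence("", "", tuple(x)) for x in X]
            if not seqs:
                raise ValueError("no sequences to fit")
            s = n_states or max((max(q.states) for q in seqs if q.states), default=0)
            if s == 0:
                raise ValueError("all sequences are empty")
            counts = pool_counts([count_transitions(q, s, labels=labels) for q in seqs])
        return self._finish_fit(counts=counts)

    def fit_from_matrix(
        self,
        M: np.ndarray,
        labels=None,
        matrix_kind: str = "probs",
        pi: Optional[np.ndarray] = None,
    ):
        """Fit from a pre-built matrix (transition counts or probabilities).

        With ``matrix_kind="probs"`` and no explicit ``pi`` the visit
        distribution must be stationary (there are no counts to take
        frequencies from); rounded rows summing within 1% of 1 are
        renormalised.
        """
        if matrix_kind == "counts":
            counts = TransitionCounts(
                labels=tuple(labels) if labels is not None else tuple(f"AOI{i+1}" for i in range(np.asarray(M).shape[0])),
                n=np.asarray(M),
            )
            return self._finish_fit(counts=counts, pi_given=pi)
        if matrix_kind != "probs":
            raise ValueError(f"unknown matrix_kind {matrix_kind!r}")
        tm = transition_matrix_from_probabilities(np.asarray(M), labels=labels)
        return self._finish_fit(counts=None, tm=tm, pi_given=pi)

    def _finish_fit(self, counts, tm=None, pi_given=None):
        if counts is not None:
            tm = normalize_rows(counts, zero_row_policy=self.zero_row_policy)
            if tm.labels != counts.labels:  # states were dropped
                keep = [counts.labels.index(l) for l in tm.labels]
                counts = TransitionCounts(
                    labels=tm.labels,
                    n=counts.n[np.ix_(keep, keep)],
                    n_sequences=counts.n_sequences,
                )
        if pi_given is not None:
            pi_arr = np.asarray(pi_given, dtype=float)
            pi = StateDistribution(labels=tm.labels, pi=pi_arr / pi_arr.sum(), source="given")
        elif self.pi_mode == "empirical" and counts is not None:
            pi = empirical_distribution(counts)
        else:
            pi = stationary_distribution(tm)
        self.counts_ = counts
        self.transition_matrix_ = tm
        self.pi_ = pi
        self.labels_ = tm.labels
        self.n_states_ = tm.s
        self.channel_ = GazeChannel(P=tm, pi=pi, log_base=self.log_base)
        self.metrics_ = channel_metrics(self.channel_)
        return self

    # ------------------------------------------------------------ transform
    def transform(self, X: Iterable[SequenceLike]) -> pd.DataFrame:
        """Per-trial metrics table: fit a fresh channel to each sequence.

        Each row carries Hs, Ht, H(X,Y), MI and the normalised-MI
        variants of one trial, computed with this estimator's settings.
        """
        self._check_fitted()
        rows = []
        for q in X:
            seq = q if isinstance(q, AOISequence) else AOISequence("", "", tuple(q))
            sub = GazeChannelAnalyzer(
                log_base=self.log_base,
                pi_mode=self.pi_mode,
                zero_row_policy=self.zero_row_policy,
            ).fit([seq], n_states=max(seq.states) if seq.states else None)
            m = sub.metrics_
            rows.append(
                {
                    "participant_id": seq.participant_id,
                    "stimulus_id": seq.stimulus_id,
                    "Hs": m.Hs,
                    "Ht": m.Ht,
                    "Hxy": m.Hxy,
                    "MI": m.MI,
                    "rho_Hs": m.rho_Hs,
                    "rho_Hxy": m.rho_Hxy,
                }
            )
        return pd.DataFrame(rows)

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, **fit_params).transform(X)

    # ----------------------------------------------------------- reporting
    def report_record(self, participant: str = "", stimulus: str = "") -> dict:
        """One flat report row for the fitted channel (JSON-serialisable)."""
        self._check_fitted()
        rec = {"participant": participant, "stimulus": stimulus}
        rec.update(self.metrics_.to_record())
        if self.counts_ is not None:
            rec["counts"] = self.counts_.n.tolist()
        return rec

    def _check_fitted(self) -> None:
        if not hasattr(self, "metrics_"):
            raise RuntimeError("this GazeChannelAnalyzer instance is not fitted yet")
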
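"""Bundled example data from a poster-reading eye-tracking experiment.

Seven scientific posters were each read for 60 s by ten observers on a
1920x1080 display, with AOIs following the posters' content sections.
Bundled here, transcribed from the study's published summary tables:

* per-observer transition probabilities and visit distributions for the
  six-AOI poster ("poster7") for observers 2 and 5 — the worked example
  contrasting a focused reader (observer 2, who dwells on the results
  section) with a balanced reader (observer 5);
* all-observer pooled transition counts for the three-AOI posters 1-3
  and the four-AOI posters 4-6.

The transcribed probability rows carry three-decimal rounding; loaders
renormalise them (see ``transition_matrix_from_probabilities``).  The
printed visit distributions are empirical frequencies, not stationary
solutions, so the two pi modes give slightly different vectors on this
data — a deliberate property of the example, kept visible.
"""

from __future__ import annotations

from importlib import resources
import warnings

import numpy as np

from .io import read_matrix_csv, read_vector_csv
from .markov import StateDistribution, TransitionCounts, TransitionMatrix, transition_matrix_from_probabilities

__all__ = [
    "load_observer_channel",
    "load_pooled_counts",
    "POOLED_POSTERS",
    "EXAMPLE_OBSERVERS",
]

POOLED_POSTERS = ("poster1", "poster2", "poster3", "poster4", "poster5", "poster6")
EXAMPLE_OBSERVERS = (2, 5)


def _data_path(name: str):
    return resources.files("gazechannel.data") / name


def load_observer_channel(observer: int) -> tuple[TransitionMatrix, StateDistribution]:
    """Transition matrix and printed visit distribution for one example observer.

    ``observer`` is 2 or 5 (the six-AOI poster worked example).  Rounded
    rows are renormalised; the returned distribution has
    ``source="given"`` because it was published as-is.
    """
    if observer not in EXAMPLE_OBSERVERS:
        raise ValueError(f"bundled example observers are {EXAMPLE_OBSERVERS}, got {observer}")
    labels, P = read_matrix_csv(_data_path(f"poster7_observer{observer}_P.csv"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rounded rows are expected here
        tm = transition_matrix_from_probabilities(P, labels=labels)
    vlabels, pi = read_vector_csv(_data_path(f"poster7_observer{observer}_pi.csv"))
    assert vlabels == labels
    pi = pi / pi.sum()
    return tm, StateDistribution(labels=labels, pi=pi, source="given")


def load_pooled_counts(poster: str) -> TransitionCounts:
    """All-observer pooled transition counts for posters 1-6.

    Posters 1-3 have three AOIs, posters 4-6 four; ``n_sequences`` is
    the ten observers pooled.
    """
    if poster not in POOLED_POSTERS:
        raise ValueError(f"bundled pooled posters are {POOLED_POSTERS}, got {poster!r}")
    labels, M = read_matrix_csv(_data_path(f"{poster}_pooled_counts.csv"))
    return TransitionCounts(labels=labels, n=M.astype(np.int64), n_sequences=10)
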
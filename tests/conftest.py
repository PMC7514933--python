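import numpy as np
import pytest

from gazechannel.aoi import AOIRegion, AOISet, FixationRecord


@pytest.fixture
def three_aois() -> AOISet:
    """Three disjoint side-by-side rectangles on a 1920x1080 screen."""
    return AOISet(
        stimulus_id="poster_x",
        regions=(
            AOIRegion(1, "title", 0, 0, 640, 1080),
            AOIRegion(2, "body", 640, 0, 1280, 1080),
            AOIRegion(3, "results", 1280, 0, 1920, 1080),
        ),
    )


@pytest.fixture
def fixation_factory():
    """Build a trial's fixation list from (x, y) points, 100 ms apart."""

    def make(points, participant="p1", stimulus="poster_x", duration=100.0):
        return [
            FixationRecord(participant, stimulus, start=200.0 * i, duration=duration, x=x, y=y)
            for i, (x, y) in enumerate(points)
        ]

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_channel(rng, s):
    """A random strictly-positive row-stochastic matrix (irreducible, aperiodic)."""
    P = rng.dirichlet(np.full(s, 0.7), size=s) + 0.01
    return P / P.sum(axis=1, keepdims=True)
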
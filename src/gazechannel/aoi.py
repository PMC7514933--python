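"""Areas of Interest and fixation-to-AOI mapping.

A stimulus (here, a scientific poster shown on a 1920x1080 screen) is
divided into rectangular Areas of Interest (AOIs) following its content
sections.  Each fixation is assigned to the AOI containing its screen
position, turning a scanpath into an ordered sequence of AOI indices —
the discrete state trajectory everything downstream is built on.

Coordinates are pixels with the origin at the top-left corner and y
increasing downward, matching eye-tracker exports.  Boxes are half-open,
``[x_min, x_max) x [y_min, y_max)``, so a point on a shared edge belongs
to exactly one region.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "FixationRecord",
    "AOIRegion",
    "AOISet",
    "AOISequence",
    "assign_fixation",
    "fixations_to_sequence",
    "dwell_summary",
]


@dataclass(frozen=True)
class FixationRecord:
    """One fixation event: onset, duration and screen position.

    Times are milliseconds; no epoch is assumed.  ``x``/``y`` are screen
    pixels, origin top-left.
    """

    participant_id: str
    stimulus_id: str
    start: float
    duration: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError(f"fixation duration must be > 0, got {self.duration}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"fixation position must be finite, got ({self.x}, {self.y})")


@dataclass(frozen=True)
class AOIRegion:
    """Axis-aligned rectangular AOI in pixel coordinates."""

    aoi_id: int
    label: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not self.x_min < self.x_max:
            raise ValueError(f"AOI {self.aoi_id}: x_min ({self.x_min}) must be < x_max ({self.x_max})")
        if not self.y_min < self.y_max:
            raise ValueError(f"AOI {self.aoi_id}: y_min ({self.y_min}) must be < y_max ({self.y_max})")

    def contains(self, x: float, y: float) -> bool:
        """Half-open containment test: [x_min, x_max) x [y_min, y_max)."""
        return self.x_min <= x < self.x_max and self.y_min <= y < self.y_max


@dataclass(frozen=True)
class AOISet:
    """The ordered AOI regions of one stimulus.

    Region ids must be the consecutive integers 1..s; region order is
    the declaration order and decides priority if regions overlap.
    """

    stimulus_id: str
    regions: tuple[AOIRegion, ...]

    def __post_init__(self) -> None:
        if isinstance(self.regions, list):
            object.__setattr__(self, "regions", tuple(self.regions))
        if len(self.regions) < 1:
            raise ValueError("an AOISet needs at least one region")
        ids = [r.aoi_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate AOI ids in stimulus {self.stimulus_id!r}: {ids}")
        if sorted(ids) != list(range(1, len(ids) + 1)):
            raise ValueError(
                f"non-consecutive ids: AOI ids for stimulus {self.stimulus_id!r} "
                f"must be 1..{len(ids)}, got {sorted(ids)}"
            )

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def labels(self) -> tuple[str, ...]:
        """Labels in aoi_id order (1..s)."""
        by_id = {r.aoi_id: r.label for r in self.regions}
        return tuple(by_id[i] for i in range(1, len(self.regions) + 1))


@dataclass(frozen=True)
class AOISequence:
    """Ordered AOI indices visited in one trial (one participant, one stimulus).

    ``states`` hold 1-based AOI indices; with the ``drop`` policy,
    ``len(states) + n_dropped == n_fixations_total``.
    """

    participant_id: str
    stimulus_id: str
    states: tuple[int, ...]
    n_fixations_total: int = field(default=-1)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.states, list):
            object.__setattr__(self, "states", tuple(self.states))
        if self.n_fixations_total == -1:
            object.__setattr__(self, "n_fixations_total", len(self.states) + self.n_dropped)
        if len(self.states) + self.n_dropped != self.n_fixations_total:
            raise ValueError(
                f"inconsistent bookkeeping: {len(self.states)} states + "
                f"{self.n_dropped} dropped != {self.n_fixations_total} fixations"
            )
        if any(s < 1 for s in self.states):
            raise ValueError("AOI states are 1-based positive integers")

    def __len__(self) -> int:
        return len(self.states)


def assign_fixation(fix: FixationRecord, aois: AOISet) -> Optional[int]:
    """Return the aoi_id of the first declared region containing the fixation.

    Returns ``None`` when the point lies outside every region; the caller's
    outside-policy decides what that means.  If more than one region
    contains the point (overlapping file), the first declared wins and a
    warning is emitted.
    """
    hits = [r.aoi_id for r in aois.regions if r.contains(fix.x, fix.y)]
    if not hits:
        return None
    if len(hits) > 1:
        warnings.warn(
            f"fixation at ({fix.x}, {fix.y}) falls in overlapping AOIs {hits} "
            f"of stimulus {aois.stimulus_id!r}; assigning first declared ({hits[0]})",
            stacklevel=2,
        )
    return hits[0]


def _check_trial(fixations: Sequence[FixationRecord]) -> None:
    keys = {(f.participant_id, f.stimulus_id) for f in fixations}
    if len(keys) > 1:
        raise ValueError(f"fixations span multiple trials: {sorted(keys)}")
    starts = [f.start for f in fixations]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ValueError("fixations must be sorted by start time")


def fixations_to_sequence(
    fixations: Sequence[FixationRecord],
    aois: AOISet,
    policy: str = "drop",
) -> AOISequence:
    """Map a trial's fixations to its AOI state sequence.

    Parameters
    ----------
    fixations
        Fixations of a single (participant, stimulus) trial, sorted by start.
    aois
        The stimulus' AOI definitions.
    policy
        How to treat fixations outside every AOI: ``"drop"`` removes them
        (counted in ``n_dropped``); ``"extra_state"`` maps them to the
        synthetic state ``s + 1``.
    """
    if policy not in ("drop", "extra_state"):
        raise ValueError(f"unknown outside-policy {policy!r}")
    if not fixations:
        return AOISequence("", "", (), 0, 0)
    _check_trial(fixations)
    s = aois.n_regions
    states: list[int] = []
    n_dropped = 0
    for fix in fixations:
        a = assign_fixation(fix, aois)
        if a is None:
            if policy == "drop":
                n_dropped += 1
            else:
                states.append(s + 1)
        else:
            states.append(a)
    return AOISequence(
        participant_id=fixations[0].participant_id,
        stimulus_id=fixations[0].stimulus_id,
        states=tuple(states),
        n_fixations_total=len(fixations),
        n_dropped=n_dropped,
    )


def dwell_summary(
    fixations: Sequence[FixationRecord],
    aois: AOISet,
    policy: str = "drop",
) -> pd.DataFrame:
    """Per-AOI visit counts and dwell times for one trial.

    Returns a DataFrame indexed by aoi_id with columns ``label``,
    ``n_fixations``, ``total_duration_ms`` and ``duration_share``; shares
    are relative to the fixations retained by the outside-policy and sum
    to 1 when any fixation is retained.  With ``policy="extra_state"``
    an extra row (id s+1, label "outside") collects outside fixations.
    """
    if policy not in ("drop", "extra_state"):
        raise ValueError(f"unknown outside-policy {policy!r}")
    if fixations:
        _check_trial(fixations)
    s = aois.n_regions
    ids = list(range(1, s + 1))
    labels = list(aois.labels)
    if policy == "extra_state":
        ids.append(s + 1)
        labels.append("outside")
    counts = {i: 0 for i in ids}
    durations = {i: 0.0 for i in ids}
    for fix in fixations:
        a = assign_fixation(fix, aois)
        if a is None:
            if policy == "drop":
                continue
            a = s + 1
        counts[a] += 1
        durations[a] += fix.duration
    total = sum(durations.values())
    out = pd.DataFrame(
        {
            "label": labels,
            "n_fixations": [counts[i] for i in ids],
            "total_duration_ms": [durations[i] for i in ids],
            "duration_share": [durations[i] / total if total > 0 else 0.0 for i in ids],
        },
        index=pd.Index(ids, name="aoi_id"),
    )
    return out
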
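"""End-to-end analysis and aggregation over many trials.

``analyze_trials`` runs fixation tables + AOI definitions through the
full path (assignment -> sequence -> counts -> channel -> metrics) and
returns one report row per (participant, stimulus).  ``aggregate_reports``
groups rows and returns means and standard deviations of the scalar
metrics; its pooled mode sums the per-trial count matrices before
normalisation, which by construction equals analysing ``pool_counts``
output directly (one code path).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .aoi import AOISet, FixationRecord, fixations_to_sequence
from .estimator import GazeChannelAnalyzer
from .markov import TransitionCounts, pool_counts

__all__ = ["analyze_trials", "aggregate_reports", "pooled_channel_record"]

_SCALARS = ("Hs", "Ht", "Hxy", "MI", "rho_Hs", "rho_Hxy")


def analyze_trials(
    fixations: Sequence[FixationRecord],
    aoi_sets: Mapping[str, AOISet],
    log_base="e",
    pi_mode: str = "empirical",
    outside_policy: str = "drop",
    zero_row_policy: str = "drop_state",
) -> list[dict]:
    """Channel metrics for every (participant, stimulus) trial.

    Trials whose stimulus has no AOI definition raise; trials with a
    single visited AOI are flagged ``degenerate`` (Hs = 0, no
    normalised MI) rather than dropped.  Each row echoes the policies
    used and the number of outside fixations dropped.
    """
    trials: dict[tuple[str, str], list[FixationRecord]] = defaultdict(list)
    for f in fixations:
        trials[(f.participant_id, f.stimulus_id)].append(f)
    records = []
    for (pid, stim), fixes in sorted(trials.items()):
        if stim not in aoi_sets:
            raise KeyError(f"no AOI definition for stimulus {stim!r}")
        aois = aoi_sets[stim]
        seq = fixations_to_sequence(sorted(fixes, key=lambda f: f.start), aois, policy=outside_policy)
        n_states = aois.n_regions + (1 if outside_policy == "extra_state" else 0)
        labels = list(aois.labels) + (["outside"] if outside_policy == "extra_state" else [])
        if len(seq) < 2:
            records.append(
                {
                    "participant": pid,
                    "stimulus": stim,
                    "degenerate": True,
                    "reason": "fewer than 2 retained fixations",
                    "n_dropped": seq.n_dropped,
                }
            )
            continue
        ana = GazeChannelAnalyzer(
            log_base=log_base, pi_mode=pi_mode, zero_row_policy=zero_row_policy
        ).fit([seq], n_states=n_states, labels=labels)
        rec = ana.report_record(participant=pid, stimulus=stim)
        rec["n_dropped"] = seq.n_dropped
        rec["outside_policy"] = outside_policy
        rec["zero_row_policy"] = zero_row_policy
        rec["degenerate"] = bool(ana.metrics_.Hs == 0.0)
        records.append(rec)
    return records


def aggregate_reports(records: Sequence[Mapping], group_by: str = "stimulus") -> pd.DataFrame:
    """Grouped mean and standard deviation of the scalar channel metrics.

    ``group_by`` is "participant" or "stimulus".  All rows must share
    one log base (mixing units is refused).  Degenerate rows are
    excluded and counted in the ``n_degenerate`` column.
    """
    if group_by not in ("participant", "stimulus"):
        raise ValueError(f"group_by must be 'participant' or 'stimulus', got {group_by!r}")
    bases = {r.get("base") for r in records if "base" in r}
    if len(bases) > 1:
        raise ValueError(f"mixed log bases in reports: {bases}")
    rows = [r for r in records if not r.get("degenerate", False)]
    degen = defaultdict(int)
    for r in records:
        if r.get("degenerate", False):
            degen[r[group_by]] += 1
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no non-degenerate reports to aggregate")
    agg = df.groupby(group_by)[list(_SCALARS)].agg(["mean", "std"])
    agg.columns = [f"{m}_{stat}" for m, stat in agg.columns]
    # single-member groups: sd is 0, not NaN
    agg[[c for c in agg.columns if c.endswith("_std")]] = agg[
        [c for c in agg.columns if c.endswith("_std")]
    ].fillna(0.0)
    agg["n_trials"] = df.groupby(group_by).size()
    agg["n_degenerate"] = [degen.get(g, 0) for g in agg.index]
    return agg


def pooled_channel_record(
    records: Sequence[Mapping],
    group: str,
    group_by: str = "stimulus",
    log_base="e",
    pi_mode: str = "empirical",
    zero_row_policy: str = "drop_state",
) -> dict:
    """Channel metrics of the pooled count matrix of one group.

    Sums the per-trial count matrices stored in the reports (fixation-
    mode reports carry them) and analyses the pooled matrix — the
    "average observer" channel of the group.
    """
    members = [r for r in records if r.get(group_by) == group and "counts" in r]
    if not members:
        raise ValueError(f"no reports with count matrices for {group_by} == {group!r}")
    parts = [
        TransitionCounts(labels=tuple(r["labels"]), n=np.asarray(r["counts"]))
        for r in members
    ]
    pooled = pool_counts(parts)
    ana = GazeChannelAnalyzer(
        log_base=log_base, pi_mode=pi_mode, zero_row_policy=zero_row_policy
    ).fit(pooled)
    rec = ana.report_record(participant="pooled", stimulus=group)
    rec["n_trials_pooled"] = len(members)
    return rec
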
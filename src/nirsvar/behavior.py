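"""Cognitive task scoring: reaction-time filtering, accuracy, sleepiness.

Two indicators summarise performance per participant and task:

* accuracy — correct responses over answerable stimuli, computed before any
  reaction-time filtering and irrespective of stimulus type;
* mean RT — the average of the responses remaining after a two-step outlier
  rule: (i) responses faster than 100 ms are removed as anticipations;
  (ii) per stimulus type, the mean and sample SD of the remaining correct
  responses define a cutoff mean + 2*SD, above which responses are removed
  as slow outliers.  The rule runs in a single pass (no re-iteration after
  removal).

Sleepiness change is the post-minus-pre difference of the 1-7 Stanford
Sleepiness Scale rating around each task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BehaviourSummary",
    "filter_rts",
    "summarize_behavior",
    "score_participant",
    "sss_change",
]

FAST_CUTOFF_MS = 100.0
SLOW_SD_FACTOR = 2.0

TRIAL_COLUMNS = [
    "participant_id",
    "task",
    "block_index",
    "stimulus_type",
    "rt_ms",
    "correct",
    "answerable",
]


@dataclass(frozen=True)
class BehaviourSummary:
    participant_id: str
    task: str
    mean_rt: float  # ms; NaN when no correct responses survive
    accuracy: float
    n_fast_excluded: int
    n_slow_excluded: int
    n_retained: int


def filter_rts(trials: pd.DataFrame) -> tuple[pd.DataFrame, int, int]:
    """Apply the two-step RT outlier rule to one participant x task.

    Returns (retained trials, n_fast_excluded, n_slow_excluded).  Only
    responded trials (non-missing RT) are subject to filtering; the slow
    cutoff for each stimulus type is computed from the remaining *correct*
    responses of that type and uses the sample SD.  Removal is strict
    (RT > mean + 2*SD), so identical RTs are never removed.
    """
    responded = trials[trials["rt_ms"].notna()]
    fast = responded["rt_ms"] < FAST_CUTOFF_MS
    n_fast = int(fast.sum())
    kept = responded[~fast]

    drop_idx: list = []
    for stim, sub in kept.groupby("stimulus_type", sort=False):
        ref = sub.loc[sub["correct"], "rt_ms"]
        if len(ref) < 2:
            continue  # no spread estimate; nothing removed for this type
        cutoff = ref.mean() + SLOW_SD_FACTOR * ref.std(ddof=1)
        drop_idx.extend(sub.index[sub["rt_ms"] > cutoff])
    n_slow = len(drop_idx)
    return kept.drop(index=drop_idx), n_fast, n_slow


def summarize_behavior(
    retained: pd.DataFrame, all_trials: pd.DataFrame
) -> BehaviourSummary:
    """Mean RT over retained correct responses; accuracy over all answerable.

    Accuracy is defined before RT filtering: correct responses divided by
    answerable stimuli, irrespective of stimulus type; missing responses
    count against accuracy.  With no correct retained responses the mean RT
    is NaN (flagged, not fabricated).
    """
    n_answerable = int(all_trials["answerable"].sum())
    if n_answerable == 0:
        raise ValueError("no answerable stimuli")
    accuracy = float(all_trials["correct"].sum() / n_answerable)
    correct_rts = retained.loc[retained["correct"], "rt_ms"]
    mean_rt = float(correct_rts.mean()) if len(correct_rts) else float("nan")
    pid = str(all_trials["participant_id"].iloc[0]) if len(all_trials) else ""
    task = str(all_trials["task"].iloc[0]) if len(all_trials) else ""
    n_fast = int(
        (all_trials["rt_ms"].notna() & (all_trials["rt_ms"] < FAST_CUTOFF_MS)).sum()
    )
    n_slow = int(all_trials["rt_ms"].notna().sum()) - n_fast - len(retained)
    return BehaviourSummary(
        participant_id=pid,
        task=task,
        mean_rt=mean_rt,
        accuracy=accuracy,
        n_fast_excluded=n_fast,
        n_slow_excluded=n_slow,
        n_retained=len(retained),
    )


def score_participant(trials: pd.DataFrame) -> BehaviourSummary:
    """Filter + summarise in one call (single participant x task)."""
    retained, _, _ = filter_rts(trials)
    return summarize_behavior(retained, trials)


def sss_change(records: pd.DataFrame) -> pd.DataFrame:
    """Per-group sleepiness change summary.

    ``records`` needs columns participant_id, group, task, sss_pre, sss_post
    with both ratings present for every row (unpaired rows are an error).
    Returns one row per group x task with mean and median post-pre delta.
    """
    if records[["sss_pre", "sss_post"]].isna().any().any():
        raise ValueError("unpaired sleepiness record (missing pre or post)")
    df = records.copy()
    df["delta"] = df["sss_post"] - df["sss_pre"]
    out = (
        df.groupby(["group", "task"], sort=False)["delta"]
        .agg(mean_delta="mean", median_delta="median", n="count")
        .reset_index()
    )
    return out
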
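"""Freezing quantification and extinction-learning metrics.

Freezing — the absence of all movement except breathing — is logged as time
intervals.  Percent freezing in a window is the fraction of the window
covered by (merged) freeze intervals.  Extinction learning is summarised by
the mean freezing over the first 10 CS trials (E-Ext), the last 10 (L-Ext),
and their difference, the per-animal extinction magnitude.  Animals that
fail to acquire conditioned fear (below 50% freezing on the first extinction
CS) are excluded from group analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .exceptions import EpochError, VtaOmissionError
from .session_model import EPOCH_N_TRIALS, SessionKind, SessionSchedule

__all__ = [
    "FreezingRecord",
    "ExtinctionMetrics",
    "EXCLUSION_THRESHOLD_PCT",
    "percent_freezing",
    "extinction_metrics",
    "apply_exclusion",
]

#: First-CS freezing below this (strict) excludes the animal.
EXCLUSION_THRESHOLD_PCT = 50.0

#: Post-CS freezing window length (movement-confound check), seconds.
POST_CS_WINDOW_S = 10.0


def _merge_intervals(intervals: Sequence[Tuple[float, float]]) -> List[Tuple[float, float]]:
    """Sort and merge overlapping or touching intervals."""
    merged: List[Tuple[float, float]] = []
    for start, stop in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], stop))
        else:
            merged.append((start, stop))
    return merged


@dataclass(frozen=True)
class FreezingRecord:
    """Scored freeze intervals of one animal in one session."""

    animal_id: str
    intervals: Tuple[Tuple[float, float], ...]
    session_kind: SessionKind = SessionKind.EXTINCTION

    def __post_init__(self) -> None:
        for start, stop in self.intervals:
            if not start < stop:
                raise VtaOmissionError(
                    f"freeze interval ({start}, {stop}) must have start < stop"
                )
        object.__setattr__(self, "intervals", tuple(_merge_intervals(self.intervals)))


@dataclass(frozen=True)
class ExtinctionMetrics:
    """Per-animal extinction summary over the CS windows of a session."""

    animal_id: str
    per_trial_pct: Tuple[float, ...]
    e_ext_pct: float
    l_ext_pct: float
    change_pct: float
    first_cs_pct: float
    post_cs_pct: Tuple[float, ...]


def percent_freezing(record: FreezingRecord, window: Tuple[float, float]) -> float:
    """Percent of a time window covered by freeze intervals."""
    start, stop = window
    if not start < stop:
        raise VtaOmissionError(f"degenerate window ({start}, {stop})")
    covered = sum(
        max(0.0, min(b, stop) - max(a, start)) for a, b in record.intervals
    )
    return 100.0 * covered / (stop - start)


def extinction_metrics(record: FreezingRecord, schedule: SessionSchedule) -> ExtinctionMetrics:
    """Per-CS freezing, epoch means, and the E-Ext minus L-Ext change.

    Also reports freezing in the 10 s after each CS offset (used as a
    movement-confound control for offset-locked neural signals).
    """
    n = schedule.n_trials
    if n < 2 * EPOCH_N_TRIALS:
        raise EpochError(
            f"extinction metrics need >= {2 * EPOCH_N_TRIALS} CS trials, got {n}"
        )
    per_trial = tuple(
        percent_freezing(record, (onset, onset + schedule.cs_duration_s))
        for onset in schedule.cs_onsets_s
    )
    post_cs = tuple(
        percent_freezing(record, (off, off + POST_CS_WINDOW_S))
        for off in schedule.cs_offsets_s
    )
    e_ext = float(np.mean(per_trial[:EPOCH_N_TRIALS]))
    l_ext = float(np.mean(per_trial[-EPOCH_N_TRIALS:]))
    return ExtinctionMetrics(
        animal_id=record.animal_id,
        per_trial_pct=per_trial,
        e_ext_pct=e_ext,
        l_ext_pct=l_ext,
        change_pct=e_ext - l_ext,
        first_cs_pct=per_trial[0],
        post_cs_pct=post_cs,
    )


def apply_exclusion(first_cs_pct: float) -> str:
    """Exclude animals with weak conditioned fear on the first extinction CS."""
    if not 0.0 <= first_cs_pct <= 100.0:
        raise VtaOmissionError("percentage must be within [0, 100]")
    return "exclude" if first_cs_pct < EXCLUSION_THRESHOLD_PCT else "include"
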
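"""Session protocols, trial schedules, and trial-epoch selection.

A cued fear-extinction experiment is organised in sessions: tone habituation
(CS alone, before conditioning), fear conditioning (CS co-terminating with a
footshock US), and extinction (CS alone again).  Every downstream stage —
spike PSTHs, photometry dF/F, freezing quantification — aligns its analysis
to the CS onsets of one of these sessions, so the schedule types here are the
shared backbone of the pipeline.

Conventions
-----------
* All times are seconds from session start, 0-based.
* Bins and windows are half-open, ``[t, t + dt)``.
* The inter-trial interval (ITI) runs from CS offset to the next CS onset and
  is drawn uniformly from its configured range.
* Trial indices are 1-based wherever they are user-facing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Tuple

import numpy as np

from .exceptions import ConfigurationError, EpochError

__all__ = [
    "SessionKind",
    "Epoch",
    "EPOCH_N_TRIALS",
    "ProtocolSpec",
    "SessionSchedule",
    "EpochSelection",
    "build_schedule",
    "epoch_trials",
]

#: Number of trials averaged in the early/late extinction epochs.
EPOCH_N_TRIALS = 10


class SessionKind(str, Enum):
    HABITUATION = "habituation"
    FEAR_CONDITIONING = "fear_conditioning"
    EXTINCTION = "extinction"
    REWARD_TASK = "reward_task"


class Epoch(str, Enum):
    """Named trial epochs: habituation, early extinction, late extinction."""

    HAB = "hab"
    E_EXT = "e_ext"
    L_EXT = "l_ext"
    ALL = "all"


@dataclass(frozen=True)
class ProtocolSpec:
    """Parameters of one behavioral session.

    Defaults follow the standard cued-fear protocol: a 10 s, 4 kHz tone CS,
    ITIs uniform on 40–120 s, and a 2 min pre-session baseline.
    """

    session_kind: SessionKind
    n_cs: int
    cs_duration_s: float = 10.0
    us_paired: bool = False
    iti_range_s: Tuple[float, float] = (40.0, 120.0)
    baseline_s: float = 120.0

    def __post_init__(self) -> None:
        if self.n_cs < 1:
            raise ConfigurationError("n_cs must be >= 1")
        if self.cs_duration_s <= 0:
            raise ConfigurationError("cs_duration_s must be positive")
        lo, hi = self.iti_range_s
        if lo < 0 or lo > hi:
            raise ConfigurationError(
                f"invalid ITI range {self.iti_range_s!r}: need 0 <= min <= max"
            )
        if self.baseline_s < 0:
            raise ConfigurationError("baseline_s must be non-negative")

    @classmethod
    def habituation(cls, n_cs: int = 10) -> "ProtocolSpec":
        return cls(SessionKind.HABITUATION, n_cs=n_cs)

    @classmethod
    def fear_conditioning(cls, n_pairings: int = 5) -> "ProtocolSpec":
        return cls(SessionKind.FEAR_CONDITIONING, n_cs=n_pairings, us_paired=True)

    @classmethod
    def extinction(cls, n_cs: int = 25) -> "ProtocolSpec":
        return cls(SessionKind.EXTINCTION, n_cs=n_cs)


@dataclass(frozen=True)
class SessionSchedule:
    """Realised event times of one session."""

    cs_onsets_s: Tuple[float, ...]
    cs_duration_s: float
    us_times_s: Tuple[float, ...]
    session_kind: SessionKind
    total_duration_s: float

    def __post_init__(self) -> None:
        onsets = np.asarray(self.cs_onsets_s)
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ConfigurationError("CS onsets must be strictly increasing")
        if self.cs_duration_s <= 0:
            raise ConfigurationError("cs_duration_s must be positive")

    @property
    def n_trials(self) -> int:
        return len(self.cs_onsets_s)

    @property
    def cs_offsets_s(self) -> Tuple[float, ...]:
        return tuple(t + self.cs_duration_s for t in self.cs_onsets_s)


@dataclass(frozen=True)
class EpochSelection:
    """1-based trial indices belonging to a named epoch."""

    epoch: Epoch
    trial_indices: Tuple[int, ...]


def build_schedule(spec: ProtocolSpec, seed: int) -> SessionSchedule:
    """Draw a randomised session schedule from a protocol spec.

    The first CS starts at the end of the pre-session baseline; each
    subsequent CS follows the previous offset after a uniform ITI draw.  For
    a US-paired session the US is delivered at every CS offset.  The same
    spec and seed always yield the same schedule.
    """
    rng = np.random.default_rng(seed)
    lo, hi = spec.iti_range_s
    itis = rng.uniform(lo, hi, size=spec.n_cs)
    onsets = [spec.baseline_s]
    for iti in itis[:-1]:
        onsets.append(onsets[-1] + spec.cs_duration_s + iti)
    us_times: Tuple[float, ...] = ()
    if spec.us_paired:
        us_times = tuple(t + spec.cs_duration_s for t in onsets)
    total = onsets[-1] + spec.cs_duration_s + itis[-1]
    return SessionSchedule(
        cs_onsets_s=tuple(onsets),
        cs_duration_s=spec.cs_duration_s,
        us_times_s=us_times,
        session_kind=spec.session_kind,
        total_duration_s=total,
    )


def epoch_trials(schedule: SessionSchedule, epoch: Epoch) -> EpochSelection:
    """Resolve an epoch name into 1-based trial indices of a session.

    ``E_EXT`` is the first 10 trials and ``L_EXT`` the last 10; ``HAB`` and
    ``ALL`` select every trial of the session.
    """
    epoch = Epoch(epoch)
    n = schedule.n_trials
    if epoch in (Epoch.HAB, Epoch.ALL):
        idx = tuple(range(1, n + 1))
    elif epoch is Epoch.E_EXT:
        if n < EPOCH_N_TRIALS:
            raise EpochError(f"early-extinction epoch needs >= {EPOCH_N_TRIALS} trials, got {n}")
        idx = tuple(range(1, EPOCH_N_TRIALS + 1))
    elif epoch is Epoch.L_EXT:
        if n < EPOCH_N_TRIALS:
            raise EpochError(f"late-extinction epoch needs >= {EPOCH_N_TRIALS} trials, got {n}")
        idx = tuple(range(n - EPOCH_N_TRIALS + 1, n + 1))
    else:  # pragma: no cover - exhaustive enum
        raise EpochError(f"unknown epoch {epoch!r}")
    return EpochSelection(epoch=epoch, trial_indices=idx)
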
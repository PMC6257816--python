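"""Fiber-photometry pipeline: filtering, downsampling, trial dF/F, windows.

Raw fluorescence is acquired at 2 kHz.  Preprocessing low-pass filters the
trace at 4 Hz (zero-phase 4th-order Butterworth by default) and downsamples
to 10 Hz by non-overlapping block averaging, which is inherently
anti-aliasing for the residual out-of-band power.

Per trial, dF/F is computed against the 5 s immediately before CS onset:
F0 is the mean fluorescence over [-5, 0) and dF/F = (F - F0)/F0 on the
-5 .. +15 s grid.  Window statistics then average dF/F over the trials of
an epoch and over either the 5 s following CS offset (the omission window)
or the full CS.  Reward responses use a 3 s pre-nosepoke baseline and the
3 s after delivery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal

from .exceptions import EpochError, ResamplingError, SignalError, WindowError

__all__ = [
    "PhotometryTrace",
    "TrialDff",
    "RewardResponse",
    "preprocess_trace",
    "trial_dff",
    "epoch_window_dff",
    "reward_dff",
]

logger = logging.getLogger(__name__)

#: Grid of a trial-aligned dF/F trace, seconds relative to CS onset.
TRIAL_PRE_S = 5.0
TRIAL_POST_S = 15.0


@dataclass(frozen=True)
class PhotometryTrace:
    """A fluorescence time series at a fixed sampling rate.

    Sample ``i`` represents time ``i / fs_hz`` from trace start (after block
    averaging this is the left edge of the averaged block).
    """

    samples: np.ndarray
    fs_hz: float
    fluorophore: str = "gCaMP6f"
    animal_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", arr)
        if self.fs_hz <= 0:
            raise SignalError("sampling rate must be positive")
        if not np.all(np.isfinite(arr)):
            raise SignalError("trace contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz


@dataclass(frozen=True)
class TrialDff:
    """CS-aligned dF/F for one trial on the -5 .. +15 s grid at 10 Hz."""

    time_rel_s: np.ndarray
    dff: np.ndarray
    trial_index: int


@dataclass(frozen=True)
class RewardResponse:
    """Mean dF/F after rewarded and unrewarded nosepokes."""

    rewarded_mean: float
    unrewarded_mean: float
    n_rewarded: int
    n_unrewarded: int
    n_skipped: int


def preprocess_trace(
    raw: PhotometryTrace,
    cutoff_hz: float = 4.0,
    target_fs_hz: float = 10.0,
    order: int = 4,
) -> PhotometryTrace:
    """Low-pass filter and downsample a raw trace.

    Zero-phase (forward-backward) Butterworth at ``cutoff_hz``, then
    non-overlapping block averaging down to ``target_fs_hz``.  The raw rate
    must be an integer multiple of the target rate; trailing samples that do
    not fill a block are dropped (output length = floor(n / factor)).
    """
    factor = raw.fs_hz / target_fs_hz
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ResamplingError(
            f"raw rate {raw.fs_hz} Hz is not an integer multiple of target {target_fs_hz} Hz"
        )
    factor = int(round(factor))
    sos = signal.butter(order, cutoff_hz, btype="low", fs=raw.fs_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, raw.samples)
    n_blocks = filtered.size // factor
    averaged = filtered[: n_blocks * factor].reshape(n_blocks, factor).mean(axis=1)
    return PhotometryTrace(
        samples=averaged, fs_hz=target_fs_hz,
        fluorophore=raw.fluorophore, animal_id=raw.animal_id,
    )


def trial_dff(
    trace10: PhotometryTrace,
    cs_onset_s: float,
    cs_duration_s: float = 10.0,
    trial_index: int = 0,
) -> TrialDff:
    """dF/F of one trial against its 5 s pre-CS baseline.

    The trace must cover [onset - 5, onset + 15); onsets are snapped to the
    nearest sample (<= half a sample period of error at 10 Hz).
    """
    fs = trace10.fs_hz
    n_pre = int(round(TRIAL_PRE_S * fs))
    n_total = int(round((TRIAL_PRE_S + TRIAL_POST_S) * fs))
    start = int(round((cs_onset_s - TRIAL_PRE_S) * fs))
    if start < 0 or start + n_total > trace10.samples.size:
        raise WindowError(
            f"trial at {cs_onset_s:.1f} s not fully covered by a "
            f"{trace10.duration_s:.1f} s trace"
        )
    segment = trace10.samples[start : start + n_total]
    f0 = float(segment[:n_pre].mean())
    if f0 <= 0:
        raise SignalError(f"non-positive baseline fluorescence F0 = {f0:.4g}")
    time_rel = np.arange(n_total) / fs - TRIAL_PRE_S
    return TrialDff(time_rel_s=time_rel, dff=(segment - f0) / f0, trial_index=trial_index)


def epoch_window_dff(
    trials: Sequence[TrialDff],
    window: str,
    cs_duration_s: float = 10.0,
) -> float:
    """Average dF/F over an epoch's trials, then over an analysis window.

    ``window`` is ``"omission_5s"`` (the 5 s following CS offset) or
    ``"cs_full"`` (the whole CS period).
    """
    if not trials:
        raise EpochError("no trials in epoch")
    if window == "omission_5s":
        lo, hi = cs_duration_s, cs_duration_s + 5.0
    elif window == "cs_full":
        lo, hi = 0.0, cs_duration_s
    else:
        raise WindowError(f"unknown window {window!r}")
    mean_trace = np.mean([t.dff for t in trials], axis=0)
    time_rel = trials[0].time_rel_s
    mask = (time_rel >= lo - 1e-9) & (time_rel < hi - 1e-9)
    if not mask.any():
        raise WindowError(f"window [{lo}, {hi}) s outside the trial grid")
    return float(mean_trace[mask].mean())


def reward_dff(
    trace10: PhotometryTrace,
    nosepoke_times_s: Sequence[float],
    rewarded_flags: Sequence[bool],
    baseline_s: float = 3.0,
    response_s: float = 3.0,
) -> RewardResponse:
    """Mean dF/F after nosepokes, split by reward delivery.

    Per event, F0 is the mean fluorescence over the ``baseline_s`` seconds
    before port entry and the response is the mean dF/F over the
    ``response_s`` seconds after delivery (delivery coincides with the
    rewarded poke).  Events too close to the trace edges are skipped with a
    warning and counted.  An empty category yields NaN, never 0.
    """
    if len(nosepoke_times_s) != len(rewarded_flags):
        raise WindowError("nosepoke times and reward flags differ in length")
    fs = trace10.fs_hz
    n_base = int(round(baseline_s * fs))
    n_resp = int(round(response_s * fs))
    by_flag: dict[bool, list[float]] = {True: [], False: []}
    n_skipped = 0
    for t, flag in zip(nosepoke_times_s, rewarded_flags):
        i = int(round(t * fs))
        if i - n_base < 0 or i + n_resp > trace10.samples.size:
            n_skipped += 1
            logger.warning("nosepoke at %.1f s too close to trace edge; skipped", t)
            continue
        f0 = float(trace10.samples[i - n_base : i].mean())
        if f0 <= 0:
            raise SignalError(f"non-positive pre-poke baseline at {t:.1f} s")
        resp = float(trace10.samples[i : i + n_resp].mean())
        by_flag[bool(flag)].append((resp - f0) / f0)
    return RewardResponse(
        rewarded_mean=float(np.mean(by_flag[True])) if by_flag[True] else float("nan"),
        unrewarded_mean=float(np.mean(by_flag[False])) if by_flag[False] else float("nan"),
        n_rewarded=len(by_flag[True]),
        n_unrewarded=len(by_flag[False]),
        n_skipped=n_skipped,
    )
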
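"""Single-unit pipeline: cell-type criteria, epoch PSTHs, z-scoring, labels.

Putative dopamine (DA) neurons are identified by the joint rate/waveform
criterion used for midbrain recordings: a home-cage baseline firing rate
strictly below 10 Hz together with a broad action potential (peak-to-peak
width strictly above 450 microseconds).  Everything else is treated as
putative non-DA (largely local GABA neurons).

Task responses are quantified on a peri-stimulus time histogram aligned to
CS onset, spanning -5 s to +15 s in 1 s bins (20 bins), averaged over the
trials of an epoch (habituation, early extinction, late extinction).  The
PSTH is z-scored against its own five pre-CS baseline bins:

    z_i = (x_i - mu_b) / sigma_b

with mu_b and sigma_b the mean and sample SD (n-1 denominator) of the five
baseline bins.  A unit is *US-omission excited* when the z-score of the
first bin after CS offset exceeds 2 AND exceeds the last CS bin's z-score
by at least 2 (so that sustained CS excitation does not masquerade as an
omission response); *omission inhibited* is the mirrored criterion.  CS
responses use the mean z over the CS bins against the same +/-2 threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import EpochError, StatisticsError, VtaOmissionError
from .session_model import Epoch, SessionSchedule, epoch_trials
from .stats_report import TestResult, paired_t

__all__ = [
    "UnitType",
    "ResponseLabel",
    "UnitRecord",
    "PSTH",
    "ZScoredPSTH",
    "DA_MAX_RATE_HZ",
    "DA_MIN_WIDTH_US",
    "classify_unit_type",
    "estimate_homecage_rate",
    "compute_epoch_psth",
    "zscore_psth",
    "classify_omission_response",
    "classify_cs_response",
    "population_omission_test",
    "analyze_units",
]

#: Putative-DA criteria: strict inequalities on both axes.
DA_MAX_RATE_HZ = 10.0
DA_MIN_WIDTH_US = 450.0

#: PSTH geometry relative to CS onset: [-5, +15) s in 1 s bins.
PSTH_START_S = -5.0
PSTH_STOP_S = 15.0
PSTH_BIN_S = 1.0
N_BINS = int(round((PSTH_STOP_S - PSTH_START_S) / PSTH_BIN_S))
N_BASELINE_BINS = 5

#: Classification thresholds on the z-scored PSTH.
Z_THRESHOLD = 2.0
Z_DELTA = 2.0


class UnitType(str, Enum):
    PUTATIVE_DA = "putative_DA"
    PUTATIVE_NON_DA = "putative_nonDA"


class ResponseLabel(str, Enum):
    EXCITED = "excited"
    INHIBITED = "inhibited"
    NONRESPONSIVE = "nonresponsive"
    UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class UnitRecord:
    """Spike times plus the metadata the classifier needs."""

    unit_id: str
    spike_times_s: np.ndarray
    homecage_rate_hz: float
    width_us: float

    def __post_init__(self) -> None:
        spikes = np.asarray(self.spike_times_s, dtype=float)
        object.__setattr__(self, "spike_times_s", spikes)
        if spikes.size and (np.any(spikes < 0) or np.any(np.diff(spikes) < 0)):
            raise VtaOmissionError(f"unit {self.unit_id}: spike times must be sorted and >= 0")
        if self.homecage_rate_hz < 0:
            raise VtaOmissionError(f"unit {self.unit_id}: home-cage rate must be >= 0")


@dataclass(frozen=True)
class PSTH:
    """Trial-averaged firing rate on the fixed 20-bin grid around CS onset."""

    bin_edges_s: np.ndarray          # 21 edges, -5 .. +15
    rate_hz: np.ndarray              # 20 trial-averaged rates
    epoch: Epoch
    n_trials: int
    trial_counts: Optional[np.ndarray] = None  # (n_trials, 20) raw counts

    @property
    def baseline_rates(self) -> np.ndarray:
        return self.rate_hz[:N_BASELINE_BINS]


@dataclass(frozen=True)
class ZScoredPSTH:
    """Baseline-normalised PSTH; invalid when the baseline SD is zero."""

    z: np.ndarray
    baseline_mean_hz: float
    baseline_sd_hz: float
    valid: bool
    epoch: Epoch


def classify_unit_type(homecage_rate_hz: float, width_us: float) -> UnitType:
    """Apply the putative-DA rate/width criterion (both strict)."""
    if homecage_rate_hz < 0 or width_us <= 0:
        raise VtaOmissionError("rate must be >= 0 and width > 0")
    if homecage_rate_hz < DA_MAX_RATE_HZ and width_us > DA_MIN_WIDTH_US:
        return UnitType.PUTATIVE_DA
    return UnitType.PUTATIVE_NON_DA


def estimate_homecage_rate(spike_times_s: Sequence[float], duration_s: float) -> float:
    """Mean firing rate of a home-cage segment: spike count over duration."""
    if duration_s <= 0:
        raise VtaOmissionError("duration must be positive")
    return len(spike_times_s) / duration_s


def compute_epoch_psth(unit: UnitRecord, schedule: SessionSchedule, epoch: Epoch) -> PSTH:
    """Trial-averaged PSTH aligned to the CS onsets of an epoch.

    Bin i covers ``[onset + edge_i, onset + edge_i + 1)`` and its value is
    the across-trial mean spike count, which is a rate in Hz because bins
    are 1 s wide.  Spikes exactly on a bin edge belong to the right-open
    bin starting there.
    """
    selection = epoch_trials(schedule, epoch)
    if not selection.trial_indices:
        raise EpochError(f"epoch {epoch!r} selects no trials")
    edges = PSTH_START_S + PSTH_BIN_S * np.arange(N_BINS + 1)
    onsets = np.asarray(schedule.cs_onsets_s)[[i - 1 for i in selection.trial_indices]]
    counts = np.empty((len(onsets), N_BINS))
    spikes = unit.spike_times_s
    for row, onset in enumerate(onsets):
        # half-open bins via searchsorted on the left edges
        idx = np.searchsorted(spikes, onset + edges, side="left")
        counts[row] = np.diff(idx)
    return PSTH(
        bin_edges_s=edges,
        rate_hz=counts.mean(axis=0),
        epoch=Epoch(epoch),
        n_trials=len(onsets),
        trial_counts=counts,
    )


def zscore_psth(psth: PSTH, baseline_sd: str = "psth_bins") -> ZScoredPSTH:
    """Normalise a PSTH by its 5-bin pre-CS baseline.

    ``baseline_sd`` selects where sigma_b comes from: ``"psth_bins"`` (the
    sample SD of the five baseline bins of the trial-averaged PSTH, the
    default) or ``"pooled_trials"`` (the sample SD of all per-trial baseline
    bin counts, requiring ``psth.trial_counts``).  A unit whose baseline SD
    is zero (e.g. a silent cell) cannot be normalised and is flagged invalid;
    downstream labels become ``unclassifiable``.
    """
    base = psth.baseline_rates
    mu = float(base.mean())
    if baseline_sd == "psth_bins":
        sd = float(base.std(ddof=1))
    elif baseline_sd == "pooled_trials":
        if psth.trial_counts is None:
            raise VtaOmissionError("pooled_trials convention needs per-trial counts")
        sd = float(psth.trial_counts[:, :N_BASELINE_BINS].std(ddof=1))
    else:
        raise VtaOmissionError(f"unknown baseline_sd convention {baseline_sd!r}")
    valid = sd > 0 and np.isfinite(sd)
    z = (psth.rate_hz - mu) / sd if valid else np.full(N_BINS, np.nan)
    return ZScoredPSTH(z=z, baseline_mean_hz=mu, baseline_sd_hz=sd if valid else 0.0,
                       valid=valid, epoch=psth.epoch)


def _bin_indices(cs_duration_s: float) -> Tuple[slice, int, int]:
    """(CS-bin slice, last-CS bin index, omission bin index) for a CS length."""
    n_cs_bins = int(round(cs_duration_s / PSTH_BIN_S))
    first_cs = N_BASELINE_BINS
    omission = first_cs + n_cs_bins
    if omission >= N_BINS:
        raise VtaOmissionError(
            f"CS of {cs_duration_s} s leaves no post-offset bin in the {N_BINS}-bin PSTH"
        )
    return slice(first_cs, omission), omission - 1, omission


def classify_omission_response(z: ZScoredPSTH, cs_duration_s: float = 10.0) -> ResponseLabel:
    """Label the response in the first 1 s bin after CS offset.

    Excited: z > 2 in the omission bin AND at least 2 above the last CS bin
    (isolating the omission from sustained CS excitation).  Inhibited is the
    mirror image.  Invalid z-scores are unclassifiable.
    """
    if not z.valid:
        return ResponseLabel.UNCLASSIFIABLE
    _, last_cs, omission = _bin_indices(cs_duration_s)
    z_omit = z.z[omission]
    z_last = z.z[last_cs]
    if z_omit > Z_THRESHOLD and (z_omit - z_last) >= Z_DELTA:
        return ResponseLabel.EXCITED
    if z_omit < -Z_THRESHOLD and (z_last - z_omit) >= Z_DELTA:
        return ResponseLabel.INHIBITED
    return ResponseLabel.NONRESPONSIVE


def classify_cs_response(z: ZScoredPSTH, cs_duration_s: float = 10.0) -> ResponseLabel:
    """Label the mean z-score over the CS bins against the +/-2 threshold."""
    if not z.valid:
        return ResponseLabel.UNCLASSIFIABLE
    cs_slice, _, _ = _bin_indices(cs_duration_s)
    mean_z = float(np.mean(z.z[cs_slice]))
    if mean_z > Z_THRESHOLD:
        return ResponseLabel.EXCITED
    if mean_z < -Z_THRESHOLD:
        return ResponseLabel.INHIBITED
    return ResponseLabel.NONRESPONSIVE


def population_omission_test(psths: Sequence[PSTH], cs_duration_s: float = 10.0) -> TestResult:
    """Paired t-test of omission-bin rate against baseline across units.

    Each unit contributes one pair: its raw omission-bin rate and the mean of
    its five baseline bins.  df = n_units - 1, two-tailed.
    """
    if len(psths) < 2:
        raise StatisticsError("population test needs at least 2 units")
    _, _, omission = _bin_indices(cs_duration_s)
    omit = np.array([p.rate_hz[omission] for p in psths])
    base = np.array([p.baseline_rates.mean() for p in psths])
    return paired_t(omit, base)


def analyze_units(
    units: Iterable[Tuple[UnitRecord, SessionSchedule, Sequence[Epoch]]],
    baseline_sd: str = "psth_bins",
) -> pd.DataFrame:
    """Run the full single-unit pipeline over (unit, schedule, epochs) triples.

    Returns one row per unit per epoch with the cell-type call, the key
    z-scores, and the omission / CS response labels.
    """
    rows = []
    for unit, schedule, epochs in units:
        cell_class = classify_unit_type(unit.homecage_rate_hz, unit.width_us)
        for epoch in epochs:
            psth = compute_epoch_psth(unit, schedule, epoch)
            z = zscore_psth(psth, baseline_sd=baseline_sd)
            cs_dur = schedule.cs_duration_s
            _, last_cs, omission = _bin_indices(cs_dur)
            cs_slice, _, _ = _bin_indices(cs_dur)
            rows.append(
                {
                    "unit_id": unit.unit_id,
                    "cell_class": cell_class.value,
                    "epoch": Epoch(epoch).value,
                    "homecage_rate_hz": unit.homecage_rate_hz,
                    "width_us": unit.width_us,
                    "omission_rate_hz": float(psth.rate_hz[omission]),
                    "psth_baseline_hz": float(psth.baseline_rates.mean()),
                    "z_omit": z.z[omission] if z.valid else np.nan,
                    "z_last_cs": z.z[last_cs] if z.valid else np.nan,
                    "cs_mean_z": float(np.mean(z.z[cs_slice])) if z.valid else np.nan,
                    "omission_label": classify_omission_response(z, cs_dur).value,
                    "cs_label": classify_cs_response(z, cs_dur).value,
                    "valid": z.valid,
                }
            )
    return pd.DataFrame(rows)
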
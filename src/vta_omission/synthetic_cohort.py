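"""Synthetic cohort generator: spike trains, photometry, freezing.

No raw recordings are deposited for this kind of experiment, so the pipeline
is exercised on simulated cohorts that carry the statistical structure the
analysis assumes:

* **Spiking** — each unit is an inhomogeneous Poisson process.  The rate is
  the home-cage baseline, optionally modulated multiplicatively during the
  CS, plus an additive transient in the 1 s after CS offset whose amplitude
  decays exponentially across extinction trials (the prediction-error-like
  omission signal).  Sampling is by thinning against the piecewise-constant
  rate ceiling.
* **Photometry** — a latent per-trial omission transient (amplitude decaying
  across trials with the animal's learning time constant) shaped by a causal
  calcium-indicator kernel ``h(t) = (1 - e^(-t/tau_rise)) * e^(-t/tau_decay)``,
  scaled onto a baseline fluorescence, plus Gaussian noise and a slow
  sinusoidal drift, sampled at 2 kHz.
* **Freezing** — per-trial expected freezing follows an exponential
  extinction curve between a start and end level, realised as freeze bouts
  inside each CS window with beta-distributed per-trial noise.

Across animals, the omission-signal amplitude and the learning rate are
drawn jointly through a Gaussian copula so that the cohort exhibits a
configurable Spearman correlation between omission amplitude and the
E-Ext minus L-Ext freezing change.

Every entity derives its RNG stream from the master seed by stable hashing
of its identifier, so cohorts are reproducible piecewise.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import special

from .behavior_analysis import FreezingRecord
from .exceptions import ParameterError
from .photometry_analysis import PhotometryTrace
from .session_model import ProtocolSpec, SessionKind, SessionSchedule, build_schedule
from .spike_analysis import UnitRecord

__all__ = [
    "CSModulation",
    "UnitParams",
    "AnimalParams",
    "CohortConfig",
    "BehaviorSimulation",
    "derive_seed_sequence",
    "simulate_unit",
    "simulate_photometry",
    "simulate_reward_photometry",
    "simulate_behavior",
    "build_reward_events",
    "draw_cohort_params",
    "generate_cohort",
]

#: Default home-cage segment used to estimate baseline rate, seconds.
HOMECAGE_DURATION_S = 300.0

#: Indicator decay constants by fluorophore, seconds.
INDICATOR_TAU_DECAY_S = {"gCaMP6f": 0.4, "gCaMP6s": 1.0, "GFP": 0.4}
INDICATOR_TAU_RISE_S = 0.05


class CSModulation(str, Enum):
    NONE = "none"
    SUSTAINED_EXC = "sustained_exc"
    SUSTAINED_INH = "sustained_inh"
    TRANSIENT_ONSET = "transient_onset"


@dataclass(frozen=True)
class UnitParams:
    """Generative parameters of one simulated unit."""

    unit_id: str
    cell_class: str = "DA"  # "DA" | "nonDA"
    baseline_rate_hz: float = 5.0
    width_us: float = 550.0
    cs_modulation: CSModulation = CSModulation.NONE
    cs_gain: float = 1.0
    omission_amplitude_hz: float = 0.0
    omission_decay_trials: float = math.inf

    def __post_init__(self) -> None:
        if self.baseline_rate_hz <= 0:
            raise ParameterError("baseline rate must be positive")
        if self.cs_gain < 0:
            raise ParameterError("cs_gain must be >= 0 (rates cannot be negative)")
        if self.omission_amplitude_hz < 0:
            raise ParameterError("omission amplitude must be >= 0")
        if self.omission_decay_trials <= 0:
            raise ParameterError("omission decay constant must be positive")


@dataclass(frozen=True)
class AnimalParams:
    """Generative parameters of one simulated photometry/behavior animal."""

    animal_id: str
    fluorophore: str = "gCaMP6f"  # "gCaMP6f" | "gCaMP6s" | "GFP"
    omission_amp: float = 0.3               # peak dF/F of the trial-1 omission transient
    indicator_tau_decay_s: float = 0.4
    indicator_tau_rise_s: float = INDICATOR_TAU_RISE_S
    noise_sd: float = 0.003                 # fraction of baseline fluorescence
    drift_amplitude: float = 0.005          # fraction of baseline fluorescence
    drift_period_s: float = 300.0
    freeze_start_pct: float = 80.0
    freeze_end_pct: float = 15.0
    learning_tau_trials: float = 5.0
    freeze_noise_conc: float = 100.0        # beta concentration; inf = noiseless
    reward_amp: float = 0.25
    cs_amp: float = 0.0                     # optional CS-onset transient, dF/F

    def __post_init__(self) -> None:
        if self.fluorophore == "GFP" and self.omission_amp != 0:
            raise ParameterError("GFP controls must have zero omission amplitude")
        for pct in (self.freeze_start_pct, self.freeze_end_pct):
            if not 0.0 <= pct <= 100.0:
                raise ParameterError("freezing percentages must lie in [0, 100]")
        if self.omission_amp < 0 or self.reward_amp < 0:
            raise ParameterError("signal amplitudes must be >= 0")
        if self.indicator_tau_decay_s <= 0 or self.indicator_tau_rise_s <= 0:
            raise ParameterError("indicator time constants must be positive")
        if self.learning_tau_trials <= 0:
            raise ParameterError("learning time constant must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level knobs; defaults mirror the study's group sizes."""

    n_animals: int = 10                     # indicator-expressing animals
    n_gfp: int = 4                          # fluorophore controls
    units_per_animal: int = 8               # per recording day
    fraction_omission_responders: float = 0.25
    target_spearman: float = 0.8
    master_seed: int = 0
    n_extinction_trials: int = 25
    include_ephys: bool = True
    include_photometry: bool = True
    include_reward: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_omission_responders <= 1.0:
            raise ParameterError("fraction_omission_responders must lie in [0, 1]")
        if abs(self.target_spearman) > 1.0:
            raise ParameterError("|target_spearman| must be <= 1")
        if abs(self.target_spearman) >= 1.0 and self.n_animals < 3:
            raise ParameterError("a degenerate copula needs at least 3 animals")
        if self.n_animals < 1 or self.units_per_animal < 0:
            raise ParameterError("cohort sizes must be positive")


@dataclass(frozen=True)
class BehaviorSimulation:
    """Freeze-interval log plus the realised per-trial percentages."""

    record: FreezingRecord
    per_trial_pct: Tuple[float, ...]


def derive_seed_sequence(master_seed: int, entity_id: str) -> np.random.SeedSequence:
    """Stable per-entity seed stream: master seed + CRC32 of the entity id."""
    return np.random.SeedSequence([int(master_seed), zlib.crc32(entity_id.encode())])


# --------------------------------------------------------------------------
# Spiking


def rate_at(times: np.ndarray, params: UnitParams, schedule: SessionSchedule) -> np.ndarray:
    """Instantaneous firing rate of the generative model at given times."""
    times = np.asarray(times, dtype=float)
    r = np.full(times.shape, params.baseline_rate_hz)
    onsets = np.asarray(schedule.cs_onsets_s)
    if onsets.size == 0:
        return r
    idx = np.searchsorted(onsets, times, side="right") - 1
    has_trial = idx >= 0
    rel = np.where(has_trial, times - onsets[np.clip(idx, 0, None)], np.inf)
    if params.cs_modulation is CSModulation.SUSTAINED_EXC or \
            params.cs_modulation is CSModulation.SUSTAINED_INH:
        in_cs = has_trial & (rel < schedule.cs_duration_s)
        r[in_cs] = params.baseline_rate_hz * params.cs_gain
    elif params.cs_modulation is CSModulation.TRANSIENT_ONSET:
        in_onset = has_trial & (rel < 1.0)
        r[in_onset] = params.baseline_rate_hz * params.cs_gain
    if params.omission_amplitude_hz > 0:
        us_times = set(np.round(schedule.us_times_s, 6))
        rel_off = rel - schedule.cs_duration_s
        in_omit = has_trial & (rel_off >= 0) & (rel_off < 1.0)
        if us_times:
            # no omission transient where the US is actually delivered
            offsets = onsets[np.clip(idx, 0, None)] + schedule.cs_duration_s
            delivered = np.isin(np.round(offsets, 6), list(us_times))
            in_omit &= ~delivered
        trial_no = np.clip(idx, 0, None) + 1
        amp = params.omission_amplitude_hz * np.exp(
            -(trial_no - 1) / params.omission_decay_trials
        )
        r = r + np.where(in_omit, amp, 0.0)
    if np.any(r < 0):
        raise ParameterError("negative instantaneous rate; check cs_gain")
    return r


def simulate_unit(
    params: UnitParams,
    schedule: SessionSchedule,
    seed,
    homecage_duration_s: float = HOMECAGE_DURATION_S,
) -> UnitRecord:
    """Draw one unit's session spike train plus a home-cage baseline segment.

    Session spikes come from the inhomogeneous Poisson model by thinning; the
    home-cage segment is homogeneous Poisson at the baseline rate and yields
    the unit's *measured* home-cage rate (count over duration), the quantity
    the DA/non-DA classifier consumes.
    """
    rng = np.random.default_rng(seed)
    gain_ceiling = max(1.0, params.cs_gain) if params.cs_modulation is not CSModulation.NONE else 1.0
    r_max = params.baseline_rate_hz * gain_ceiling + params.omission_amplitude_hz
    total = schedule.total_duration_s
    n_cand = rng.poisson(r_max * total)
    candidates = np.sort(rng.uniform(0.0, total, size=n_cand))
    accept = rng.uniform(size=n_cand) * r_max < rate_at(candidates, params, schedule)
    spikes = candidates[accept]
    n_home = rng.poisson(params.baseline_rate_hz * homecage_duration_s)
    return UnitRecord(
        unit_id=params.unit_id,
        spike_times_s=spikes,
        homecage_rate_hz=n_home / homecage_duration_s,
        width_us=params.width_us,
    )


# --------------------------------------------------------------------------
# Photometry


def indicator_kernel(
    t: np.ndarray, tau_rise_s: float, tau_decay_s: float, normalize: bool = True
) -> np.ndarray:
    """Causal calcium-indicator impulse response, optionally peak-normalised."""
    t = np.asarray(t, dtype=float)
    h = np.where(t >= 0, (1.0 - np.exp(-t / tau_rise_s)) * np.exp(-t / tau_decay_s), 0.0)
    if normalize:
        t_peak = tau_rise_s * math.log1p(tau_decay_s / tau_rise_s)
        h_peak = (1.0 - math.exp(-t_peak / tau_rise_s)) * math.exp(-t_peak / tau_decay_s)
        h = h / h_peak
    return h


def _add_transients(
    latent: np.ndarray,
    event_times_s: Sequence[float],
    amplitudes: Sequence[float],
    fs_hz: float,
    tau_rise_s: float,
    tau_decay_s: float,
) -> None:
    """Add peak-normalised indicator transients in place."""
    n = latent.size
    span = int(round((tau_rise_s + 8.0 * tau_decay_s) * fs_hz))
    tail_t = np.arange(span) / fs_hz
    kernel = indicator_kernel(tail_t, tau_rise_s, tau_decay_s)
    for t0, amp in zip(event_times_s, amplitudes):
        if amp == 0:
            continue
        i0 = int(round(t0 * fs_hz))
        i1 = min(i0 + span, n)
        if i0 >= n:
            continue
        latent[i0:i1] += amp * kernel[: i1 - i0]


def simulate_photometry(
    params: AnimalParams,
    schedule: SessionSchedule,
    seed,
    fs_hz: float = 2000.0,
    baseline_f: float = 1.0,
    apply_omission: Optional[bool] = None,
) -> PhotometryTrace:
    """Simulate one session's raw fluorescence trace at acquisition rate.

    The omission transient (peak dF/F ``omission_amp`` on trial 1, decaying
    across trials with the animal's learning time constant) is placed at each
    CS offset of extinction sessions; habituation and conditioned sessions
    carry no omission expectation and get none unless ``apply_omission``
    forces it.
    """
    if baseline_f <= 0:
        raise ParameterError("baseline fluorescence must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(schedule.total_duration_s * fs_hz))
    latent = np.zeros(n)
    if apply_omission is None:
        apply_omission = schedule.session_kind is SessionKind.EXTINCTION
    tau_d = params.indicator_tau_decay_s
    tau_r = params.indicator_tau_rise_s
    if apply_omission and params.omission_amp > 0:
        trials = np.arange(1, schedule.n_trials + 1)
        amps = params.omission_amp * np.exp(-(trials - 1) / params.learning_tau_trials)
        _add_transients(latent, schedule.cs_offsets_s, amps, fs_hz, tau_r, tau_d)
    if params.cs_amp > 0:
        _add_transients(
            latent, schedule.cs_onsets_s,
            np.full(schedule.n_trials, params.cs_amp), fs_hz, tau_r, tau_d,
        )
    t = np.arange(n) / fs_hz
    drift = params.drift_amplitude * np.sin(2.0 * np.pi * t / params.drift_period_s)
    noise = rng.normal(0.0, params.noise_sd * baseline_f, size=n) if params.noise_sd > 0 else 0.0
    samples = baseline_f * (1.0 + latent + drift) + noise
    return PhotometryTrace(
        samples=samples, fs_hz=fs_hz,
        fluorophore=params.fluorophore, animal_id=params.animal_id,
    )


def build_reward_events(
    n_pokes: int = 40,
    iti_range_s: Tuple[float, float] = (3.0, 5.0),
    p_reward: float = 0.5,
    start_s: float = 30.0,
    seed=None,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Nosepoke times, reward flags, and session duration for the reward task."""
    rng = np.random.default_rng(seed)
    gaps = rng.uniform(*iti_range_s, size=n_pokes)
    times = start_s + np.cumsum(gaps)
    rewarded = rng.uniform(size=n_pokes) < p_reward
    return times, rewarded, float(times[-1] + 30.0)


def simulate_reward_photometry(
    params: AnimalParams,
    nosepoke_times_s: Sequence[float],
    rewarded_flags: Sequence[bool],
    total_duration_s: float,
    seed,
    fs_hz: float = 2000.0,
    baseline_f: float = 1.0,
) -> PhotometryTrace:
    """Simulate the operant-task trace: transients at rewarded pokes only."""
    if baseline_f <= 0:
        raise ParameterError("baseline fluorescence must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(total_duration_s * fs_hz))
    latent = np.zeros(n)
    amps = [params.reward_amp if f else 0.0 for f in rewarded_flags]
    _add_transients(latent, nosepoke_times_s, amps, fs_hz,
                    params.indicator_tau_rise_s, params.indicator_tau_decay_s)
    t = np.arange(n) / fs_hz
    drift = params.drift_amplitude * np.sin(2.0 * np.pi * t / params.drift_period_s)
    noise = rng.normal(0.0, params.noise_sd * baseline_f, size=n) if params.noise_sd > 0 else 0.0
    samples = baseline_f * (1.0 + latent + drift) + noise
    return PhotometryTrace(samples=samples, fs_hz=fs_hz,
                           fluorophore=params.fluorophore, animal_id=params.animal_id)


# --------------------------------------------------------------------------
# Behavior


def expected_freezing_pct(params: AnimalParams, trial: np.ndarray) -> np.ndarray:
    """Exponential extinction curve between the start and end freezing levels."""
    k = np.asarray(trial, dtype=float)
    return params.freeze_end_pct + (params.freeze_start_pct - params.freeze_end_pct) * np.exp(
        -(k - 1.0) / params.learning_tau_trials
    )


def simulate_behavior(params: AnimalParams, schedule: SessionSchedule, seed) -> BehaviorSimulation:
    """Realise per-trial freezing as freeze bouts inside each CS window.

    Per-trial freezing fractions follow the extinction curve with
    beta-distributed noise of concentration ``freeze_noise_conc`` (infinite
    concentration = noiseless).  Each trial's freeze time is placed as one
    contiguous bout at a random offset inside the CS window.
    """
    rng = np.random.default_rng(seed)
    cs_dur = schedule.cs_duration_s
    expected = expected_freezing_pct(params, np.arange(1, schedule.n_trials + 1)) / 100.0
    intervals = []
    realized = []
    for onset, p in zip(schedule.cs_onsets_s, expected):
        p = float(np.clip(p, 0.0, 1.0))
        if math.isfinite(params.freeze_noise_conc):
            p_eff = float(np.clip(p, 1e-6, 1.0 - 1e-6))
            c = params.freeze_noise_conc
            p = float(rng.beta(c * p_eff, c * (1.0 - p_eff)))
        realized.append(100.0 * p)
        duration = p * cs_dur
        if duration <= 0:
            continue
        offset = rng.uniform(0.0, cs_dur - duration) if duration < cs_dur else 0.0
        intervals.append((onset + offset, onset + offset + duration))
    record = FreezingRecord(
        animal_id=params.animal_id,
        intervals=tuple(intervals),
        session_kind=schedule.session_kind,
    )
    return BehaviorSimulation(record=record, per_trial_pct=tuple(realized))


# --------------------------------------------------------------------------
# Cohort assembly


#: Ranges of the copula-mapped animal parameters (see docs/methods.md).
OMISSION_AMP_RANGE = (0.05, 0.60)     # peak dF/F
FREEZE_END_RANGE = (40.0, 5.0)        # percent, high->low with learning score
LEARNING_TAU_RANGE = (2.0, 8.0)       # trials
FREEZE_START_PCT = 80.0


def draw_cohort_params(config: CohortConfig, seed=None) -> List[AnimalParams]:
    """Draw per-animal parameters; the Gaussian copula couples the omission
    amplitude with a latent learning score that drives both the asymptotic
    freezing level and the extinction time constant.

    The latent bivariate-normal correlation is ``2 sin(pi * rho_s / 6)``, the
    exact inverse of the normal-scores Spearman relation, so the *latent*
    Spearman between amplitude and learning score equals ``target_spearman``
    (the measured value is attenuated only by behavioral trial noise).
    GFP controls get a zero-amplitude signal and a median learning score.
    """
    rng = np.random.default_rng(
        derive_seed_sequence(config.master_seed, "cohort_params") if seed is None else seed
    )
    rho = config.target_spearman
    r_latent = 2.0 * math.sin(math.pi * rho / 6.0)
    cov = [[1.0, r_latent], [r_latent, 1.0]]
    z = rng.multivariate_normal([0.0, 0.0], cov, size=config.n_animals)
    u = special.ndtr(z)
    amp_lo, amp_hi = OMISSION_AMP_RANGE
    fe_hi, fe_lo = FREEZE_END_RANGE
    tau_lo, tau_hi = LEARNING_TAU_RANGE
    animals: List[AnimalParams] = []
    for i in range(config.n_animals):
        s = u[i, 1]  # learning score in (0, 1)
        fluor = "gCaMP6f" if i % 2 == 0 else "gCaMP6s"
        animals.append(
            AnimalParams(
                animal_id=f"a{i + 1:02d}",
                fluorophore=fluor,
                omission_amp=amp_lo + (amp_hi - amp_lo) * u[i, 0],
                indicator_tau_decay_s=INDICATOR_TAU_DECAY_S[fluor],
                freeze_start_pct=FREEZE_START_PCT,
                freeze_end_pct=fe_hi + (fe_lo - fe_hi) * s,
                learning_tau_trials=tau_lo + (tau_hi - tau_lo) * s,
                reward_amp=float(rng.uniform(0.10, 0.40)),
            )
        )
    for j in range(config.n_gfp):
        animals.append(
            AnimalParams(
                animal_id=f"g{j + 1:02d}",
                fluorophore="GFP",
                omission_amp=0.0,
                indicator_tau_decay_s=INDICATOR_TAU_DECAY_S["GFP"],
                freeze_start_pct=FREEZE_START_PCT,
                freeze_end_pct=float(np.mean(FREEZE_END_RANGE)),
                learning_tau_trials=float(np.mean(LEARNING_TAU_RANGE)),
                reward_amp=0.0,
            )
        )
    return animals


#: Unit-population composition on each recording day.
DA_FRACTION = 0.55
DA_RATE_RANGE_HZ = (1.5, 8.5)
DA_WIDTH_RANGE_US = (480.0, 650.0)
NONDA_RATE_RANGE_HZ = (4.0, 25.0)
NONDA_WIDTH_RANGE_US = (150.0, 430.0)
OMISSION_AMP_RANGE_HZ = (10.0, 20.0)
OMISSION_DECAY_TRIALS = 4.0
CS_MOD_FRACTIONS = {CSModulation.SUSTAINED_EXC: 0.07, CSModulation.SUSTAINED_INH: 0.07}


def draw_unit_params(
    n_units: int,
    session: str,
    prefix: str,
    fraction_omission_responders: float,
    rng: np.random.Generator,
) -> List[UnitParams]:
    """Draw one recording day's unit population.

    DA units sit inside the rate/width criterion with margin; non-DA units
    fail the width criterion.  Only extinction-day DA units can carry an
    omission transient (habituation precedes conditioning, so there is no
    US expectation to violate).
    """
    units: List[UnitParams] = []
    for i in range(n_units):
        is_da = rng.uniform() < DA_FRACTION
        mod = CSModulation.NONE
        gain = 1.0
        roll = rng.uniform()
        if roll < CS_MOD_FRACTIONS[CSModulation.SUSTAINED_EXC]:
            mod, gain = CSModulation.SUSTAINED_EXC, float(rng.uniform(1.3, 1.8))
        elif roll < sum(CS_MOD_FRACTIONS.values()):
            mod, gain = CSModulation.SUSTAINED_INH, float(rng.uniform(0.4, 0.8))
        amp = 0.0
        if is_da and session == "ext" and rng.uniform() < fraction_omission_responders:
            amp = float(rng.uniform(*OMISSION_AMP_RANGE_HZ))
        units.append(
            UnitParams(
                unit_id=f"{prefix}_{session}_u{i + 1:02d}",
                cell_class="DA" if is_da else "nonDA",
                baseline_rate_hz=float(rng.uniform(*(DA_RATE_RANGE_HZ if is_da else NONDA_RATE_RANGE_HZ))),
                width_us=float(rng.uniform(*(DA_WIDTH_RANGE_US if is_da else NONDA_WIDTH_RANGE_US))),
                cs_modulation=mod,
                cs_gain=gain,
                omission_amplitude_hz=amp,
                omission_decay_trials=OMISSION_DECAY_TRIALS,
            )
        )
    return units


def generate_cohort(config: CohortConfig, output_dir) -> dict:
    """Generate and write a full synthetic cohort; returns the manifest.

    Per animal: habituation and extinction schedules (events table), spike
    trains plus unit metadata for both recording days, raw 2 kHz photometry
    for both sessions and the operant reward task, and the extinction
    freeze-interval log.  All streams are seeded from the master seed by
    stable id hashing.  The manifest (also written as ``manifest.json``)
    lists every file and the generative ground truth.
    """
    from . import io as _io  # local import to keep module load light

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    animals = draw_cohort_params(config)
    manifest: dict = {
        "config": {
            "n_animals": config.n_animals,
            "n_gfp": config.n_gfp,
            "units_per_animal": config.units_per_animal,
            "fraction_omission_responders": config.fraction_omission_responders,
            "target_spearman": config.target_spearman,
            "master_seed": config.master_seed,
            "n_extinction_trials": config.n_extinction_trials,
        },
        "cs_duration_s": 10.0,
        "animals": [],
    }
    for params in animals:
        aid = params.animal_id
        ss = derive_seed_sequence(config.master_seed, aid)
        seeds = ss.spawn(8)
        hab_schedule = build_schedule(ProtocolSpec.habituation(), seeds[0])
        ext_schedule = build_schedule(
            ProtocolSpec.extinction(config.n_extinction_trials), seeds[1]
        )
        sessions = {"hab": hab_schedule, "ext": ext_schedule}
        entry: dict = {
            "animal_id": aid,
            "fluorophore": params.fluorophore,
            "sessions": {
                name: {"kind": sch.session_kind.value, "n_trials": sch.n_trials}
                for name, sch in sessions.items()
            },
            "true_params": {
                "omission_amp": params.omission_amp,
                "learning_tau_trials": params.learning_tau_trials,
                "freeze_end_pct": params.freeze_end_pct,
                "reward_amp": params.reward_amp,
            },
            "files": {},
        }
        # events
        reward_pokes = reward_flags = None
        reward_duration = None
        if config.include_reward:
            reward_pokes, reward_flags, reward_duration = build_reward_events(seed=seeds[2])
        events_path = out / f"events_{aid}.csv"
        _io.write_events(events_path, aid, sessions, reward_pokes, reward_flags)
        entry["files"]["events"] = events_path.name
        # spiking (both recording days)
        if config.include_ephys:
            unit_rng = np.random.default_rng(seeds[3])
            unit_records = []
            unit_meta = []
            true_units = []
            for session_name, schedule in sessions.items():
                day_units = draw_unit_params(
                    config.units_per_animal, session_name, aid,
                    config.fraction_omission_responders, unit_rng,
                )
                for up in day_units:
                    rec = simulate_unit(
                        up, schedule, derive_seed_sequence(config.master_seed, up.unit_id)
                    )
                    unit_records.append((session_name, rec))
                    unit_meta.append(
                        {
                            "unit_id": up.unit_id,
                            "session": session_name,
                            "baseline_rate_hz": rec.homecage_rate_hz,
                            "width_us": up.width_us,
                        }
                    )
                    true_units.append(
                        {
                            "unit_id": up.unit_id,
                            "cell_class": up.cell_class,
                            "omission_amplitude_hz": up.omission_amplitude_hz,
                        }
                    )
            spikes_path = out / f"spikes_{aid}.csv"
            units_path = out / f"units_{aid}.csv"
            _io.write_spikes(spikes_path, [rec for _, rec in unit_records])
            _io.write_unit_metadata(units_path, unit_meta)
            entry["files"]["spikes"] = spikes_path.name
            entry["files"]["units"] = units_path.name
            entry["true_units"] = true_units
        # photometry
        if config.include_photometry:
            traces = {
                "hab": simulate_photometry(params, hab_schedule, seeds[4]),
                "ext": simulate_photometry(params, ext_schedule, seeds[5]),
            }
            if config.include_reward:
                traces["reward"] = simulate_reward_photometry(
                    params, reward_pokes, reward_flags, reward_duration, seeds[6]
                )
            trace_path = out / f"traces_{aid}.h5"
            _io.write_traces(trace_path, traces)
            entry["files"]["traces"] = trace_path.name
        # behavior (extinction session)
        behavior = simulate_behavior(params, ext_schedule, seeds[7])
        freezing_path = out / f"freezing_{aid}.csv"
        _io.write_freezing(freezing_path, behavior.record)
        entry["files"]["freezing"] = freezing_path.name
        manifest["animals"].append(entry)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
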
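"""Readers and writers for the cohort's on-disk formats.

Delimited text for events, spikes, unit metadata, and freeze intervals;
an HDF5 container for fluorescence traces (one group per session, dataset
``F`` with attribute ``fs_hz``); JSON for the cohort manifest.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd

from .behavior_analysis import FreezingRecord
from .exceptions import IntegrityError
from .photometry_analysis import PhotometryTrace
from .session_model import SessionKind, SessionSchedule
from .spike_analysis import UnitRecord

__all__ = [
    "write_events", "read_schedules",
    "write_spikes", "read_spikes",
    "write_unit_metadata", "read_unit_metadata",
    "write_traces", "read_traces",
    "write_freezing", "read_freezing",
    "read_manifest", "read_reward_events",
]


def write_events(
    path,
    animal_id: str,
    sessions: Mapping[str, SessionSchedule],
    nosepoke_times: Optional[Sequence[float]] = None,
    rewarded_flags: Optional[Sequence[bool]] = None,
) -> None:
    """Event table: one row per event, columns session_id/event_type/time_s."""
    rows = []
    for name, schedule in sessions.items():
        sid = f"{animal_id}_{name}"
        for onset in schedule.cs_onsets_s:
            rows.append((sid, "cs_on", onset))
            rows.append((sid, "cs_off", onset + schedule.cs_duration_s))
        for t in schedule.us_times_s:
            rows.append((sid, "us", t))
    if nosepoke_times is not None:
        sid = f"{animal_id}_reward"
        for t, flag in zip(nosepoke_times, rewarded_flags):
            rows.append((sid, "nosepoke", t))
            if flag:
                rows.append((sid, "reward", t))
    pd.DataFrame(rows, columns=["session_id", "event_type", "time_s"]).to_csv(
        path, index=False
    )


def read_schedules(
    path, session_kinds: Mapping[str, str]
) -> Dict[str, SessionSchedule]:
    """Rebuild session schedules from an event table.

    ``session_kinds`` maps the session suffix (e.g. ``"ext"``) to its kind.
    """
    df = pd.read_csv(path)
    schedules: Dict[str, SessionSchedule] = {}
    for sid, sub in df.groupby("session_id"):
        name = sid.rsplit("_", 1)[-1]
        if name not in session_kinds:
            continue
        onsets = np.sort(sub.loc[sub["event_type"] == "cs_on", "time_s"].to_numpy())
        offsets = np.sort(sub.loc[sub["event_type"] == "cs_off", "time_s"].to_numpy())
        if len(onsets) != len(offsets):
            raise IntegrityError(f"{sid}: unmatched cs_on/cs_off events")
        if len(onsets) == 0:
            continue
        cs_dur = float(np.round(np.mean(offsets - onsets), 6))
        us = tuple(np.sort(sub.loc[sub["event_type"] == "us", "time_s"].to_numpy()))
        schedules[name] = SessionSchedule(
            cs_onsets_s=tuple(onsets),
            cs_duration_s=cs_dur,
            us_times_s=us,
            session_kind=SessionKind(session_kinds[name]),
            total_duration_s=float(offsets[-1] + 120.0),
        )
    return schedules


def read_reward_events(path) -> Tuple[np.ndarray, np.ndarray]:
    """Nosepoke times and reward flags from an animal's event table."""
    df = pd.read_csv(path)
    sub = df[df["session_id"].str.endswith("_reward")]
    pokes = np.sort(sub.loc[sub["event_type"] == "nosepoke", "time_s"].to_numpy())
    rewards = set(np.round(sub.loc[sub["event_type"] == "reward", "time_s"], 6))
    flags = np.array([round(t, 6) in rewards for t in pokes])
    return pokes, flags


def write_spikes(path, units: Iterable[UnitRecord]) -> None:
    """Spike list: columns unit_id, time_s."""
    frames = [
        pd.DataFrame({"unit_id": u.unit_id, "time_s": u.spike_times_s}) for u in units
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.5f")


def read_spikes(path) -> Dict[str, np.ndarray]:
    df = pd.read_csv(path)
    return {
        uid: np.sort(sub["time_s"].to_numpy())
        for uid, sub in df.groupby("unit_id")
    }


def write_unit_metadata(path, rows: Sequence[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def read_unit_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_traces(path, traces: Mapping[str, PhotometryTrace]) -> None:
    """One HDF5 group per session; dataset ``F`` (float32), attr ``fs_hz``."""
    with h5py.File(path, "w") as fh:
        for name, trace in traces.items():
            grp = fh.create_group(name)
            ds = grp.create_dataset("F", data=trace.samples.astype(np.float32))
            ds.attrs["fs_hz"] = trace.fs_hz
            grp.attrs["fluorophore"] = trace.fluorophore
            grp.attrs["animal_id"] = trace.animal_id


def read_traces(path) -> Dict[str, PhotometryTrace]:
    out: Dict[str, PhotometryTrace] = {}
    with h5py.File(path, "r") as fh:
        for name, grp in fh.items():
            ds = grp["F"]
            out[name] = PhotometryTrace(
                samples=ds[()].astype(float),
                fs_hz=float(ds.attrs["fs_hz"]),
                fluorophore=str(grp.attrs.get("fluorophore", "")),
                animal_id=str(grp.attrs.get("animal_id", "")),
            )
    return out


def write_freezing(path, record: FreezingRecord) -> None:
    pd.DataFrame(record.intervals, columns=["start_s", "stop_s"]).to_csv(
        path, index=False, float_format="%.4f"
    )


def read_freezing(path, animal_id: str, session_kind=SessionKind.EXTINCTION) -> FreezingRecord:
    df = pd.read_csv(path)
    return FreezingRecord(
        animal_id=animal_id,
        intervals=tuple(zip(df["start_s"], df["stop_s"])),
        session_kind=session_kind,
    )


def read_manifest(data_dir) -> dict:
    path = Path(data_dir) / "manifest.json"
    if not path.exists():
        raise IntegrityError(f"missing manifest: {path}")
    with open(path) as fh:
        return json.load(fh)
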
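"""End-to-end orchestration: simulate -> analyze -> report.

``run_pipeline`` chains the cohort generator and the three analysis stages
into a single seeded, logged workflow and assembles the report bundle: the
per-unit response table, the per-animal photometry and freezing tables, the
responder contingency tables with their exact tests, the population omission
t-tests, and the omission-signal / extinction-learning correlations.  A
fixed config and seed reproduce the bundle bit for bit (no timestamps are
embedded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _scipy_stats

from . import io as _io
from .behavior_analysis import apply_exclusion, extinction_metrics
from .exceptions import IntegrityError
from .session_model import Epoch
from .spike_analysis import UnitRecord, analyze_units, population_omission_test, compute_epoch_psth
from .stats_report import (
    TestResult,
    build_proportion_tables,
    omission_learning_correlation,
    paired_t,
)
from .photometry_analysis import epoch_window_dff, preprocess_trace, reward_dff, trial_dff
from .synthetic_cohort import CohortConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "ephys_stage", "photometry_stage",
           "behavior_stage", "report_stage"]

logger = logging.getLogger(__name__)

SESSION_KINDS = {"hab": "habituation", "ext": "extinction"}
SESSION_EPOCHS = {"hab": (Epoch.HAB,), "ext": (Epoch.E_EXT, Epoch.L_EXT)}


@dataclass
class PipelineConfig:
    """Everything needed to rerun the workflow deterministically."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    data_dir: str = "cohort_data"
    out_dir: str = "pipeline_out"
    simulate: bool = True
    sigma_convention: str = "psth_bins"
    filter_order: int = 4
    spearman_method: str = "auto"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        return cls(cohort=cohort, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _require(path: Path) -> Path:
    if not path.exists():
        raise IntegrityError(f"missing input file: {path}")
    return path


def ephys_stage(data_dir, sigma_convention: str = "psth_bins") -> pd.DataFrame:
    """Single-unit analysis over every unit in the cohort.

    Habituation-day units are analysed over the habituation epoch;
    extinction-day units over early and late extinction.
    """
    data_dir = Path(data_dir)
    manifest = _io.read_manifest(data_dir)
    triples = []
    for animal in manifest["animals"]:
        files = animal["files"]
        if "spikes" not in files:
            continue
        schedules = _io.read_schedules(
            _require(data_dir / files["events"]), SESSION_KINDS
        )
        spikes = _io.read_spikes(_require(data_dir / files["spikes"]))
        meta = _io.read_unit_metadata(_require(data_dir / files["units"]))
        missing = sorted(set(meta["unit_id"]) - set(spikes))
        if missing:
            raise IntegrityError(
                f"{animal['animal_id']}: units in metadata without spikes: {missing}"
            )
        for row in meta.itertuples():
            unit = UnitRecord(
                unit_id=row.unit_id,
                spike_times_s=spikes[row.unit_id],
                homecage_rate_hz=row.baseline_rate_hz,
                width_us=row.width_us,
            )
            triples.append((unit, schedules[row.session], SESSION_EPOCHS[row.session]))
    df = analyze_units(triples, baseline_sd=sigma_convention)
    n_invalid = int((~df["valid"]).sum()) if not df.empty else 0
    if n_invalid:
        logger.info("excluded %d unclassifiable unit-epochs (zero baseline SD)", n_invalid)
    return df


def photometry_stage(data_dir, filter_order: int = 4) -> pd.DataFrame:
    """Per-animal dF/F window statistics for every photometry animal."""
    data_dir = Path(data_dir)
    manifest = _io.read_manifest(data_dir)
    cs_dur = float(manifest.get("cs_duration_s", 10.0))
    rows = []
    for animal in manifest["animals"]:
        files = animal["files"]
        if "traces" not in files:
            continue
        aid = animal["animal_id"]
        schedules = _io.read_schedules(_require(data_dir / files["events"]), SESSION_KINDS)
        traces = _io.read_traces(_require(data_dir / files["traces"]))
        row: Dict[str, object] = {"animal_id": aid, "fluorophore": animal["fluorophore"]}
        epochs = {
            "hab": ("hab", slice(None)),
            "e_ext": ("ext", slice(0, 10)),
            "l_ext": ("ext", slice(-10, None)),
        }
        processed = {
            name: preprocess_trace(trace, order=filter_order)
            for name, trace in traces.items()
            if name in ("hab", "ext")
        }
        for epoch_name, (session, trial_slice) in epochs.items():
            schedule = schedules[session]
            onsets = schedule.cs_onsets_s[trial_slice]
            trials = [
                trial_dff(processed[session], onset, cs_dur, trial_index=i)
                for i, onset in enumerate(onsets)
            ]
            row[f"omission_dff_{epoch_name}"] = epoch_window_dff(trials, "omission_5s", cs_dur)
            row[f"cs_dff_{epoch_name}"] = epoch_window_dff(trials, "cs_full", cs_dur)
        if "reward" in traces:
            pokes, flags = _io.read_reward_events(data_dir / files["events"])
            reward10 = preprocess_trace(traces["reward"], order=filter_order)
            resp = reward_dff(reward10, pokes, flags)
            row["reward_dff"] = resp.rewarded_mean
            row["unrewarded_dff"] = resp.unrewarded_mean
            if resp.n_skipped:
                logger.info("%s: skipped %d edge nosepokes", aid, resp.n_skipped)
        rows.append(row)
    return pd.DataFrame(rows)


def behavior_stage(data_dir) -> pd.DataFrame:
    """Extinction freezing metrics and the weak-conditioning exclusion."""
    data_dir = Path(data_dir)
    manifest = _io.read_manifest(data_dir)
    rows = []
    for animal in manifest["animals"]:
        aid = animal["animal_id"]
        files = animal["files"]
        schedules = _io.read_schedules(_require(data_dir / files["events"]), SESSION_KINDS)
        record = _io.read_freezing(_require(data_dir / files["freezing"]), aid)
        metrics = extinction_metrics(record, schedules["ext"])
        status = apply_exclusion(metrics.first_cs_pct)
        if status == "exclude":
            logger.info("%s excluded: first-CS freezing %.1f%% < 50%%", aid, metrics.first_cs_pct)
        rows.append(
            {
                "animal_id": aid,
                "first_cs_pct": metrics.first_cs_pct,
                "e_ext_pct": metrics.e_ext_pct,
                "l_ext_pct": metrics.l_ext_pct,
                "change_pct": metrics.change_pct,
                "exclusion": status,
            }
        )
    return pd.DataFrame(rows)


def report_stage(
    unit_df: pd.DataFrame,
    photo_df: pd.DataFrame,
    behav_df: pd.DataFrame,
    spearman_method: str = "auto",
) -> dict:
    """Assemble proportion tables, population tests, and correlations."""
    report: dict = {}
    if not unit_df.empty:
        report["proportion_tables"] = build_proportion_tables(unit_df)
        population = {}
        for epoch in ("hab", "e_ext", "l_ext"):
            sub = unit_df[(unit_df["epoch"] == epoch) & (unit_df["cell_class"] == "putative_DA")]
            if len(sub) >= 2:
                population[epoch] = paired_t(
                    sub["omission_rate_hz"].to_numpy(), sub["psth_baseline_hz"].to_numpy()
                )
        report["population_omission_t"] = population
    if not photo_df.empty and not behav_df.empty:
        merged = photo_df.merge(behav_df, on="animal_id")
        gcamp = merged[(merged["fluorophore"] != "GFP") & (merged["exclusion"] == "include")]
        if len(gcamp) >= 3:
            report["correlations"] = omission_learning_correlation(
                gcamp["omission_dff_e_ext"].to_numpy(),
                gcamp["change_pct"].to_numpy(),
                reward_dff=gcamp["reward_dff"].to_numpy() if "reward_dff" in gcamp else None,
                method=spearman_method,
            )
        gfp = merged[merged["fluorophore"] == "GFP"]
        if len(gcamp) >= 1 and len(gfp) >= 1:
            mw = _scipy_stats.mannwhitneyu(
                gcamp["omission_dff_e_ext"], gfp["omission_dff_e_ext"],
                alternative="two-sided",
            )
            report["group_contrast_e_ext"] = TestResult(
                statistic=float(mw.statistic), p_two_sided=float(mw.pvalue),
                method="rank_sum", n=len(gcamp) + len(gfp),
            )
    return report


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and (obj != obj):
        return None  # NaN -> null for valid JSON
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and write the report bundle.

    Stages: (optional) cohort simulation, single-unit analysis, photometry
    analysis, freezing analysis, statistics report.  Tables are written as
    delimited text and the bundle as ``report.json`` under ``out_dir``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    data_dir = Path(config.data_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.simulate:
        logger.info("simulating cohort into %s (seed %d)", data_dir, config.cohort.master_seed)
        generate_cohort(config.cohort, data_dir)
    unit_df = ephys_stage(data_dir, config.sigma_convention)
    photo_df = photometry_stage(data_dir, config.filter_order)
    behav_df = behavior_stage(data_dir)
    report = report_stage(unit_df, photo_df, behav_df, config.spearman_method)
    bundle = {
        "provenance": {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.cohort.master_seed,
            "inputs": sorted(p.name for p in data_dir.glob("*") if p.is_file()),
        },
        "report": report,
    }
    unit_df.to_csv(out_dir / "unit_responses.csv", index=False)
    photo_df.to_csv(out_dir / "photometry_epochs.csv", index=False)
    behav_df.to_csv(out_dir / "freezing_metrics.csv", index=False)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(_jsonify(bundle), fh, indent=2, sort_keys=True)
    logger.info("report bundle written to %s", out_dir / "report.json")
    bundle["tables"] = {"units": unit_df, "photometry": photo_df, "behavior": behav_df}
    return bundle
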
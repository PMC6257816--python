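#!/usr/bin/env python
"""Statistics layer: proportion tests, population tests, correlations.

Loads the per-unit, per-animal, and freezing tables written by the earlier
steps, assembles the responder contingency tables with their two-sided
Fisher exact tests, the population paired t-tests of omission-bin firing
against baseline, and the Spearman correlation between the E-Ext omission
dF/F and the extinction magnitude (with the reward-response placement
control).  Also reprints the exact tests recomputed from the published
response counts.  Writes ``results/report.json``.
"""

import json
from pathlib import Path

import pandas as pd

from vta_omission.pipeline import _jsonify, report_stage
from vta_omission.stats_report import ContingencyTable, fisher_exact_2x2

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

PUBLISHED_COUNTS = {
    "DA omission-excited, E-Ext vs Hab": (10, 30, 1, 42),
    "non-DA omission-excited, E-Ext vs Hab": (1, 34, 1, 46),
    "DA CS-excited, E-Ext vs Hab": (2, 38, 3, 40),
    "DA CS-inhibited, E-Ext vs Hab": (3, 37, 0, 43),
}


def main() -> None:
    unit_df = pd.read_csv(RESULTS / "unit_responses.csv")
    photo_df = pd.read_csv(RESULTS / "photometry_epochs.csv")
    behav_df = pd.read_csv(RESULTS / "freezing_metrics.csv")
    report = report_stage(unit_df, photo_df, behav_df)

    print("exact tests recomputed from published counts:")
    for label, counts in PUBLISHED_COUNTS.items():
        p = fisher_exact_2x2(ContingencyTable(*counts)).p_two_sided
        print(f"  {label}: p = {p:.6g}")

    print("simulated-cohort proportion tests (omission excited, vs Hab):")
    for entry in report["proportion_tables"]:
        if entry["criterion"] == "omission" and entry["response"] == "excited":
            tab, test = entry["table"], entry["test"]
            print(f"  {entry['cell_class']:15s} {entry['epoch_pair']}: "
                  f"{tab.a}/{tab.a + tab.b} vs {tab.c}/{tab.c + tab.d}, "
                  f"p = {test.p_two_sided:.4g}")
    corr = report.get("correlations", {})
    if "omission" in corr:
        r = corr["omission"]
        print(f"omission dF/F vs extinction change: rho = {r.statistic:.3f}, "
              f"p = {r.p_two_sided:.4g} ({r.method}, n = {r.n})")
    if "reward_control" in corr:
        r = corr["reward_control"]
        print(f"reward dF/F control:                rho = {r.statistic:.3f}, "
              f"p = {r.p_two_sided:.4g}")

    with open(RESULTS / "report.json", "w") as fh:
        json.dump(_jsonify(report), fh, indent=2, sort_keys=True)
    print(f"full report -> {RESULTS / 'report.json'}")


if __name__ == "__main__":
    main()
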
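#!/usr/bin/env python
"""Freezing quantification over the simulated cohort.

Computes per-CS freezing from the interval logs, the E-Ext / L-Ext epoch
means and their difference (the extinction magnitude), and applies the
<50% first-CS conditioning exclusion.  Writes
``results/freezing_metrics.csv``.
"""

from pathlib import Path

from vta_omission.pipeline import behavior_stage

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "cohort"
OUT = ROOT / "results" / "freezing_metrics.csv"


def main() -> None:
    df = behavior_stage(DATA_DIR)
    OUT.parent.mkdir(exist_ok=True)
    df.to_csv(OUT, index=False)
    print(f"{len(df)} animals -> {OUT}")
    print(f"  mean E-Ext freezing: {df.e_ext_pct.mean():.1f}%")
    print(f"  mean L-Ext freezing: {df.l_ext_pct.mean():.1f}%")
    print(f"  mean extinction change: {df.change_pct.mean():.1f} points")
    excluded = df[df.exclusion == "exclude"]
    print(f"  excluded animals (<50% first CS): {len(excluded)}")


if __name__ == "__main__":
    main()
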
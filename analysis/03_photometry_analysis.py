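#!/usr/bin/env python
"""Photometry pipeline over the simulated cohort.

Low-pass filters each 2 kHz trace at 4 Hz, downsamples to 10 Hz, computes
trial dF/F against the 5 s pre-CS baseline, and averages the omission
(5 s after CS offset), CS, and reward windows per epoch.  Writes the
per-animal table to ``results/photometry_epochs.csv``.
"""

from pathlib import Path

from vta_omission.pipeline import photometry_stage

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "cohort"
OUT = ROOT / "results" / "photometry_epochs.csv"


def main() -> None:
    df = photometry_stage(DATA_DIR)
    OUT.parent.mkdir(exist_ok=True)
    df.to_csv(OUT, index=False)
    print(f"{len(df)} animals -> {OUT}")
    gcamp = df[df.fluorophore != "GFP"]
    gfp = df[df.fluorophore == "GFP"]
    for label, sub in (("gCaMP6", gcamp), ("GFP", gfp)):
        print(f"  {label}: omission dF/F  Hab {sub.omission_dff_hab.mean():+.4f}  "
              f"E-Ext {sub.omission_dff_e_ext.mean():+.4f}  "
              f"L-Ext {sub.omission_dff_l_ext.mean():+.4f}")


if __name__ == "__main__":
    main()
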
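#!/usr/bin/env python
"""Single-unit pipeline over the simulated cohort.

Classifies each unit as putative DA / non-DA from its home-cage rate and
spike width, builds the CS-aligned z-scored PSTHs per epoch, and labels
omission and CS responses.  Writes the per-unit table to
``results/unit_responses.csv`` and prints the epoch responder proportions.
"""

from pathlib import Path

from vta_omission.pipeline import ephys_stage

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "cohort"
OUT = ROOT / "results" / "unit_responses.csv"


def main() -> None:
    df = ephys_stage(DATA_DIR)
    OUT.parent.mkdir(exist_ok=True)
    df.to_csv(OUT, index=False)
    print(f"{len(df)} unit-epoch rows -> {OUT}")
    for cell_class in ("putative_DA", "putative_nonDA"):
        for epoch in ("hab", "e_ext", "l_ext"):
            sub = df[(df.cell_class == cell_class) & (df.epoch == epoch)
                     & (df.omission_label != "unclassifiable")]
            if sub.empty:
                continue
            n_exc = (sub.omission_label == "excited").sum()
            print(f"  {cell_class:15s} {epoch:6s}: omission-excited "
                  f"{n_exc}/{len(sub)} ({100 * n_exc / len(sub):.1f}%)")


if __name__ == "__main__":
    main()
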
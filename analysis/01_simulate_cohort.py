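#!/usr/bin/env python
"""Generate the default synthetic cohort.

Writes spike lists, unit metadata, event tables, 2 kHz photometry traces,
and freeze-interval logs for 10 indicator-expressing and 4 GFP-control
animals (8 units per animal per recording day, 25 extinction trials) under
``scratch/cohort`` — the bulky inputs every later step consumes.
"""

from pathlib import Path

from vta_omission.synthetic_cohort import CohortConfig, generate_cohort

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "cohort"
MASTER_SEED = 1


def main() -> None:
    config = CohortConfig(master_seed=MASTER_SEED)
    manifest = generate_cohort(config, DATA_DIR)
    n_units = sum(len(a.get("true_units", [])) for a in manifest["animals"])
    print(f"cohort written to {DATA_DIR}")
    print(f"  animals: {len(manifest['animals'])} "
          f"({config.n_animals} gCaMP6, {config.n_gfp} GFP)")
    print(f"  simulated units: {n_units}")
    print(f"  extinction trials per animal: {config.n_extinction_trials}")


if __name__ == "__main__":
    main()
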
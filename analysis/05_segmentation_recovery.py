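#!/usr/bin/env python
"""How reliably does segmentation recover a known four-phase profile?

Simulates the four-phase failure-rate profile (learning 0.35 x 30,
proficient 0.08 x 60, worsening 0.30 x 40, proficient 0.08 x 70) 200
times, classifies each replicate, and measures how often the full
learning / proficiency / worsening / proficiency structure is recovered
with change-point estimates within 15 attempts of the true changes.
A strong-contrast profile is included as a positive control.  Writes
results/segmentation_recovery.csv.
"""

from pathlib import Path

import pandas as pd

from cusumlearn import CusumParams, Phase
from cusumlearn.simulate import simulate_segmentation_recovery

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 7

PROFILES = {
    "study_scale": (Phase(30, 0.35), Phase(60, 0.08), Phase(40, 0.30), Phase(70, 0.08)),
    "strong_contrast": (Phase(40, 0.60), Phase(120, 0.02), Phase(60, 0.50), Phase(120, 0.02)),
}


def main():
    design = CusumParams()
    rows = []
    for name, phases in PROFILES.items():
        res = simulate_segmentation_recovery(design, phases, n_reps=200, seed=SEED)
        rows.append({"profile": name,
                     "horizon": sum(p.n_attempts for p in phases),
                     **res.to_dict()})
        print(
            f"{name:16s}: four-interval structure in "
            f"{res.fraction_four_intervals:.3f}, recovered within +/-15 in "
            f"{res.fraction_recovered:.3f} of {res.n_reps} replicates"
        )
    print(
        "\nAt study scale the proficient stretches are too short for the "
        "2*H excursion to fire reliably (expected drift 60 x 0.065 = 3.9 "
        "< 5.42), so the four-interval structure emerges in only a "
        "minority of replicates; with longer, cleaner phases recovery is "
        "near-certain and change-point estimates are accurate."
    )
    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "segmentation_recovery.csv", index=False)
    print(f"wrote {OUT / 'segmentation_recovery.csv'}")


if __name__ == "__main__":
    main()
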
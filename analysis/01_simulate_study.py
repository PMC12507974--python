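"""Lay out the synthetic study and write a small on-disk demo dataset.

The default design emulates a three-session cTBS posture experiment:
28 subjects x 3 stimulation sessions (Sham / left DLPFC / right DLPFC,
order randomized per subject) x 15 trials (5 Silent, 5 Easy, 5 Hard;
Silent at positions 1, 2, 8, 14, 15; Easy/Hard as blocks).  Every trial
is a 90-s, 200-Hz CoP recording; Easy/Hard trials also carry a scored
n-back response.

Writes results/design_summary.csv and a 3-subject demo dataset (135
trial files in the pipeline's text layout) under scratch/demo_study/.
"""

from pathlib import Path

import pandas as pd

from swaylab.simulate import make_design, simulate_study

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

if __name__ == "__main__":
    design = make_design(n_subjects=28, seed=1)
    counts = (
        design.table.groupby(["stim", "condition"]).size().rename("n_trials").reset_index()
    )
    RESULTS.mkdir(exist_ok=True)
    counts.to_csv(RESULTS / "design_summary.csv", index=False)
    print(f"default design: {design.n_trials} trial slots "
          f"({design.n_subjects} subjects x 3 sessions x 15 trials)")
    print(counts.to_string(index=False))

    demo = simulate_study(seed=1, n_subjects=3)
    out = demo.to_directory(SCRATCH / "demo_study")
    n_files = len(list((out / "data").rglob("trial_*.csv")))
    print(f"\ndemo dataset: {n_files} CoP trial files, "
          f"{len(demo.responses)} scored n-back responses -> {out}")
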
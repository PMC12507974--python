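"""Regenerate the shipped Hurst -> alpha calibration table.

Run from the repository root:

    python scripts/build_calibration.py

Measures, for a grid of axis Hurst values, the mean DFA alpha and the
mean trial-average RS of a unit fBm axis pair under the pipeline's
default settings (18000 samples at 200 Hz, 800-sample trim, default DFA
windows), and writes the table to ``src/swaylab/data/calibration.json``.
"""

from pathlib import Path

import numpy as np

from swaylab.calibration import build_calibration_table, save_calibration

HURSTS = np.round(np.arange(0.10, 0.7001, 0.05), 2)
N_REPS = 150
SEED = 20260101

if __name__ == "__main__":
    table = build_calibration_table(HURSTS, n_reps=N_REPS, seed=SEED)
    out = Path(__file__).resolve().parents[1] / "src" / "swaylab" / "data"
    out.mkdir(parents=True, exist_ok=True)
    save_calibration(
        table,
        out / "calibration.json",
        meta={
            "n_reps": N_REPS,
            "seed": SEED,
            "n_samples": 18000,
            "trim_samples": 800,
            "dfa": "DFA-1, 20 log windows, 16..N/4",
        },
    )
    print(table.to_string(index=False))
    print(f"written to {out / 'calibration.json'}")
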
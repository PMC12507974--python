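"""Generator calibration: axis Hurst exponent -> realized RS-series alpha.

The synthetic CoP generator builds each axis as a fractional Brownian
motion path.  Radial sway is a nonlinear (norm) transform of the two
axes, so the DFA exponent of the RS series is not the fBm identity
``alpha = H + 1``; the mapping is measured once by Monte Carlo and
shipped as a small JSON table:

* ``alpha_rs``  — mean DFA alpha of the trimmed RS series of a unit
  fBm pair, per axis Hurst value;
* ``unit_mean_rs`` — mean trial-average RS of the same unit pair, used
  to scale axes so the expected trial mean RS hits a target.

Both are measured under the pipeline's own settings (18000 samples at
200 Hz, first 800 samples trimmed, default DFA windows), so targets
expressed on the alpha / mean-RS scale translate directly into an axis
Hurst and an amplitude scale via monotone interpolation.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from swaylab.dfa import DFAConfig, estimate_alpha
from swaylab.fractal import gen_fbm

__all__ = [
    "build_calibration_table",
    "load_calibration",
    "hurst_for_alpha",
    "unit_mean_rs",
]

_CALIBRATION_FILE = "calibration.json"


def build_calibration_table(
    hursts: np.ndarray | list[float],
    n_reps: int = 100,
    n_samples: int = 18000,
    trim_samples: int = 800,
    dfa_config: DFAConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Measure the Hurst -> (alpha_rs, unit_mean_rs) mapping by Monte Carlo.

    For each Hurst value, ``n_reps`` unit fBm axis pairs are drawn, the
    trimmed radial-sway series is formed, and its DFA alpha and trial
    mean are averaged.  Returns a tidy table with one row per Hurst.
    """
    dfa_config = dfa_config or DFAConfig()
    rows = []
    for j, h in enumerate(hursts):
        alphas = np.empty(n_reps)
        means = np.empty(n_reps)
        for r in range(n_reps):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(j, r))
            )
            x = gen_fbm(n_samples, float(h), rng)
            y = gen_fbm(n_samples, float(h), rng)
            rs = np.hypot(x, y)[trim_samples:]
            alphas[r] = estimate_alpha(rs, dfa_config).alpha
            means[r] = rs.mean()
        rows.append(
            {
                "hurst": float(h),
                "alpha_rs": float(alphas.mean()),
                "alpha_rs_sd": float(alphas.std(ddof=1)),
                "unit_mean_rs": float(means.mean()),
                "unit_mean_rs_cv": float(means.std(ddof=1) / means.mean()),
            }
        )
    return pd.DataFrame(rows)


def save_calibration(table: pd.DataFrame, path, meta: Mapping | None = None) -> None:
    payload = {"meta": dict(meta or {}), "table": table.to_dict(orient="list")}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_calibration(path=None) -> pd.DataFrame:
    """Load the shipped (or a user-supplied) calibration table."""
    if path is None:
        ref = resources.files("swaylab").joinpath("data", _CALIBRATION_FILE)
        payload = json.loads(ref.read_text())
    else:
        with open(path) as fh:
            payload = json.load(fh)
    table = pd.DataFrame(payload["table"])
    table.attrs["meta"] = payload.get("meta", {})
    return table


def hurst_for_alpha(alpha_target: float, table: pd.DataFrame) -> float:
    """Axis Hurst whose RS series realizes ``alpha_target``, by monotone
    interpolation; targets outside the measured range are clipped."""
    a = np.asarray(table["alpha_rs"], dtype=float)
    h = np.asarray(table["hurst"], dtype=float)
    if not np.all(np.diff(a) > 0):
        raise ValueError("calibration table alpha_rs is not strictly increasing")
    return float(np.interp(alpha_target, a, h))


def unit_mean_rs(hurst: float, table: pd.DataFrame) -> float:
    """Expected trial-mean RS of a unit fBm pair at ``hurst`` (interpolated
    on the log scale, since the constant grows geometrically in H)."""
    h = np.asarray(table["hurst"], dtype=float)
    c = np.log(np.asarray(table["unit_mean_rs"], dtype=float))
    return float(np.exp(np.interp(hurst, h, c)))
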
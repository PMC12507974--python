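"""Fit the mixed-effects models and build the contrast tables.

Reads results/metrics.csv and results/responses.csv (from
02_compute_sway_metrics.py) and fits, by REML:

* mean_rs, mean_rs_low, mean_rs_high, alpha
      ~ Stim + Condition + (1 + Trial | Subject)
* abs_error ~ Stim + Difficulty + (1 | Subject)

then derives all pairwise Tukey-adjusted contrasts of the
Stim x Condition cells per sway response.  Writes coefficients_*.csv
and contrasts_*.csv under results/models/.
"""

from pathlib import Path

import pandas as pd

from swaylab.models import build_report, fit_error_model, fit_lme, pairwise_contrasts

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

if __name__ == "__main__":
    metrics = pd.read_csv(RESULTS / "metrics.csv")
    responses = pd.read_csv(RESULTS / "responses.csv")

    fits, contrasts = {}, {}
    for response in ("mean_rs", "mean_rs_low", "mean_rs_high", "alpha"):
        fit = fit_lme(metrics, response=response)
        fits[response] = fit
        contrasts[response] = pairwise_contrasts(fit)
        flag = "" if fit.converged else "  [did not converge]"
        print(f"\n=== {response} ==={flag}")
        print(fit.params.round(4).to_string(index=False))
    fits["abs_error"] = fit_error_model(responses)
    print("\n=== abs_error ===")
    print(fits["abs_error"].params.round(4).to_string(index=False))

    written = build_report(fits, contrasts, RESULTS / "models")
    print(f"\n{len(written)} report files under {RESULTS / 'models'}")
    print("\nSham-cell Tukey contrasts for mean_rs:")
    t = contrasts["mean_rs"]
    print(t[t["contrast"].str.count("SHAM") == 2].round(4).to_string(index=False))
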
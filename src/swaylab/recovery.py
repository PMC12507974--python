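"""Parameter-recovery experiments: simulate a full study, analyze it with
the pipeline, and read back the fitted fixed effects.

These experiments close the loop between the generator and the analysis
stack: the generator injects known effects (stimulation and cognitive
load on trial-mean radial sway, on the DFA exponent, and on the
cognitive error score), the pipeline recovers them, and the averaged
estimates over several independent study replicates are compared with
the injected truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from swaylab.models import fit_error_model, fit_lme
from swaylab.pipeline import PipelineConfig, compute_metrics
from swaylab.simulate import EffectConfig, TemporalConfig, simulate_study

__all__ = ["recover_sway_models", "recover_error_model", "run_recovery"]


def _seed_list(seed: int, n_seeds: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n_seeds) % (2**31 - 1)]


def recover_sway_models(
    seed: int = 1,
    n_seeds: int = 5,
    n_subjects: int = 28,
    effects: EffectConfig | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Simulate ``n_seeds`` independent studies and fit the RS and alpha
    mixed models on each; returns one row per (replicate, response, term)."""
    effects = effects or EffectConfig()
    config = config or PipelineConfig(n_subjects=n_subjects)
    rows = []
    for rep_seed in _seed_list(seed, n_seeds):
        sim = simulate_study(
            effects=effects,
            temporal=TemporalConfig(fs=config.fs),
            seed=rep_seed,
            n_subjects=n_subjects,
        )
        metrics = compute_metrics(sim.iter_trials(), config)
        for response in ("mean_rs", "alpha"):
            fit = fit_lme(metrics, response=response)
            for _, prow in fit.params.iterrows():
                rows.append(
                    {
                        "replicate_seed": rep_seed,
                        "response": response,
                        "term": prow["term"],
                        "estimate": prow["estimate"],
                        "se": prow["se"],
                        "converged": fit.converged,
                        "n_trials": int(len(metrics)),
                        "n_used": int((~metrics["excluded"]).sum()),
                    }
                )
    return pd.DataFrame(rows)


def recover_error_model(
    seed: int = 1,
    n_seeds: int = 5,
    n_subjects: int = 28,
    effects: EffectConfig | None = None,
) -> pd.DataFrame:
    """Simulate the n-back responses of ``n_seeds`` studies and fit the
    error-score model on each (CoP trials are never materialized)."""
    effects = effects or EffectConfig()
    rows = []
    for rep_seed in _seed_list(seed, n_seeds):
        sim = simulate_study(effects=effects, seed=rep_seed, n_subjects=n_subjects)
        fit = fit_error_model(sim.responses)
        for _, prow in fit.params.iterrows():
            rows.append(
                {
                    "replicate_seed": rep_seed,
                    "response": "abs_error",
                    "term": prow["term"],
                    "estimate": prow["estimate"],
                    "se": prow["se"],
                    "converged": fit.converged,
                    "n_trials": int(len(sim.responses)),
                }
            )
    return pd.DataFrame(rows)


def summarize(recovery: pd.DataFrame) -> pd.DataFrame:
    """Mean estimate per (response, term) across replicates."""
    return (
        recovery.groupby(["response", "term"], as_index=False)
        .agg(
            mean_estimate=("estimate", "mean"),
            sd_estimate=("estimate", "std"),
            mean_se=("se", "mean"),
            n_reps=("estimate", "size"),
        )
        .sort_values(["response", "term"])
        .reset_index(drop=True)
    )


def run_recovery(
    seed: int = 1,
    n_seeds: int = 5,
    n_subjects: int = 28,
) -> dict[str, pd.DataFrame]:
    """Full recovery experiment (sway + error models), summarized."""
    sway = recover_sway_models(seed=seed, n_seeds=n_seeds, n_subjects=n_subjects)
    error = recover_error_model(seed=seed, n_seeds=n_seeds, n_subjects=n_subjects)
    both = pd.concat([sway, error], ignore_index=True)
    return {"per_replicate": both, "summary": summarize(both)}
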
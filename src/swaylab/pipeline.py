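"""Pipeline orchestration: simulate -> per-trial metrics -> models -> report.

The pipeline turns raw two-axis CoP trials into the tidy per-trial table
the mixed models consume.  Per trial:

1. band-split the full recording at the configured cutoff (the
   discarded onset serves as filter burn-in), then trim the onset from
   the raw and filtered axes;
2. radial sway per band; trial means ``mean_rs``, ``mean_rs_low``,
   ``mean_rs_high``;
3. DFA alpha of the trimmed, unfiltered RS series;
4. after all trials: flag ±k SD outliers per subject x condition.

``run_analyze`` then fits the four sway models and the cognitive error
model and writes coefficient and Tukey-contrast tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from swaylab import __version__
from swaylab.dfa import DFAConfig, EstimationError, estimate_alpha
from swaylab.io import read_cop_csv, write_metrics
from swaylab.models import ModelFit, ModelSpec, build_report, fit_error_model, fit_lme, pairwise_contrasts
from swaylab.simulate import EffectConfig, TemporalConfig, simulate_study
from swaylab.sway import (
    CoPTrial,
    band_split,
    band_split_series,
    exclude_outliers,
    mean_radial_sway,
    radial_sway,
    trim_onset,
)

__all__ = ["PipelineConfig", "compute_trial_metrics", "compute_metrics", "run_simulate", "run_analyze"]

log = logging.getLogger("swaylab")


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline knobs in one (JSON-serializable) place."""

    fs: float = 200.0
    trim_seconds: float = 4.0
    band_cutoff_hz: float = 0.3
    outlier_k: float = 2.0
    # exclusion cell: per session ("subject","stim","condition") by default;
    # ("subject","condition") pools a condition's trials across sessions
    outlier_groups: tuple = ("subject", "stim", "condition")
    band_order: str = "components"  # "components": filter axes then norm; "rs": filter RS
    centered_rs: bool = False
    dfa: DFAConfig = field(default_factory=DFAConfig)
    n_subjects: int = 28
    seed: int = 0
    fit_models: bool = True

    def __post_init__(self) -> None:
        if self.trim_seconds < 0 or self.band_cutoff_hz <= 0 or self.outlier_k <= 0:
            raise ValueError("thresholds must be positive")
        if self.band_order not in ("components", "rs"):
            raise ValueError("band_order must be 'components' or 'rs'")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        dfa_raw = raw.pop("dfa", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "outlier_groups" in raw:
            raw["outlier_groups"] = tuple(raw["outlier_groups"])
        return cls(**raw, dfa=DFAConfig(**dfa_raw))

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def compute_trial_metrics(trial: CoPTrial, config: PipelineConfig | None = None) -> dict:
    """Per-trial scalar metrics (one tidy row)."""
    config = config or PipelineConfig()
    warnings_out: list[str] = []
    low_full, high_full = band_split(trial, cutoff=config.band_cutoff_hz)
    trimmed = trim_onset(trial, config.trim_seconds)
    rs = radial_sway(trimmed.x, trimmed.y, fs=trial.fs, centered=config.centered_rs)
    if config.band_order == "components":
        low, high = trim_onset(low_full, config.trim_seconds), trim_onset(
            high_full, config.trim_seconds
        )
        rs_low = radial_sway(low.x, low.y, fs=trial.fs, centered=config.centered_rs)
        rs_high = radial_sway(high.x, high.y, fs=trial.fs, centered=config.centered_rs)
    else:  # filter the RS series itself
        rs_full = radial_sway(trial.x, trial.y, fs=trial.fs, centered=config.centered_rs)
        lo, hi = band_split_series(rs_full, cutoff=config.band_cutoff_hz)
        n_drop = int(round(config.trim_seconds * trial.fs))
        rs_low = type(lo)(values=lo.values[n_drop:], fs=lo.fs, band="low")
        rs_high = type(hi)(values=hi.values[n_drop:], fs=hi.fs, band="high")
    try:
        alpha = estimate_alpha(rs.values, config.dfa).alpha
    except EstimationError as exc:
        warnings_out.append(f"DFA failed: {exc}")
        alpha = float("nan")
    row = {
        "subject": trial.subject,
        "stim": trial.session,
        "condition": trial.condition,
        "trial": trial.trial_index,
        "mean_rs": mean_radial_sway(rs),
        "mean_rs_low": mean_radial_sway(rs_low),
        "mean_rs_high": mean_radial_sway(rs_high),
        "alpha": alpha,
    }
    if warnings_out:
        row["warnings"] = "; ".join(warnings_out)
    return row


def compute_metrics(
    trials: Iterable[CoPTrial], config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Metrics for a stream of trials, with the outlier flag applied."""
    config = config or PipelineConfig()
    rows = [compute_trial_metrics(t, config) for t in trials]
    table = pd.DataFrame(rows)
    return exclude_outliers(
        table, k=config.outlier_k, group_cols=tuple(config.outlier_groups)
    )


def run_simulate(config: PipelineConfig, outdir: str | Path) -> Path:
    """Generate a synthetic study and write it to ``outdir``."""
    sim = simulate_study(
        effects=EffectConfig(),
        temporal=TemporalConfig(fs=config.fs),
        seed=config.seed,
        n_subjects=config.n_subjects,
    )
    root = sim.to_directory(outdir)
    config.to_json(root / "pipeline_config.json")
    log.info("wrote %d trials under %s", sim.design.n_trials, root)
    return root


def _iter_dataset(root: Path) -> Iterable[CoPTrial]:
    files = sorted((root / "data").rglob("trial_*.csv"))
    if not files:
        raise FileNotFoundError(f"no trial files under {root / 'data'}")
    for f in files:
        yield read_cop_csv(f)


def run_analyze(
    config: PipelineConfig,
    dataset: str | Path,
    outdir: str | Path | None = None,
) -> dict:
    """Analyze an on-disk dataset: metrics, models, contrast tables.

    Returns a dict with the metrics table, fitted models and contrast
    tables; writes CSV outputs (plus a JSON run log) when ``outdir``
    is given.  Set ``config.fit_models = False`` for metrics only.
    """
    root = Path(dataset)
    metrics = compute_metrics(_iter_dataset(root), config)
    out: dict = {"metrics": metrics}
    run_log: dict = {
        "swaylab_version": __version__,
        "seed": config.seed,
        "n_trials": int(len(metrics)),
        "n_excluded": int(metrics["excluded"].sum()),
        "warnings": metrics["warnings"].dropna().tolist()
        if "warnings" in metrics.columns
        else [],
    }
    if config.fit_models:
        fits: dict[str, ModelFit] = {}
        contrasts: dict[str, pd.DataFrame] = {}
        for response in ("mean_rs", "mean_rs_low", "mean_rs_high", "alpha"):
            fit = fit_lme(metrics, response=response)
            fits[response] = fit
            contrasts[response] = pairwise_contrasts(fit)
            if not fit.converged:
                run_log["warnings"].append(f"{response}: fit did not converge")
        resp_path = root / "responses.csv"
        if resp_path.exists():
            responses = pd.read_csv(resp_path)
            fits["abs_error"] = fit_error_model(responses)
            if not fits["abs_error"].converged:
                run_log["warnings"].append("abs_error: fit did not converge")
        out["fits"] = fits
        out["contrasts"] = contrasts
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_metrics(metrics, outdir / "metrics.csv")
        if config.fit_models:
            build_report(out["fits"], out.get("contrasts", {}), outdir)
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(run_log, fh, indent=1)
    out["run_log"] = run_log
    return out
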
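"""Synthetic dual-task posture study generator.

Emulates the study design the analysis pipeline expects: 28 subjects,
each completing three stimulation sessions (Sham, LDLPFC, RDLPFC cTBS,
order randomized per subject) of 15 trials — five per cognitive
condition, with the no-task (Silent) trials placed two at the start, one
in the middle and two at the end, and blocked Easy / Hard sets filling
the remaining slots.  Every trial is a 90-s, 200-Hz two-axis CoP
recording; every Easy/Hard trial additionally carries a scored n-back
response.

Effects are injected additively on the linear scale, mirroring the
linear mixed model used for analysis:

    target = intercept + stim effect + condition effect
             + subject intercept + subject slope * trial index + noise

* Trial mean RS is controlled by scaling a pair of fractional Brownian
  axis paths so the expected trimmed-trial mean RS equals the linear
  predictor; the scale constant comes from the Monte-Carlo calibration
  table (per-trial renormalization would destroy sampling variance).
* The RS-series DFA alpha is controlled by choosing the axis Hurst from
  the same calibration table (the norm is nonlinear, so the fBm identity
  alpha = H + 1 does not apply to RS).
* Cognitive error counts are Poisson draws whose mean is the error-model
  linear predictor (floored at 0.05).

Default fixed-effect values are the package's reference configuration
for a plausible cTBS dual-task experiment (baseline sway ~4.9 mm,
stimulation effects ~0.4-0.6 mm, cognitive-load effects up to ~1.6 mm;
baseline alpha 1.36 with small negative load effects; baseline error
~2 with stimulation and difficulty penalties).  Variance components are
free parameters chosen so a full-design fit lands near plausible
standard errors; they are not implied by the fixed effects.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from swaylab import nback
from swaylab.calibration import hurst_for_alpha, load_calibration, unit_mean_rs
from swaylab.fractal import gen_fbm, gen_fgn
from swaylab.sway import CONDITIONS, SESSIONS, CoPTrial

__all__ = [
    "CTBSProtocol",
    "CTBS_DEFAULT",
    "ResponseEffects",
    "EffectConfig",
    "TemporalConfig",
    "StudyDesign",
    "StudySimulation",
    "make_design",
    "gen_cop_trial",
    "gen_error_counts",
    "simulate_study",
    "gen_fgn",
    "gen_fbm",
]

TRIALS_PER_SESSION = 15
SILENT_POSITIONS = (1, 2, 8, 14, 15)  # two at start, one mid, two at end


@dataclass(frozen=True)
class CTBSProtocol:
    """Continuous theta-burst stimulation descriptor: bursts of
    ``pulses_per_burst`` pulses at ``pulse_hz`` within a burst, bursts
    every ``burst_interval_s``, for ``duration_s`` seconds."""

    pulses_per_burst: int = 3
    pulse_hz: float = 50.0
    burst_interval_s: float = 0.2
    duration_s: float = 40.0

    @property
    def n_bursts(self) -> int:
        return int(round(self.duration_s / self.burst_interval_s))

    @property
    def total_pulses(self) -> int:
        return self.n_bursts * self.pulses_per_burst


#: 3-pulse 50-Hz bursts every 200 ms for 40 s -> 600 pulses.
CTBS_DEFAULT = CTBSProtocol()


@dataclass(frozen=True)
class ResponseEffects:
    """Additive linear-scale effect set for one response variable."""

    intercept: float
    rdlpfc: float = 0.0
    ldlpfc: float = 0.0
    easy: float = 0.0
    hard: float = 0.0
    subject_sd: float = 0.0
    slope_sd: float = 0.0
    resid_sd: float = 0.001

    def cell_mean(self, stim: str, condition: str) -> float:
        """Population linear predictor for a design cell."""
        mu = self.intercept
        mu += {"Sham": 0.0, "RDLPFC": self.rdlpfc, "LDLPFC": self.ldlpfc}[stim]
        mu += {"Silent": 0.0, "Easy": self.easy, "Hard": self.hard}[condition]
        return mu


@dataclass(frozen=True)
class EffectConfig:
    """Per-response effect sets driving the generator.

    ``rs``, ``alpha`` and ``error`` are targeted directly.  ``rs_low``
    and ``rs_high`` record the intended band-wise directions for
    reference; the generator does not target them individually — hitting
    four fitted sway models simultaneously would be overconstrained, so
    band-wise behaviour is checked at the level of signs only.
    """

    rs: ResponseEffects = field(
        default_factory=lambda: ResponseEffects(
            intercept=4.921, rdlpfc=0.433, ldlpfc=0.597, easy=0.385, hard=1.563,
            subject_sd=1.1, slope_sd=0.02, resid_sd=0.3,
        )
    )
    alpha: ResponseEffects = field(
        default_factory=lambda: ResponseEffects(
            intercept=1.36, rdlpfc=0.005, ldlpfc=-0.008, easy=-0.071, hard=-0.085,
            subject_sd=0.04, slope_sd=0.001, resid_sd=0.02,
        )
    )
    error: ResponseEffects = field(
        default_factory=lambda: ResponseEffects(
            intercept=1.95, rdlpfc=0.72, ldlpfc=1.57, easy=0.0, hard=1.77,
            subject_sd=1.0, slope_sd=0.0, resid_sd=0.0,
        )
    )
    # reference-only band directions (not individually targeted)
    rs_low: ResponseEffects = field(
        default_factory=lambda: ResponseEffects(
            intercept=4.787, rdlpfc=0.531, ldlpfc=0.606, easy=-0.763, hard=-0.536
        )
    )
    rs_high: ResponseEffects = field(
        default_factory=lambda: ResponseEffects(
            intercept=2.461, rdlpfc=0.414, ldlpfc=0.253, easy=0.175, hard=0.532
        )
    )


@dataclass(frozen=True)
class TemporalConfig:
    """Temporal-structure knobs for the CoP generator.

    ``hf_mix`` adds a white-noise (fast) component of the given relative
    amplitude to each axis before scaling; 0 keeps pure fractional paths
    so the DFA calibration applies exactly.  ``calibration`` is the
    Hurst -> (alpha_rs, unit_mean_rs) table.
    """

    fs: float = 200.0
    trial_seconds: float = 90.0
    trim_samples: int = 800
    hf_mix: float = 0.0
    calibration: pd.DataFrame | None = None

    def table(self) -> pd.DataFrame:
        return self.calibration if self.calibration is not None else _default_table()


_TABLE_CACHE: dict[str, pd.DataFrame] = {}


def _default_table() -> pd.DataFrame:
    if "t" not in _TABLE_CACHE:
        _TABLE_CACHE["t"] = load_calibration()
    return _TABLE_CACHE["t"]


@dataclass(frozen=True)
class StudyDesign:
    """Trial-slot layout: one row per (subject, session, trial)."""

    table: pd.DataFrame  # subject, day, stim, condition, trial
    n_subjects: int

    @property
    def n_trials(self) -> int:
        return len(self.table)


def make_design(n_subjects: int = 28, seed: int = 0) -> StudyDesign:
    """Randomized study layout.

    Each subject gets the three stimulation sessions in random order
    (one per day); within a session, Silent trials occupy positions
    1, 2, 8, 14 and 15, and the two five-trial blocks at positions 3-7
    and 9-13 are assigned to Easy and Hard in random order.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    rows = []
    for s in range(1, n_subjects + 1):
        subject = f"S{s:02d}"
        order = rng.permutation(SESSIONS)
        for day, stim in enumerate(order, start=1):
            blocks = rng.permutation(("Easy", "Hard"))
            cond_by_pos = {}
            for pos in SILENT_POSITIONS:
                cond_by_pos[pos] = "Silent"
            for pos in range(3, 8):
                cond_by_pos[pos] = blocks[0]
            for pos in range(9, 14):
                cond_by_pos[pos] = blocks[1]
            for trial in range(1, TRIALS_PER_SESSION + 1):
                rows.append(
                    {
                        "subject": subject,
                        "day": day,
                        "stim": str(stim),
                        "condition": cond_by_pos[trial],
                        "trial": trial,
                    }
                )
    return StudyDesign(table=pd.DataFrame(rows), n_subjects=n_subjects)


def gen_error_counts(
    stim: str,
    difficulty: str,
    subject_effect: float = 0.0,
    config: ResponseEffects | None = None,
    seed: int | np.random.Generator = 0,
    mean_floor: float = 0.05,
) -> int:
    """One Poisson-distributed absolute-error count for a task trial.

    The Poisson mean is the error-model linear predictor (intercept +
    stimulation effect + Hard effect + subject effect), floored at
    ``mean_floor`` so it stays a valid rate.
    """
    if difficulty not in ("Easy", "Hard"):
        raise ValueError(f"difficulty must be Easy or Hard, got {difficulty!r}")
    cfg = config or EffectConfig().error
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = max(cfg.cell_mean(stim, difficulty) + subject_effect, mean_floor)
    return int(rng.poisson(lam))


def gen_cop_trial(
    stim: str,
    condition: str,
    trial_index: int,
    subject: str = "S01",
    rs_target: float | None = None,
    alpha_target: float | None = None,
    temporal: TemporalConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> CoPTrial:
    """Generate one synthetic CoP trial.

    ``rs_target`` is the desired expected trimmed-trial mean RS (mm) and
    ``alpha_target`` the desired expected DFA alpha of the trimmed RS
    series; both default to the population cell means of the default
    :class:`EffectConfig`.  Axes are two independent fBm paths at the
    calibrated Hurst, scaled by ``rs_target / unit_mean_rs(H)``; a
    non-positive target is clipped to a small positive floor.
    """
    temporal = temporal or TemporalConfig()
    if stim not in SESSIONS or condition not in CONDITIONS:
        raise ValueError(f"invalid cell ({stim!r}, {condition!r})")
    defaults = EffectConfig()
    if rs_target is None:
        rs_target = defaults.rs.cell_mean(stim, condition)
    if alpha_target is None:
        alpha_target = defaults.alpha.cell_mean(stim, condition)
    rs_target = max(float(rs_target), 0.1)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    table = temporal.table()
    hurst = hurst_for_alpha(float(alpha_target), table)
    n = int(round(temporal.trial_seconds * temporal.fs))
    x = gen_fbm(n, hurst, rng)
    y = gen_fbm(n, hurst, rng)
    if temporal.hf_mix > 0:
        x = x + temporal.hf_mix * rng.standard_normal(n)
        y = y + temporal.hf_mix * rng.standard_normal(n)
    scale = rs_target / unit_mean_rs(hurst, table)
    return CoPTrial(
        subject=subject,
        session=stim,
        condition=condition,
        trial_index=trial_index,
        fs=temporal.fs,
        x=scale * x,
        y=scale * y,
    )


@dataclass
class StudySimulation:
    """A fully specified synthetic study.

    CoP trials are generated lazily (one 90-s trial is ~140 kB of
    floats; the full study would be ~360 MB) from per-trial seed
    sequences, so iterating twice reproduces identical trials.  The
    response table and subject effects are materialized eagerly.
    """

    design: StudyDesign
    effects: EffectConfig
    temporal: TemporalConfig
    seed: int
    subject_effects: pd.DataFrame
    responses: pd.DataFrame
    sequences: pd.DataFrame  # one presented letter stream per task trial

    @property
    def metadata(self) -> pd.DataFrame:
        meta = self.design.table.copy()
        resp = self.responses[
            ["subject", "stim", "trial", "expected", "reported"]
        ].rename(columns={"expected": "expected_count", "reported": "reported_count"})
        return meta.merge(resp, on=["subject", "stim", "trial"], how="left")

    def _trial_rng(self, row_index: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(10, row_index))
        )

    def trial_targets(self, row: pd.Series) -> tuple[float, float]:
        """Per-trial (mean-RS, alpha) targets: linear predictor plus
        subject intercept, subject slope x trial, and residual jitter."""
        eff = self.subject_effects
        srow = eff.loc[eff["subject"] == row["subject"]].iloc[0]
        jrng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(11, int(row.name)))
        )
        rs = (
            self.effects.rs.cell_mean(row["stim"], row["condition"])
            + srow["rs_intercept"]
            + srow["rs_slope"] * row["trial"]
            + jrng.normal(0.0, self.effects.rs.resid_sd)
        )
        al = (
            self.effects.alpha.cell_mean(row["stim"], row["condition"])
            + srow["alpha_intercept"]
            + srow["alpha_slope"] * row["trial"]
            + jrng.normal(0.0, self.effects.alpha.resid_sd)
        )
        return rs, al

    def iter_trials(self) -> Iterator[CoPTrial]:
        """Yield every CoP trial in design order (deterministic)."""
        for idx, row in self.design.table.iterrows():
            rs_t, al_t = self.trial_targets(row)
            yield gen_cop_trial(
                stim=row["stim"],
                condition=row["condition"],
                trial_index=int(row["trial"]),
                subject=row["subject"],
                rs_target=rs_t,
                alpha_target=al_t,
                temporal=self.temporal,
                seed=self._trial_rng(int(idx)),
            )

    def to_directory(self, path: str | Path) -> Path:
        """Write the study to disk in the pipeline's file layout:
        ``data/<subject>/<stim>/trial_NN.csv`` plus ``metadata.csv``,
        ``responses.csv``, ``sequences.txt`` and a config snapshot."""
        from swaylab.io import write_cop_csv  # local import; io imports sway only

        root = Path(path)
        root.mkdir(parents=True, exist_ok=True)
        for trial in self.iter_trials():
            d = root / "data" / trial.subject / trial.session
            d.mkdir(parents=True, exist_ok=True)
            write_cop_csv(trial, d / f"trial_{trial.trial_index:02d}.csv")
        self.metadata.to_csv(root / "metadata.csv", index=False)
        self.responses.to_csv(root / "responses.csv", index=False)
        with open(root / "sequences.txt", "w") as fh:
            for _, r in self.sequences.iterrows():
                fh.write(
                    f"{r['subject']},{r['stim']},{r['trial']}:{r['letters']}\n"
                )
        snapshot = {
            "seed": self.seed,
            "n_subjects": self.design.n_subjects,
            "effects": {
                name: dataclasses.asdict(getattr(self.effects, name))
                for name in ("rs", "alpha", "error", "rs_low", "rs_high")
            },
            "temporal": {
                "fs": self.temporal.fs,
                "trial_seconds": self.temporal.trial_seconds,
                "trim_samples": self.temporal.trim_samples,
                "hf_mix": self.temporal.hf_mix,
            },
        }
        with open(root / "config.json", "w") as fh:
            json.dump(snapshot, fh, indent=1)
        return root


def _draw_subject_effects(
    design: StudyDesign, effects: EffectConfig, seed: int
) -> pd.DataFrame:
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    subjects = sorted(design.table["subject"].unique())
    rows = []
    for subject in subjects:
        rows.append(
            {
                "subject": subject,
                "rs_intercept": rng.normal(0.0, effects.rs.subject_sd),
                "rs_slope": rng.normal(0.0, effects.rs.slope_sd),
                "alpha_intercept": rng.normal(0.0, effects.alpha.subject_sd),
                "alpha_slope": rng.normal(0.0, effects.alpha.slope_sd),
                "error_intercept": rng.normal(0.0, effects.error.subject_sd),
            }
        )
    return pd.DataFrame(rows)


def _make_responses(
    design: StudyDesign, effects: EffectConfig, subject_effects: pd.DataFrame, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every Easy/Hard trial: presented stream, expected count,
    Poisson error draw, and the implied self-report.  Silent trials get
    no response record (none existed in the protocol)."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    eff_by_subject = subject_effects.set_index("subject")["error_intercept"]
    resp_rows, seq_rows = [], []
    task = design.table[design.table["condition"] != "Silent"]
    for _, row in task.iterrows():
        difficulty = row["condition"]
        # plant a plausible ground-truth repeat count (1-5 per trial)
        target = int(rng.integers(1, 6))
        easy_t, hard_t = (target, 0) if difficulty == "Easy" else (0, target)
        seq = nback.generate_letter_stream(
            nback.LETTERS_PER_TRIAL, easy_t, hard_t, seed=rng
        )
        expected = (
            nback.count_easy_repeats(seq.letters)
            if difficulty == "Easy"
            else nback.count_hard_repeats(seq.letters)
        )
        err = gen_error_counts(
            row["stim"],
            difficulty,
            subject_effect=float(eff_by_subject[row["subject"]]),
            config=effects.error,
            seed=rng,
        )
        # place the miscount below the truth when possible, else above
        sign = -1 if (rng.random() < 0.5 and err <= expected) else 1
        reported = expected + sign * err
        if reported < 0:
            reported = expected + err
        resp_rows.append(
            {
                "subject": row["subject"],
                "day": row["day"],
                "stim": row["stim"],
                "condition": difficulty,
                "trial": row["trial"],
                "expected": expected,
                "reported": reported,
                "abs_error": abs(expected - reported),
            }
        )
        seq_rows.append(
            {
                "subject": row["subject"],
                "stim": row["stim"],
                "trial": row["trial"],
                "letters": seq.to_line(),
            }
        )
    return pd.DataFrame(resp_rows), pd.DataFrame(seq_rows)


def simulate_study(
    effects: EffectConfig | None = None,
    temporal: TemporalConfig | None = None,
    design: StudyDesign | None = None,
    seed: int = 0,
    n_subjects: int = 28,
) -> StudySimulation:
    """Assemble a full synthetic study (lazily generated CoP trials).

    All randomness flows from ``seed`` through named seed-sequence
    branches (design, subject effects, responses, per-trial paths), so
    two simulations with the same arguments are identical and any trial
    can be regenerated in isolation.
    """
    effects = effects or EffectConfig()
    temporal = temporal or TemporalConfig()
    design = design or make_design(n_subjects=n_subjects, seed=seed)
    subject_effects = _draw_subject_effects(design, effects, seed)
    responses, sequences = _make_responses(design, effects, subject_effects, seed)
    return StudySimulation(
        design=design,
        effects=effects,
        temporal=temporal,
        seed=seed,
        subject_effects=subject_effects,
        responses=responses,
        sequences=sequences,
    )
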
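"""Linear mixed-effects models and Tukey-adjusted pairwise contrasts.

The sway outcomes (trial-mean RS, band-wise RS, DFA alpha) are modelled
as

    response ~ Stim + Condition + (1 + Trial | Subject)

with treatment coding (Sham and Silent as reference levels), estimated
by REML.  The random intercept absorbs between-subject baseline
differences; the random slope on trial index absorbs per-subject
learning or fatigue trends.  The cognitive error score uses
``abs_error ~ Stim + Difficulty + (1 | Subject)`` (Easy as reference) —
a per-trial count has no meaningful within-trial slope.

Pairwise comparisons are built from estimated marginal means over the
Stim x Condition cells and adjusted with Tukey's studentized-range
method.  Denominator degrees of freedom use the residual approximation
(observations minus fixed-effect parameters); this is recorded in every
report header, as fancier approximations (Kenward-Roger, Satterthwaite)
shift p-values but not estimates or SEs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from swaylab.sway import CONDITIONS, SESSIONS

__all__ = [
    "ModelSpec",
    "ModelFit",
    "fit_lme",
    "fit_error_model",
    "pairwise_contrasts",
    "build_report",
]

DF_METHOD_NOTE = "df=residual (nobs - n_fixed); Tukey via studentized range"


@dataclass(frozen=True)
class ModelSpec:
    """Fixed/random structure of one mixed model."""

    response: str
    stim_col: str = "stim"
    cond_col: str = "condition"
    subject_col: str = "subject"
    trial_col: str = "trial"
    stim_levels: tuple[str, ...] = SESSIONS
    cond_levels: tuple[str, ...] = CONDITIONS
    random_slope: bool = True

    @property
    def formula(self) -> str:
        return (
            f"{self.response} ~ C({self.stim_col}, Treatment('{self.stim_levels[0]}'))"
            f" + C({self.cond_col}, Treatment('{self.cond_levels[0]}'))"
        )


@dataclass
class ModelFit:
    """A fitted mixed model with cleaned-up coefficient names."""

    spec: ModelSpec
    params: pd.DataFrame  # term, estimate, se, t, p
    variance_components: dict
    converged: bool
    method: str
    result: object = field(repr=False)  # statsmodels MixedLMResults
    cov_fe: np.ndarray = field(default=None, repr=False)  # GLS fixed-effect cov

    def coef(self, term: str) -> float:
        return float(self.params.set_index("term").loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.params.set_index("term").loc[term, "se"])


def _clean_term(name: str, spec: ModelSpec) -> str:
    if name == "Intercept":
        return "Intercept"
    if "[T." in name:
        return name.split("[T.")[1].rstrip("]")
    return name


def _sane(res) -> bool:
    """Reject degenerate optima (an optimizer can report convergence with a
    collapsed random-effect covariance and absurd fixed-effect SEs)."""
    with np.errstate(invalid="ignore"):
        bse = np.asarray(res.bse_fe, dtype=float)
    return bool(np.all(np.isfinite(bse)) and np.max(bse) < 1e4)


def _fit_mixedlm(model, reml: bool = True):
    """Fit with a ladder of optimizers, keeping the first sane optimum."""
    methods = (None, ["powell"], ["cg"], ["lbfgs"])
    last = None
    for meth in methods:
        with warnings.catch_warnings(), np.errstate(invalid="ignore", divide="ignore"):
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            try:
                if meth is None:
                    res = model.fit(reml=reml)
                    label = "default"
                else:
                    res = model.fit(reml=reml, method=meth, maxiter=2000)
                    label = "+".join(meth)
            except (np.linalg.LinAlgError, ValueError):
                continue
        if not _sane(res):
            continue
        last = (res, label)
        if res.converged:
            return res, label, True
    if last is None:
        raise RuntimeError("mixed model estimation failed for all optimizers")
    return last[0], last[1], False


def _fe_covariance(res) -> np.ndarray:
    """Conditional GLS covariance of the fixed effects, (X' V^-1 X)^-1
    at the estimated variance components.

    This is the convention mixed-model software reports (and what
    marginal-means contrasts assume); the joint-Hessian SEs some
    optimizers return additionally fold in variance-parameter
    uncertainty and can differ noticeably for the intercept.
    """
    model = res.model
    X = np.asarray(model.exog)
    groups = np.asarray(model.groups)
    Z = (
        np.asarray(model.exog_re)
        if getattr(model, "exog_re", None) is not None
        else np.ones((len(X), 1))
    )
    G = np.atleast_2d(np.asarray(res.cov_re))
    s2 = float(res.scale)
    k = X.shape[1]
    A = np.zeros((k, k))
    for g in pd.unique(groups):
        m = groups == g
        Xs, Zs = X[m], Z[m]
        V = Zs @ G @ Zs.T + s2 * np.eye(int(m.sum()))
        A += Xs.T @ np.linalg.solve(V, Xs)
    return np.linalg.inv(A)


def fit_lme(
    data: pd.DataFrame,
    response: str = "mean_rs",
    spec: ModelSpec | None = None,
    reml: bool = True,
) -> ModelFit:
    """Fit the sway mixed model on a tidy trial table.

    Excluded trials (``excluded == True``) are dropped if the column is
    present.  Non-convergence is flagged on the returned fit, never
    silently discarded.
    """
    spec = spec or ModelSpec(response=response)
    df = data.copy()
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    for col in (spec.response, spec.subject_col, spec.stim_col, spec.cond_col):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    if df[spec.subject_col].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    re_formula = f"~{spec.trial_col}" if spec.random_slope else "~1"
    model = smf.mixedlm(
        spec.formula, data=df, groups=df[spec.subject_col], re_formula=re_formula
    )
    res, method, converged = _fit_mixedlm(model, reml=reml)
    cov_fe = _fe_covariance(res)
    df_resid = float(res.nobs - len(res.fe_params))
    rows = []
    for i, name in enumerate(res.fe_params.index):
        est = float(res.fe_params[name])
        se = float(np.sqrt(cov_fe[i, i]))
        t = est / se if se > 0 else np.nan
        rows.append(
            {
                "term": _clean_term(name, spec),
                "estimate": est,
                "se": se,
                "t": t,
                "p": float(2 * stats.t.sf(abs(t), df_resid)),
            }
        )
    cov_re = np.asarray(res.cov_re)
    vc = {"residual_sd": float(np.sqrt(res.scale))}
    vc["subject_intercept_sd"] = float(np.sqrt(max(cov_re[0, 0], 0.0)))
    if cov_re.shape[0] > 1:
        vc["trial_slope_sd"] = float(np.sqrt(max(cov_re[1, 1], 0.0)))
        denom = np.sqrt(max(cov_re[0, 0], 1e-300) * max(cov_re[1, 1], 1e-300))
        vc["intercept_slope_corr"] = float(cov_re[0, 1] / denom)
    return ModelFit(
        spec=spec,
        params=pd.DataFrame(rows),
        variance_components=vc,
        converged=bool(converged),
        method=method,
        result=res,
        cov_fe=cov_fe,
    )


def fit_error_model(
    responses: pd.DataFrame,
    spec: ModelSpec | None = None,
    reml: bool = True,
) -> ModelFit:
    """Fit the cognitive error-score model.

    One row per scored task trial with ``abs_error``, stimulation and
    difficulty labels; random intercept per subject, Easy as the
    difficulty reference.
    """
    spec = spec or ModelSpec(
        response="abs_error",
        cond_levels=("Easy", "Hard"),
        random_slope=False,
    )
    return fit_lme(responses, response=spec.response, spec=spec, reml=reml)


def _cell_label(stim: str, condition: str) -> str:
    return f"{condition} {'SHAM' if stim == 'Sham' else stim}"


def pairwise_contrasts(
    fit: ModelFit,
    cells: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """All pairwise Tukey-adjusted comparisons of Stim x Condition cells.

    Estimated marginal means are the fixed-effect predictions per cell
    (random effects at zero); each difference is tested with the
    studentized-range distribution over the whole cell family, so the
    adjusted p controls the family-wise error rate.  A single-pair family
    reduces to the ordinary two-sided t-test.
    """
    spec = fit.spec
    res = fit.result
    if cells is None:
        cells = [(s, c) for s in spec.stim_levels for c in spec.cond_levels]
    design_info = res.model.data.design_info
    grid = pd.DataFrame(
        [{spec.stim_col: s, spec.cond_col: c} for s, c in cells]
    )
    try:
        X = np.asarray(patsy.dmatrix(design_info, grid))
    except patsy.PatsyError as exc:
        raise ValueError(f"cannot form cell design matrix: {exc}") from exc
    beta = np.asarray(res.fe_params)
    k_fe = beta.size
    cov = fit.cov_fe if fit.cov_fe is not None else np.asarray(res.cov_params())[:k_fe, :k_fe]
    emm = X @ beta
    n_cells = len(cells)
    df_resid = float(res.nobs - k_fe)
    rows = []
    for i, j in combinations(range(n_cells), 2):
        L = X[i] - X[j]
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        if se == 0.0:
            continue  # identical cells under the fitted structure
        t = est / se
        p_adj = float(
            stats.studentized_range.sf(np.sqrt(2.0) * abs(t), n_cells, df_resid)
        )
        rows.append(
            {
                "contrast": f"{_cell_label(*cells[i])} - {_cell_label(*cells[j])}",
                "estimate": est,
                "se": se,
                "df": df_resid,
                "t_ratio": t,
                "p_value": min(max(p_adj, 0.0), 1.0),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["emmeans"] = pd.DataFrame(
        {
            "cell": [_cell_label(*c) for c in cells],
            "emmean": emm,
        }
    )
    return out


def build_report(
    fits: Mapping[str, ModelFit],
    contrasts: Mapping[str, pd.DataFrame],
    outdir: str | Path,
) -> list[Path]:
    """Write per-response coefficient and contrast CSVs.

    Each file opens with a ``#`` header line recording the estimation
    method and df approximation; missing models are noted in
    ``report_notes.txt`` rather than silently skipped.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    notes: list[str] = []
    for name in sorted(set(fits) | set(contrasts)):
        if name in fits:
            fit = fits[name]
            path = outdir / f"coefficients_{name}.csv"
            with open(path, "w") as fh:
                fh.write(
                    f"# response={name}; method=REML({fit.method}); "
                    f"converged={fit.converged}; {DF_METHOD_NOTE}\n"
                )
                fit.params.to_csv(fh, index=False)
            written.append(path)
        else:
            notes.append(f"no fitted model for {name}")
        if name in contrasts:
            path = outdir / f"contrasts_{name}.csv"
            with open(path, "w") as fh:
                fh.write(f"# response={name}; {DF_METHOD_NOTE}\n")
                table = contrasts[name]
                if table.empty:
                    fh.write("contrast,estimate,se,df,t_ratio,p_value\n")
                else:
                    table.to_csv(fh, index=False)
            written.append(path)
        else:
            notes.append(f"no contrast table for {name}")
    if notes:
        note_path = outdir / "report_notes.txt"
        note_path.write_text("\n".join(notes) + "\n")
        written.append(note_path)
    return written
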
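"""Risk statistics: Kaplan-Meier curves, Cox hazard ratios, logistic odds
ratios, and the serial-ECG analysis with its label-leakage guard.

Aging-effect groups enter every model as a factor with "correct" (delta-age
within +/-8 years) as the reference category.  Cox models use the Breslow
partial likelihood for ties (Efron optional) with Wald 95 % intervals;
logistic models are maximum-likelihood fits with Wald intervals, optionally
stratified by sex (two independent fits omitting sex from the covariates).

The serial analysis fits three models: "baseline" (group and clock from the
first exam), "followup" (group and clock from the second exam), and "serial"
(the ordered pair of groups, reference pair ("correct", "correct"), clock
from the second exam).  Survival time accrued before the group-defining exam
is never credited — time at risk is anchored at that exam and asserted
non-negative per row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.api import Logit, add_constant
from statsmodels.duration.hazard_regression import PHReg

__all__ = [
    "EffectEstimate",
    "SurvivalCurve",
    "ModelFitError",
    "km_estimate",
    "cox_hr",
    "logistic_or",
    "serial_hr_analysis",
    "bh_adjust",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = [
    "age_at_exam",
    "is_female",
    "hypertension",
    "hyperlipidemia",
    "diabetes",
    "beta_blocker",
    "calcium_channel_blocker",
    "antiarrhythmic",
]

GROUP_ORDER = ("over", "under")  # non-reference factor levels, "correct" is reference


class ModelFitError(RuntimeError):
    """Raised when a regression fails (separation, non-convergence), with diagnostics."""


@dataclass
class EffectEstimate:
    term: str
    estimate: float  # HR or OR
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    model: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("confidence interval must bracket the point estimate")


@dataclass
class SurvivalCurve:
    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12) or np.any(np.diff(s) > 1e-12):
            raise ValueError("survival probabilities must be nonincreasing within [0, 1]")


def km_estimate(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> dict[str, SurvivalCurve]:
    """Product-limit survival estimate per group (ties multiply simultaneously)."""
    time = np.asarray(time, dtype=float)
    if np.any(time < 0):
        raise ValueError("survival times must be non-negative")
    event = np.asarray(event).astype(bool)
    group = np.asarray(group)
    out = {}
    for g in pd.unique(group):
        mask = group == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event_observed=event[mask], label=str(g))
        tbl = kmf.event_table
        out[str(g)] = SurvivalCurve(
            group=str(g),
            times=kmf.survival_function_.index.to_numpy(),
            survival=kmf.survival_function_.iloc[:, 0].to_numpy(),
            at_risk=tbl["at_risk"].to_numpy(),
        )
    return out


def _group_dummies(group: pd.Series, levels=GROUP_ORDER) -> pd.DataFrame:
    return pd.DataFrame(
        {f"group_{lvl}": (group == lvl).astype(float).to_numpy() for lvl in levels},
        index=group.index,
    )


def _wald(params, bse, names, n, model) -> list[EffectEstimate]:
    z = stats.norm.ppf(0.975)
    out = []
    for b, se, name in zip(params, bse, names):
        out.append(
            EffectEstimate(
                term=name,
                estimate=float(np.exp(b)),
                ci_low=float(np.exp(max(b - z * se, -700.0))),
                ci_high=float(np.exp(min(b + z * se, 700.0))),
                p_value=float(2 * stats.norm.sf(abs(b / se))),
                n=n,
                model=model,
            )
        )
    return out


def cox_hr(
    table: pd.DataFrame,
    duration_col: str = "time_at_risk",
    event_col: str = "died",
    group_col: str = "group",
    covariates: list[str] | None = None,
    ties: str = "breslow",
) -> list[EffectEstimate]:
    """Cox proportional-hazards HRs for the aging-effect groups vs "correct".

    Wald 95 % CIs and p-values on the exponentiated coefficients.  Breslow tie
    handling by default (``ties="efron"`` optional).  Non-convergence or a
    degenerate design raises :class:`ModelFitError` with diagnostics.
    """
    covariates = DEFAULT_COVARIATES if covariates is None else covariates
    df = table.dropna(subset=[duration_col, event_col, group_col] + covariates)
    dummies = _group_dummies(df[group_col])
    X = pd.concat([dummies, df[covariates]], axis=1)
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ModelFitError(f"constant columns in the Cox design: {const}")
    for lvl in GROUP_ORDER:
        if df.loc[df[group_col] == lvl, event_col].sum() < 1:
            raise ModelFitError(f"no events in group {lvl!r}")
    try:
        fit = PHReg(
            df[duration_col].to_numpy(),
            X.to_numpy(),
            status=df[event_col].to_numpy(),
            ties=ties,
        ).fit(disp=0)
    except Exception as exc:  # pragma: no cover - statsmodels raise paths vary
        raise ModelFitError(f"Cox fit failed: {exc!r}") from exc
    if not np.all(np.isfinite(fit.params)) or not np.all(np.isfinite(fit.bse)):
        raise ModelFitError("Cox fit did not converge to finite estimates")
    return _wald(fit.params, fit.bse, list(X.columns), len(df), model="cox")


def logistic_or(
    table: pd.DataFrame,
    outcome_col: str,
    group_col: str = "group",
    covariates: list[str] | None = None,
    stratify_by_sex: bool = False,
) -> list[EffectEstimate] | dict[str, list[EffectEstimate]]:
    """Logistic-regression ORs for the aging-effect groups vs "correct".

    With ``stratify_by_sex`` two independent fits are run (females, males)
    with sex dropped from the covariates.  Perfect separation or
    non-convergence raises :class:`ModelFitError`.
    """
    covariates = DEFAULT_COVARIATES if covariates is None else covariates
    if stratify_by_sex:
        cov = [c for c in covariates if c != "is_female"]
        return {
            label: logistic_or(
                table[table["is_female"] == flag], outcome_col, group_col, cov, False
            )
            for label, flag in (("female", 1), ("male", 0))
        }

    df = table.dropna(subset=[outcome_col, group_col] + covariates)
    y = df[outcome_col].astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome_col!r} must be binary")
    for lvl in GROUP_ORDER:
        sub = y[df[group_col] == lvl]
        if sub.size and (sub.sum() == 0 or sub.sum() == sub.size):
            raise ModelFitError(f"outcome is constant within group {lvl!r} (separation)")
    X = add_constant(pd.concat([_group_dummies(df[group_col]), df[covariates]], axis=1))
    try:
        fit = Logit(y.to_numpy(), X.to_numpy()).fit(disp=0, maxiter=200)
    except Exception as exc:
        raise ModelFitError(f"logistic fit failed: {exc!r}") from exc
    if not fit.mle_retvals.get("converged", True) or not np.all(np.isfinite(fit.bse)):
        raise ModelFitError("logistic fit did not converge (possible separation)")
    names = list(X.columns)
    keep = [i for i, name in enumerate(names) if name != "const"]
    return _wald(fit.params[keep], fit.bse[keep], [names[i] for i in keep], len(df),
                 model="logistic")


SERIAL_REFERENCE = "correct,correct"


def serial_hr_analysis(
    table: pd.DataFrame,
    group_col: str = "group",
    adjust: tuple[str, ...] = ("age_at_exam", "is_female"),
    ties: str = "breslow",
) -> pd.DataFrame:
    """Mortality HRs for baseline-only, follow-up-only, and serial-ECG models.

    ``table`` holds one row per attended exam with per-exam clocks
    (``time_at_risk`` = death-or-censor time minus the exam time) and a group
    assignment in ``group_col``.  Subjects without a follow-up exam (those who
    died or dropped out before it) are absent from the follow-up and serial
    models by construction.  Returns a tidy frame with one row per category
    (model, group, n, hr, ci_low, ci_high, p); the reference categories carry
    NaN estimates.  Categories with no members are omitted with a zero count
    recorded via the ``n`` column of the reference frame they would join.
    """
    exam0 = table[table["exam_index"] == 0].set_index("subject_id")
    exam1 = table[table["exam_index"] == 1].set_index("subject_id")

    rows: list[dict] = []

    def fit_groups(df: pd.DataFrame, model_name: str) -> None:
        assert (df["time_at_risk"] >= 0).all(), "time at risk must be anchored at the exam"
        X = pd.concat([_group_dummies(df[group_col]), df[list(adjust)]], axis=1)
        fit = PHReg(
            df["time_at_risk"].to_numpy(),
            X.to_numpy(),
            status=df["died"].to_numpy(),
            ties=ties,
        ).fit(disp=0)
        counts = df[group_col].value_counts()
        rows.append({"model": model_name, "group": "correct", "n": int(counts.get("correct", 0)),
                     "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan})
        for est in _wald(fit.params[:2], fit.bse[:2],
                         [f"{lvl}" for lvl in GROUP_ORDER], len(df), model_name):
            rows.append({"model": model_name, "group": est.term,
                         "n": int(counts.get(est.term, 0)), "hr": est.estimate,
                         "ci_low": est.ci_low, "ci_high": est.ci_high, "p": est.p_value})

    fit_groups(exam0.reset_index(), "baseline")
    fit_groups(exam1.reset_index(), "followup")

    # serial model: ordered pair categories, clock from the follow-up exam
    both = exam1.join(exam0[[group_col]], rsuffix="_baseline")
    pair = both[f"{group_col}_baseline"] + "," + both[group_col]
    df = both.assign(pair=pair).reset_index()
    assert (df["time_at_risk"] >= 0).all(), "serial time at risk must start at the follow-up exam"
    levels = [p for p in pair.value_counts().index if p != SERIAL_REFERENCE]
    X = pd.concat(
        [
            pd.DataFrame({f"pair_{lvl}": (df["pair"] == lvl).astype(float) for lvl in levels}),
            df[list(adjust)].reset_index(drop=True),
        ],
        axis=1,
    )
    fit = PHReg(df["time_at_risk"].to_numpy(), X.to_numpy(), status=df["died"].to_numpy(),
                ties=ties).fit(disp=0)
    counts = df["pair"].value_counts()
    rows.append({"model": "serial", "group": SERIAL_REFERENCE,
                 "n": int(counts.get(SERIAL_REFERENCE, 0)),
                 "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan})
    for est in _wald(fit.params[: len(levels)], fit.bse[: len(levels)], levels, len(df), "serial"):
        rows.append({"model": "serial", "group": est.term, "n": int(counts.get(est.term, 0)),
                     "hr": est.estimate, "ci_low": est.ci_low, "ci_high": est.ci_high,
                     "p": est.p_value})
    return pd.DataFrame(rows)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (helper; not applied by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * p.size / (np.arange(p.size) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(ranked, 0, 1)
    return out
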
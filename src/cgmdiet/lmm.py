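"""Linear mixed models predicting glycemic load and macronutrient intake.

Each model regresses a diet quantity (per-meal GL, or daily energy /
carbohydrate / sugar / fiber) on CGM metrics — plus, optionally, personal
characteristics — with a per-participant random intercept estimated by
restricted maximum likelihood:

    y_ij = beta0 + x_ij' beta + b_i + e_ij,   b_i ~ N(0, sigma_b^2)

A model is considered valid when its residuals pass a Shapiro-Wilk
normality check and a Levene homoscedasticity check (residuals grouped by
fitted-value tertiles), both at the 0.05 level. Out-of-cohort performance
is summarized by leave-one-participant-out cross-validation: the held-out
subject is predicted from fixed effects alone, since a new participant's
random intercept is unidentified.

The module also provides exact evaluators of two published fixed-effect
equations (a 2 h GL model from AUC/Amp/Var, and a daily energy model from
SD/MAGE plus personal characteristics) so external predictions can be
reproduced without refitting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

SEX_CODING = {"female": 0.0, "male": 1.0}

PERSONAL_COVARIATES = (
    "sex_code",
    "moderate_pa",
    "sedentary_pa",
    "age",
    "waist_circumference",
    "muscle_mass",
    "body_fat",
    "sleep_duration",
)

# Published fixed-effect equations (GL from 2 h postprandial metrics;
# daily energy from CGM variability plus personal characteristics).
GL2H_COEFFICIENTS = {"intercept": -23.0, "auc": 0.001, "amp": -3.56, "var": 16.7}
ENERGY_COEFFICIENTS = {
    "intercept": 162.3,
    "sex_code": 7.7,
    "moderate_pa": 410.0,
    "sedentary_pa": 97.2,
    "age": -12.7,
    "waist_circumference": -3.5,
    "muscle_mass": 30.1,
    "body_fat": -13.9,
    "sleep_duration": 0.008,
    "sd": 848.0,
    "mage": -21.1,
}


@dataclass(frozen=True)
class LMMSpec:
    """Specification of one mixed model (response, fixed effects, grouping)."""

    response: str
    fixed_effects: tuple[str, ...]
    group: str = "participant_id"
    window: float | None = None  # hours; None for daily models

    def __post_init__(self) -> None:
        fx = set(self.fixed_effects)
        if {"sd", "var"} <= fx:
            raise ValueError(
                "sd and var must not both be fixed effects: Var is a strictly "
                "monotone transform of SD (Spearman rho = 1), the design would "
                "be pathologically collinear"
            )


@dataclass
class LMMFit:
    """REML fit of a random-intercept model with validity diagnostics."""

    spec: LMMSpec
    coefficients: dict[str, dict[str, float]]  # name -> estimate / se / p_value
    random_intercept_variance: float
    residual_variance: float
    log_likelihood: float
    residuals: np.ndarray
    fitted: np.ndarray
    residual_normality_p: float
    homoscedasticity_p: float
    valid: bool
    n_obs: int
    n_groups: int

    @property
    def fe_params(self) -> np.ndarray:
        return np.array(
            [self.coefficients["intercept"]["estimate"]]
            + [self.coefficients[f]["estimate"] for f in self.spec.fixed_effects]
        )

    def predict_fixed(self, table: pd.DataFrame) -> np.ndarray:
        """Population-level prediction (random effect at its zero mean)."""
        X = np.column_stack(
            [np.ones(len(table))] + [table[f].to_numpy(float) for f in self.spec.fixed_effects]
        )
        return X @ self.fe_params


@dataclass(frozen=True)
class CVSummary:
    """Leave-one-participant-out MAE, summarized across folds."""

    mae_mean: float
    mae_std: float
    n_folds: int


def _model_frame(spec: LMMSpec, table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in (spec.response, *spec.fixed_effects, spec.group) if c not in table]
    if missing:
        raise ValueError(f"columns missing from analysis table: {missing}")
    cols = [spec.group, spec.response, *spec.fixed_effects]
    df = table[cols].copy()
    num = [spec.response, *spec.fixed_effects]
    df[num] = df[num].apply(pd.to_numeric)
    return df.dropna(subset=num)


def _check_design(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via near-zero diagonal of R in QR
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"singular design matrix; collinear columns: {bad or names}")


def fit_lmm(spec: LMMSpec, table: pd.DataFrame, min_groups: int = 2) -> LMMFit:
    """REML fit of ``response ~ 1 + fixed_effects + (1 | participant)``.

    Diagnostics: Shapiro-Wilk on the residuals and a Levene test on
    residuals grouped by fitted-value tertiles; ``valid`` requires both
    p >= 0.05 (normal residuals, no detected heteroscedasticity).
    """
    df = _model_frame(spec, table)
    if df[spec.group].nunique() < min_groups:
        raise ValueError(f"need >= {min_groups} participants, got {df[spec.group].nunique()}")
    y = df[spec.response].to_numpy(float)
    if np.all(y == y[0]):
        raise ValueError("response is constant; degenerate fit rejected")
    names = ["intercept", *spec.fixed_effects]
    X = np.column_stack([np.ones(len(df))] + [df[f].to_numpy(float) for f in spec.fixed_effects])
    _check_design(X, names)

    model = MixedLM(y, X, groups=df[spec.group].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        # boundary fits (zero random-intercept variance) warn via UserWarning
        warnings.simplefilter("ignore", UserWarning)
        result = model.fit(reml=True)
        fe = np.asarray(result.fe_params)
        se = np.asarray(result.bse_fe)
    with np.errstate(invalid="ignore", divide="ignore"):
        pvals = 2 * stats.norm.sf(np.abs(fe / se))
    coefficients = {
        name: {"estimate": float(fe[i]), "se": float(se[i]), "p_value": float(pvals[i])}
        for i, name in enumerate(names)
    }

    fitted = np.asarray(result.fittedvalues)
    resid = y - fitted
    _, sh_p = stats.shapiro(resid) if len(resid) >= 3 else (np.nan, np.nan)
    lev_p = _levene_by_fitted(resid, fitted)
    valid = bool(sh_p >= 0.05 and lev_p >= 0.05)

    return LMMFit(
        spec=spec,
        coefficients=coefficients,
        random_intercept_variance=float(np.asarray(result.cov_re)[0, 0]),
        residual_variance=float(result.scale),
        log_likelihood=float(result.llf),
        residuals=resid,
        fitted=fitted,
        residual_normality_p=float(sh_p),
        homoscedasticity_p=float(lev_p),
        valid=valid,
        n_obs=len(df),
        n_groups=int(df[spec.group].nunique()),
    )


def _levene_by_fitted(resid: np.ndarray, fitted: np.ndarray, n_bins: int = 3) -> float:
    """Levene test of residual spread across fitted-value tertile bins."""
    edges = np.quantile(fitted, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges[1:-1], fitted, side="right"), 0, n_bins - 1)
    groups = [resid[bins == b] for b in range(n_bins) if np.sum(bins == b) >= 2]
    if len(groups) < 2:
        return math.nan
    _, p = stats.levene(*groups)
    return float(p)


def loocv_mae(spec: LMMSpec, table: pd.DataFrame) -> CVSummary:
    """Leave-one-participant-out cross-validated mean absolute error.

    Each fold refits on the remaining participants and predicts the
    held-out subject from fixed effects only. Folds whose refit fails
    (singular design, too little data) are skipped with a warning.
    """
    df = _model_frame(spec, table)
    participants = sorted(df[spec.group].unique())
    if len(participants) < 3:
        raise ValueError("LOOCV needs at least 3 participants")
    maes = []
    for pid in participants:
        train = df[df[spec.group] != pid]
        test = df[df[spec.group] == pid]
        try:
            fit = fit_lmm(spec, train)
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"LOOCV fold {pid!r} skipped: {exc}")
            continue
        pred = fit.predict_fixed(test)
        maes.append(float(np.mean(np.abs(test[spec.response].to_numpy(float) - pred))))
    maes_arr = np.asarray(maes)
    return CVSummary(
        mae_mean=float(maes_arr.mean()),
        mae_std=float(maes_arr.std(ddof=1)) if maes_arr.size > 1 else math.nan,
        n_folds=int(maes_arr.size),
    )


# ---------------------------------------------------------------------------
# Published fixed-effect equation evaluators


def predict_published_gl2h(auc: float, amp: float, var: float) -> float:
    """Published 2 h GL equation, random effect at its zero mean.

    GL = -23.0 + 0.001*AUC - 3.56*Amp + 16.7*Var, with AUC in mmol*min/L,
    Amp in mmol/L, Var in (mmol/L)^2.
    """
    c = GL2H_COEFFICIENTS
    return c["intercept"] + c["auc"] * auc + c["amp"] * amp + c["var"] * var


def predict_published_energy(
    profile: "Mapping[str, float] | object",
    sd: float,
    mage: float,
    sex_coding: dict[str, float] | None = None,
) -> float:
    """Published daily energy (kCal) equation, random effect at zero.

    ``profile`` may be a ParticipantProfile or a mapping providing
    sex/moderate_pa/sedentary_pa/age/waist_circumference/muscle_mass/
    body_fat/sleep_duration. Sex coding defaults to female=0, male=1
    (configurable, as published equations rarely document it); PA and
    sleep enter in hours/day.
    """
    coding = SEX_CODING if sex_coding is None else sex_coding
    cov = _profile_covariates(profile, coding)
    c = ENERGY_COEFFICIENTS
    return (
        c["intercept"]
        + c["sex_code"] * cov["sex_code"]
        + c["moderate_pa"] * cov["moderate_pa"]
        + c["sedentary_pa"] * cov["sedentary_pa"]
        + c["age"] * cov["age"]
        + c["waist_circumference"] * cov["waist_circumference"]
        + c["muscle_mass"] * cov["muscle_mass"]
        + c["body_fat"] * cov["body_fat"]
        + c["sleep_duration"] * cov["sleep_duration"]
        + c["sd"] * sd
        + c["mage"] * mage
    )


def _profile_covariates(profile, coding: dict[str, float]) -> dict[str, float]:
    if hasattr(profile, "activity_hours"):  # ParticipantProfile
        return {
            "sex_code": coding[profile.sex],
            "moderate_pa": profile.activity_hours["moderate"],
            "sedentary_pa": profile.activity_hours["sedentary"],
            "age": profile.age,
            "waist_circumference": profile.waist_circumference,
            "muscle_mass": profile.muscle_mass,
            "body_fat": profile.body_fat,
            "sleep_duration": profile.sleep_duration,
        }
    needed = (
        "moderate_pa",
        "sedentary_pa",
        "age",
        "waist_circumference",
        "muscle_mass",
        "body_fat",
        "sleep_duration",
    )
    missing = [k for k in needed if k not in profile]
    if "sex_code" not in profile and "sex" not in profile:
        missing.append("sex")
    if missing:
        raise ValueError(f"missing covariates: {missing}")
    cov = {k: float(profile[k]) for k in needed}
    cov["sex_code"] = (
        float(profile["sex_code"]) if "sex_code" in profile else coding[profile["sex"]]
    )
    return cov


# ---------------------------------------------------------------------------
# The seven-model suite


@dataclass
class ModelReport:
    name: str
    spec: LMMSpec
    fit: LMMFit | None
    cv: CVSummary | None
    error: str | None = None


def model_suite(
    meal_table: pd.DataFrame,
    daily_table: pd.DataFrame,
    include_personal: bool = True,
    gl_windows: tuple[float, ...] = (2.0, 3.0, 4.0),
    run_cv: bool = True,
) -> list[ModelReport]:
    """Fit the study's seven mixed models and collect validity verdicts.

    Three GL models on the 2/3/4 h postprandial windows use the moderately
    GL-correlated metrics AUC, Amp and Var (SD is excluded because it is a
    monotone transform of Var); four daily models predict energy,
    carbohydrate, sugar and fiber from SD and MAGE, optionally with
    personal characteristics. Cross-validation is run for valid models.
    """
    personal = PERSONAL_COVARIATES if include_personal else ()
    reports: list[ModelReport] = []

    for w in gl_windows:
        spec = LMMSpec(response="gl", fixed_effects=("auc", "amp", "var"), window=float(w))
        sub = meal_table[meal_table["window_h"] == float(w)]
        reports.append(_run_model(f"gl_{w:g}h", spec, sub, run_cv))

    fixed = ("sd", "mage") + tuple(personal)
    for macro in ("energy", "carbohydrate", "sugar", "fiber"):
        spec = LMMSpec(response=macro, fixed_effects=fixed, window=None)
        reports.append(_run_model(f"{macro}_24h", spec, daily_table, run_cv))
    return reports


def _run_model(name: str, spec: LMMSpec, table: pd.DataFrame, run_cv: bool) -> ModelReport:
    try:
        fit = fit_lmm(spec, table)
    except (ValueError, np.linalg.LinAlgError) as exc:
        return ModelReport(name=name, spec=spec, fit=None, cv=None, error=str(exc))
    cv = None
    if run_cv and fit.valid:
        try:
            cv = loocv_mae(spec, table)
        except ValueError as exc:
            warnings.warn(f"CV for {name} skipped: {exc}")
    return ModelReport(name=name, spec=spec, fit=fit, cv=cv)


def suite_summary_frame(reports: list[ModelReport], p_threshold: float = 0.05) -> pd.DataFrame:
    """Per-model summary: validity, log-likelihood, important coefficients."""
    rows = []
    for rep in reports:
        if rep.fit is None:
            rows.append({"model": rep.name, "valid": False, "error": rep.error})
            continue
        important = {
            k: v
            for k, v in rep.fit.coefficients.items()
            if k != "intercept" and v["p_value"] < p_threshold
        }
        rows.append(
            {
                "model": rep.name,
                "valid": rep.fit.valid,
                "log_likelihood": rep.fit.log_likelihood,
                "residual_normality_p": rep.fit.residual_normality_p,
                "homoscedasticity_p": rep.fit.homoscedasticity_p,
                "important_coefficients": "; ".join(
                    f"{k}={v['estimate']:.4g} (p={v['p_value']:.3g}, se={v['se']:.3g})"
                    for k, v in important.items()
                ),
                "mae_mean": rep.cv.mae_mean if rep.cv else np.nan,
                "mae_std": rep.cv.mae_std if rep.cv else np.nan,
                "n_folds": rep.cv.n_folds if rep.cv else 0,
                "error": "",
            }
        )
    return pd.DataFrame(rows)
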
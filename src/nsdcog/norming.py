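"""Regression-based internal norms and the cognitive summary score (CSS).

Each of the six raw cognitive scores is regressed, within the robust
healthy-control reference, on age (years), sex (male indicator) and
education (years) by ordinary least squares. A participant's standardized
score is the residual relative to their demographic expectation divided by
the reference residual scale, and the CSS is the arithmetic mean of the six
z-scores — defined only when all six are available (hence participants with
a missing score or missing education are not evaluable).

By construction the reference group has per-test z means of zero and z
uncorrelated with the covariates, so the CSS measures displacement from
demographically matched healthy performance: more negative = worse.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import NormOptions
from .schema import COGNITIVE_TESTS, male_indicator

_COVARIATES = ("age", "male", "education_years")


class NormFitError(ValueError):
    """Raised when a norm regression cannot be fit."""


@dataclass
class NormModel:
    """OLS norm for one test: coefficients in raw-score units."""

    test: str
    intercept: float
    age_slope: float
    male_slope: float
    education_slope: float
    residual_scale: float
    n_reference: int

    def predict(self, age, male, education):
        """Demographically expected raw score."""
        return (
            self.intercept
            + self.age_slope * np.asarray(age, dtype=float)
            + self.male_slope * np.asarray(male, dtype=float)
            + self.education_slope * np.asarray(education, dtype=float)
        )


def _design(records: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": records["age"].astype("Float64").astype(float),
            "male": male_indicator(records["sex"]).astype(float),
            "education_years": records["education_years"]
            .astype("Float64")
            .astype(float),
        },
        index=records.index,
    )


def fit_norm_model(reference: pd.DataFrame, test: str,
                   options: NormOptions | None = None) -> NormModel:
    """Fit the norm regression for one test on the reference group.

    Rows missing the score or any covariate are dropped (complete-case).
    The residual scale defaults to the degrees-of-freedom-corrected RMSE,
    ``sqrt(SSR / (n - 4))``.
    """
    options = options or NormOptions()
    if test not in COGNITIVE_TESTS:
        raise NormFitError(f"unknown test {test!r}; expected one of {COGNITIVE_TESTS}")
    X = _design(reference)
    y = reference[test].astype("Float64").astype(float)
    complete = X.notna().all(axis=1) & y.notna()
    X, y = X.loc[complete], y.loc[complete]
    n = len(y)
    if n < options.min_reference_n:
        raise NormFitError(
            f"only {n} complete reference rows for {test}; "
            f"need at least {options.min_reference_n}"
        )
    for col in _COVARIATES:
        if np.ptp(X[col].to_numpy()) == 0:
            raise NormFitError(f"degenerate design: no variation in {col!r}")
    design = sm.add_constant(X.astype(float), has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise NormFitError("degenerate design: collinear covariates")
    fit = sm.OLS(y.astype(float), design).fit()
    dof = n - design.shape[1]
    ssr = float(np.sum(fit.resid**2))
    scale = np.sqrt(ssr / dof) if options.residual_scale == "rmse" else np.sqrt(ssr / n)
    return NormModel(
        test=test,
        intercept=float(fit.params["const"]),
        age_slope=float(fit.params["age"]),
        male_slope=float(fit.params["male"]),
        education_slope=float(fit.params["education_years"]),
        residual_scale=float(scale),
        n_reference=n,
    )


def fit_all_norms(reference: pd.DataFrame,
                  options: NormOptions | None = None) -> dict[str, NormModel]:
    """Fit all six norm regressions on the reference group."""
    return {t: fit_norm_model(reference, t, options) for t in COGNITIVE_TESTS}


def compute_z(records: pd.DataFrame, model: NormModel) -> pd.Series:
    """Standardized score: (observed − expected) / residual scale.

    Missing raw score, age, sex or education yields a missing z.
    """
    X = _design(records)
    y = records[model.test].astype("Float64").astype(float)
    pred = model.predict(X["age"], X["male"], X["education_years"])
    z = (y - pred) / model.residual_scale
    z[X.isna().any(axis=1) | y.isna()] = np.nan
    return z


def compute_css(zscores: pd.DataFrame) -> pd.DataFrame:
    """CSS = mean of the six z-scores; evaluable only when all six present.

    ``zscores`` must hold one column per test (``z_<test>`` or bare test
    names). Returns a frame with ``css`` and ``css_evaluable``.
    """
    cols = []
    for t in COGNITIVE_TESTS:
        if f"z_{t}" in zscores.columns:
            cols.append(f"z_{t}")
        elif t in zscores.columns:
            cols.append(t)
        else:
            raise KeyError(f"no z-score column for test {t!r}")
    z = zscores[cols].astype(float)
    evaluable = z.notna().all(axis=1)
    css = z.mean(axis=1)
    css[~evaluable] = np.nan
    return pd.DataFrame({"css": css, "css_evaluable": evaluable}, index=zscores.index)


def apply_norms(records: pd.DataFrame,
                models: dict[str, NormModel]) -> pd.DataFrame:
    """Score a cohort: adds ``z_<test>`` columns, ``css``, ``css_evaluable``."""
    out = records.copy()
    for test in COGNITIVE_TESTS:
        out[f"z_{test}"] = compute_z(records, models[test])
    css = compute_css(out[[f"z_{t}" for t in COGNITIVE_TESTS]])
    out["css"] = css["css"]
    out["css_evaluable"] = css["css_evaluable"]
    return out


def save_models(models: dict[str, NormModel], path) -> None:
    payload = {t: asdict(m) for t, m in models.items()}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def load_models(path) -> dict[str, NormModel]:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    return {t: NormModel(**kwargs) for t, kwargs in payload.items()}
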
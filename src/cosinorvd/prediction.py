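"""Predicting follow-up 25OHD from a single anchored baseline measurement.

All methods share the same anchoring construction: a seasonal-curve model
is fitted on the baseline cohort, the patient's curve is shifted so that
it passes through the observed baseline value, and the prediction at a
follow-up month is read off the shifted curve::

    predicted = baseline_value + curve(followup_month) - curve(baseline_month)

The methods differ only in the curve: a cosinor model (optionally with
covariate interactions giving patient-specific curves), a step function
over the four season quarters ("linear regression adjusted for season"),
or the degenerate flat curve (baseline value carried forward).  Accuracy
is compared by mean squared prediction error with paired t-tests on the
per-observation squared errors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import data_model
from .cosinor import CosinorFit, CosinorSpec, FitError, Z95, fit_cosinor, time_angle

log = logging.getLogger("cosinorvd")


class PredictionError(ValueError):
    """Prediction inputs are inconsistent with the fitted model."""


#: the default method battery
METHODS = (
    "cosinor_unadjusted",
    "cosinor_plus_age",
    "cosinor_multivariate",
    "baseline_carry",
    "season_dummy_regression",
)
#: covariates of the multivariate cosinor prediction model
MULTIVARIATE_COVARIATES = ("age_ge62", "female", "smoker", "supplements")


# ---------------------------------------------------------------------------
# per-method prediction rules


def _patient_sin_cos(fit: CosinorFit, covariates: Optional[Mapping]) -> tuple[float, float]:
    b = fit.params
    s, c = float(b["sin"]), float(b["cos"])
    for cov in fit.spec.interactions:
        if covariates is None or cov not in covariates:
            raise PredictionError(f"covariate {cov!r} required by the fit is absent")
        v = covariates[cov]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise PredictionError(f"covariate {cov!r} required by the fit is missing")
        for term in fit.term_map[cov]:
            x = (1.0 if term == f"{cov}_{v}" else 0.0) if isinstance(v, str) else float(v)
            s += x * float(b[f"{term}:sin"])
            c += x * float(b[f"{term}:cos"])
    return s, c


def predict_cosinor(
    fit: CosinorFit,
    baseline_value: float,
    baseline_month: int,
    followup_month: int,
    covariates: Optional[Mapping] = None,
) -> float:
    """Anchored cosinor prediction of a follow-up concentration.

    The height of the patient's curve is set by the observed baseline
    value; its shape comes from the fitted sine/cosine coefficients,
    modified by the patient's interaction covariates.  Level terms cancel
    in the within-patient difference, so only the seasonal component
    matters.
    """
    for m in (baseline_month, followup_month):
        if not 1 <= int(m) <= 12:
            raise PredictionError(f"month {m!r} out of range 1..12")
    s, c = _patient_sin_cos(fit, covariates)
    tb = time_angle(baseline_month, fit.spec.period)
    tf = time_angle(followup_month, fit.spec.period)
    curve_b = s * np.sin(tb) + c * np.cos(tb)
    curve_f = s * np.sin(tf) + c * np.cos(tf)
    return float(baseline_value + curve_f - curve_b)


def predict_baseline_carry(baseline_value: float) -> float:
    """Naive prediction: the follow-up equals the baseline measurement."""
    return float(baseline_value)


class SeasonDummyModel:
    """OLS of 25OHD on season-quarter dummies fitted to the baseline cohort.

    The fitted step function gives one mean level per quarter; anchored
    prediction offsets the baseline value by the difference between the
    follow-up-season and baseline-season fitted means.
    """

    def __init__(self, table: pd.DataFrame):
        df = table
        if "visit" in df:
            df = df[df["visit"] == "baseline"]
        df = df[df["usable"].astype(bool) & df["ohd"].notna()]
        if df.empty:
            raise FitError("no usable baseline rows for the season-dummy model")
        dummies = pd.get_dummies(
            pd.Categorical(df["season"], categories=data_model.SEASONS), dtype=float
        )
        X = sm.add_constant(dummies.iloc[:, 1:], has_constant="add")
        res = sm.OLS(df["ohd"].astype(float).to_numpy(), X).fit()
        self.n_used = int(res.nobs)
        means = {data_model.SEASONS[0]: res.params["const"]}
        for sname in data_model.SEASONS[1:]:
            means[sname] = res.params["const"] + res.params.get(sname, 0.0)
        self.season_means = {k: float(v) for k, v in means.items()}

    def predict(self, baseline_value: float, baseline_month: int, followup_month: int) -> float:
        sb = data_model.assign_calendar(baseline_month).season
        sf = data_model.assign_calendar(followup_month).season
        return float(baseline_value + self.season_means[sf] - self.season_means[sb])


def predict_season_dummy(
    table: pd.DataFrame, baseline_value: float, baseline_month: int, followup_month: int
) -> float:
    """Convenience wrapper: fit the season-dummy model and predict once."""
    return SeasonDummyModel(table).predict(baseline_value, baseline_month, followup_month)


# ---------------------------------------------------------------------------
# pairing and the method battery


def prediction_pairs(table: pd.DataFrame) -> pd.DataFrame:
    """Join each usable follow-up row to its patient's baseline row.

    Returns one row per follow-up observation with the baseline month and
    value, the follow-up month, the measured follow-up concentration and
    the patient's baseline covariates.
    """
    base = table[(table["visit"] == "baseline") & table["usable"].astype(bool)]
    fup = table[table["visit"].isin(("followup1", "followup2")) & table["usable"].astype(bool)]
    if fup.empty:
        raise PredictionError("no usable follow-up rows in the table")
    covcols = [c for c in table.columns
               if c not in ("visit", "month", "ohd", "ohd2", "ohd3", "usable",
                            "season", "period") and not c.startswith("_")]
    merged = fup[["patient_id", "visit", "month", "ohd"]].merge(
        base[covcols + ["month", "ohd"]],
        on="patient_id",
        suffixes=("", "_baseline"),
        how="inner",
    )
    return merged.rename(
        columns={
            "month": "followup_month",
            "ohd": "measured",
            "month_baseline": "baseline_month",
            "ohd_baseline": "baseline_value",
        }
    )


def _cosinor_predict_frame(fit: CosinorFit, pairs: pd.DataFrame) -> np.ndarray:
    """Vectorised anchored cosinor prediction; NaN where covariates are missing."""
    s = np.full(len(pairs), float(fit.params["sin"]))
    c = np.full(len(pairs), float(fit.params["cos"]))
    for cov in fit.spec.interactions:
        if cov not in pairs:
            raise PredictionError(f"covariate {cov!r} required by the fit is absent")
        col = pairs[cov]
        for term in fit.term_map[cov]:
            if col.dtype == object:
                level = term[len(cov) + 1:]
                x = np.where(col.isna(), np.nan, (col == level).astype(float))
            else:
                x = col.to_numpy(dtype=float)
            s = s + x * float(fit.params[f"{term}:sin"])
            c = c + x * float(fit.params[f"{term}:cos"])
    tb = time_angle(pairs["baseline_month"], fit.spec.period)
    tf = time_angle(pairs["followup_month"], fit.spec.period)
    offset = s * (np.sin(tf) - np.sin(tb)) + c * (np.cos(tf) - np.cos(tb))
    return pairs["baseline_value"].to_numpy(dtype=float) + offset


#: model specification behind each cosinor prediction method
_COSINOR_SPECS = {
    "cosinor_unadjusted": CosinorSpec(),
    "cosinor_plus_age": CosinorSpec(covariates=("age_ge62",), interactions=("age_ge62",)),
    "cosinor_multivariate": CosinorSpec(
        covariates=MULTIVARIATE_COVARIATES, interactions=MULTIVARIATE_COVARIATES
    ),
}


def predict_all(
    table: pd.DataFrame, methods: Sequence[str] = METHODS
) -> pd.DataFrame:
    """Predict every follow-up observation with every requested method.

    Models are fitted on the full baseline cohort.  Returns a long frame
    with one row per (observation, method), including the squared error;
    predictions are NaN when a required covariate is missing for that
    patient (complete-case per method).
    """
    pairs = prediction_pairs(table)
    season_model = (
        SeasonDummyModel(table) if "season_dummy_regression" in methods else None
    )
    frames = []
    for method in methods:
        if method in _COSINOR_SPECS:
            fit = fit_cosinor(table, _COSINOR_SPECS[method])
            predicted = _cosinor_predict_frame(fit, pairs)
        elif method == "baseline_carry":
            predicted = pairs["baseline_value"].to_numpy(dtype=float)
        elif method == "season_dummy_regression":
            means = season_model.season_means
            sb = pairs["baseline_month"].map(lambda m: means[data_model.assign_calendar(m).season])
            sf = pairs["followup_month"].map(lambda m: means[data_model.assign_calendar(m).season])
            predicted = pairs["baseline_value"].to_numpy(dtype=float) + (sf - sb).to_numpy()
        else:
            raise ValueError(f"unknown method {method!r}")
        out = pairs[["patient_id", "visit", "baseline_month", "followup_month",
                     "baseline_value", "measured"]].copy()
        out["method"] = method
        out["predicted"] = predicted
        out["squared_error"] = (out["predicted"] - out["measured"]) ** 2
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# method comparison


def _pearson_ci(r: float, n: int) -> tuple[float, float]:
    """Fisher z-transformed 95% CI for a Pearson correlation."""
    if n <= 3 or abs(r) >= 1:
        return (math.nan, math.nan)
    z = math.atanh(r)
    h = Z95 / math.sqrt(n - 3)
    return (math.tanh(z - h), math.tanh(z + h))


def evaluate_methods(
    predictions: pd.DataFrame, reference: str = "cosinor_unadjusted"
) -> pd.DataFrame:
    """Summarise predictive accuracy per method.

    Per method: Pearson correlation of predicted with measured (Fisher-z
    95% CI), MSE, RMSE, SD of the predicted values, the proportion of
    predictions within 10 nmol/l of the measured value, and a paired
    t-test p-value of the squared errors against the reference method
    (on the observations where both are defined).
    """
    key = ["patient_id", "visit"]
    methods = list(dict.fromkeys(predictions["method"]))
    if reference not in methods:
        raise PredictionError(f"reference method {reference!r} not among predictions")
    keysets = {
        m: set(map(tuple, predictions.loc[predictions["method"] == m, key].to_numpy()))
        for m in methods
    }
    if len({frozenset(k) for k in keysets.values()}) != 1:
        raise PredictionError("methods were evaluated on different observation sets")

    wide_pred = predictions.pivot_table(index=key, columns="method", values="predicted")
    wide_se = predictions.pivot_table(index=key, columns="method", values="squared_error")
    measured = predictions.drop_duplicates(subset=key).set_index(key)["measured"]
    measured = measured.loc[wide_pred.index]

    rows = []
    for m in methods:
        ok = wide_pred[m].notna()
        pred, meas = wide_pred.loc[ok, m], measured[ok]
        n = int(ok.sum())
        r = float(np.corrcoef(pred, meas)[0, 1]) if n > 2 else math.nan
        mse = float(wide_se.loc[ok, m].mean())
        if m == reference:
            p = math.nan
        else:
            both = ok & wide_se[reference].notna()
            d = wide_se.loc[both, m] - wide_se.loc[both, reference]
            if np.allclose(d, 0):
                p = 1.0
            else:
                p = float(stats.ttest_rel(wide_se.loc[both, m], wide_se.loc[both, reference]).pvalue)
        lo, hi = _pearson_ci(r, n)
        rows.append(
            {
                "method": m,
                "n": n,
                "pearson_r": r,
                "r_ci_low": lo,
                "r_ci_high": hi,
                "mse": mse,
                "rmse": math.sqrt(mse),
                "sd_pred": float(np.std(pred, ddof=1)),
                "prop_within_10": float((np.abs(pred - meas) < 10).mean()),
                "p_vs_reference": p,
            }
        )
    return pd.DataFrame(rows)
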
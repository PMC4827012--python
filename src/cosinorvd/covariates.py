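"""Covariate effects on annual mean and seasonal swing, with Wald tests.

Two kinds of contrast are computed per covariate level against its
reference:

* annual-mean difference — the level-shift coefficient of a cosinor model
  with the covariate (plus any adjustment covariates) as level shifts;
  including a level shift moves the fitted curve up or down without
  changing its shape;
* seasonal-variation (peak-trough) difference — from a model that adds
  covariate-by-sine and covariate-by-cosine interactions, the difference
  in 2*amplitude between the level and the reference, with a Delta-method
  standard error over the joint coefficient covariance.

Adjusted models add age group, gender, study site, BMI group and smoking
as level shifts only.  P-values are two-sided Wald tests; no multiplicity
correction is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cosinor import CosinorFit, CosinorSpec, FitError, Z95, delta_se, fit_cosinor

log = logging.getLogger("cosinorvd")

#: adjustment set of the adjusted models
DEFAULT_ADJUSTMENT = ("age_ge62", "female", "site", "bmi_group", "smoker")

#: covariates examined one at a time
DEFAULT_COVARIATES = (
    "female", "age_ge62", "site", "smoker", "bmi_group", "activity_ge2h",
    "egfr_le60", "crp_gt10", "supplements", "diabetes",
)


@dataclass
class GroupContrast:
    """One covariate-level-vs-reference contrast."""

    covariate: str
    level: str
    quantity: str  # annual_mean_diff | peak_trough_diff
    estimate: float
    se: float
    ci95: tuple
    p_value: float
    model: str  # unadjusted | adjusted
    n_used: int

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["ci95"] = [float(x) for x in self.ci95]
        return d


def _wald_p(z: float) -> float:
    return 2.0 * stats.norm.sf(abs(z))


def _contrast(covariate, term, quantity, est, se, model, n) -> GroupContrast:
    return GroupContrast(
        covariate=covariate,
        level=term,
        quantity=quantity,
        estimate=float(est),
        se=float(se),
        ci95=(est - Z95 * se, est + Z95 * se),
        p_value=_wald_p(est / se) if se > 0 else math.nan,
        model=model,
        n_used=n,
    )


def _adjust_for(covariate: str, adjust: Sequence[str]) -> tuple:
    return tuple(a for a in adjust if a != covariate)


def mean_contrast(
    table: pd.DataFrame,
    covariate: str,
    adjust: Sequence[str] = (),
) -> list[GroupContrast]:
    """Difference in annual mean 25OHD per level of ``covariate``.

    Fits a cosinor model with the covariate (and any adjustment
    covariates) entering as level shifts; the contrast is the level-shift
    coefficient itself, with its OLS standard error and Wald p-value.
    """
    adj = _adjust_for(covariate, adjust)
    spec = CosinorSpec(covariates=(covariate, *adj))
    fit = fit_cosinor(table, spec)
    model = "adjusted" if adj else "unadjusted"
    out = []
    for term in fit.term_map[covariate]:
        if term not in fit.params.index:
            log.warning("mean_contrast: level %s absent in complete cases", term)
            continue
        est = float(fit.params[term])
        se = float(np.sqrt(fit.vcov.loc[term, term]))
        out.append(_contrast(covariate, term, "annual_mean_diff", est, se, model, fit.n_used))
    return out


def amplitude_contrast(
    table: pd.DataFrame,
    covariate: str,
    adjust: Sequence[str] = (),
) -> list[GroupContrast]:
    """Difference in seasonal peak-trough variation per level of ``covariate``.

    Fits a cosinor model with covariate-by-sine and covariate-by-cosine
    interactions (adjustment covariates enter as level shifts only) and
    contrasts 2*amplitude at the level against 2*amplitude at the
    reference, with a Delta-method SE.
    """
    adj = _adjust_for(covariate, adjust)
    spec = CosinorSpec(covariates=(covariate, *adj), interactions=(covariate,))
    fit = fit_cosinor(table, spec)
    model = "adjusted" if adj else "unadjusted"
    b = fit.params
    s0, c0 = float(b["sin"]), float(b["cos"])
    out = []
    for term in fit.term_map[covariate]:
        s1 = s0 + float(b[f"{term}:sin"])
        c1 = c0 + float(b[f"{term}:cos"])
        est = 2.0 * (math.hypot(s1, c1) - math.hypot(s0, c0))
        at = {covariate: _level_of(covariate, term)}
        se = delta_se(fit, "amplitude_contrast", at=at, reference=None)
        out.append(_contrast(covariate, term, "peak_trough_diff", est, se, model, fit.n_used))
    return out


def _level_of(covariate: str, term: str):
    """Recover the setting value a design term represents."""
    if term == covariate:
        return 1.0
    return term[len(covariate) + 1:]


def joint_wald(fit: CosinorFit, terms: Sequence[str]) -> tuple[float, int, float]:
    """Joint Wald test that a coefficient subset is zero.

    ``W = theta' V^-1 theta`` compared to chi-square with df = len(terms).
    """
    theta = fit.params[list(terms)].to_numpy()
    V = fit.vcov.loc[list(terms), list(terms)].to_numpy()
    try:
        Vinv_theta = np.linalg.solve(V, theta)
    except np.linalg.LinAlgError as e:
        raise FitError(f"singular covariance submatrix for {list(terms)}") from e
    W = float(theta @ Vinv_theta)
    df = len(terms)
    return W, df, float(stats.chi2.sf(W, df))


def covariate_table(
    table: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    adjust: Sequence[str] = DEFAULT_ADJUSTMENT,
) -> pd.DataFrame:
    """Full contrast table: both quantities, unadjusted and adjusted models.

    One row per covariate level x quantity x model, with estimate, 95% CI,
    Wald p-value and the complete-case n of the fitted model.
    """
    rows = []
    for cov in covariates:
        for model_adj in ((), tuple(adjust)):
            for fn in (mean_contrast, amplitude_contrast):
                try:
                    contrasts = fn(table, cov, adjust=model_adj)
                except FitError as e:
                    log.warning("covariate_table: %s/%s skipped: %s", cov, fn.__name__, e)
                    continue
                rows.extend(c.to_dict() for c in contrasts)
    df = pd.DataFrame(rows)
    if not df.empty:
        df[["ci_low", "ci_high"]] = pd.DataFrame(df.pop("ci95").tolist(), index=df.index)
    return df
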
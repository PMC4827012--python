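"""Single-component cosinor regression with Delta-method inference.

The model regresses 25OHD onto ``sin(2*pi*m/12)`` and ``cos(2*pi*m/12)``
of the calendar month ``m``, optionally with covariate level shifts and
covariate-by-season interactions::

    y = b0 + b_s*sin(t) + b_c*cos(t) + sum_k g_k*x_k
        + sum_j x_j*(d_sj*sin(t) + d_cj*cos(t)) + e,      t = 2*pi*m/12

With ``s = b_s + sum active d_sj`` and ``c = b_c + sum active d_cj``, the
fitted seasonal curve at a covariate setting is ``A*cos(t - phi)`` with
amplitude ``A = sqrt(s^2 + c^2)`` and acrophase ``phi = atan2(s, c)``; the
peak month is ``phi`` rescaled to a continuous [0, 12) month axis.  The
MESOR (annual mean at that setting) is the intercept plus the active level
shifts.  Standard errors of amplitude, peak-trough and peak month are
first-order Delta-method propagations of the OLS coefficient covariance;
confidence intervals are Wald intervals with the normal 1.96 multiplier.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

TWO_PI = 2.0 * math.pi
Z95 = 1.959963984540054  # normal 0.975 quantile

#: reference level of each categorical covariate (first = reference)
CATEGORY_ORDERS = {
    "site": ["bergen", "stavanger"],
    "bmi_group": ["lt25", "25to30", "gt30"],
    "season": ["JanMar", "AprJun", "JulSep", "OctDec"],
}


class FitError(ValueError):
    """The design matrix cannot be fitted (empty or rank deficient)."""


@dataclass(frozen=True)
class CosinorSpec:
    """Model specification: which covariates shift the level and which
    additionally interact with the sine and cosine terms."""

    covariates: tuple = ()
    interactions: tuple = ()
    period: float = 12.0

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "interactions", tuple(self.interactions))


def time_angle(month, period: float = 12.0) -> np.ndarray:
    """Angular time ``t = 2*pi*m/period`` for calendar month(s) ``m``."""
    return TWO_PI * np.asarray(month, dtype=float) / period


def expand_covariate(values: pd.Series, name: str) -> list[tuple[str, np.ndarray]]:
    """Expand a covariate column into named 0/1 (or numeric) design terms.

    Categorical columns become one indicator per non-reference level,
    named ``<column>_<level>``; numeric/boolean columns pass through under
    their own name.
    """
    if values.dtype == object or isinstance(values.dtype, pd.CategoricalDtype):
        if name not in CATEGORY_ORDERS:
            levels = sorted(pd.unique(values.dropna()))
        else:
            levels = CATEGORY_ORDERS[name]
        observed = set(pd.unique(values.dropna()))
        unknown = observed - set(levels)
        if unknown:
            raise FitError(f"unknown levels {sorted(unknown)} in covariate {name!r}")
        return [
            (f"{name}_{lv}", (values == lv).to_numpy(dtype=float))
            for lv in levels[1:]
            if lv in observed
        ]
    return [(name, values.to_numpy(dtype=float))]


def build_design(
    table: pd.DataFrame,
    spec: CosinorSpec,
    baseline_only: bool = True,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Build the cosinor design matrix on the complete-case rows.

    Returns ``(X, y, term_map)`` where ``term_map`` maps each covariate
    name to its design term names (interaction columns are the term name
    suffixed with ``:sin`` / ``:cos``).
    """
    df = table
    mask = pd.Series(True, index=df.index)
    if baseline_only and "visit" in df:
        mask &= df["visit"] == "baseline"
    if "usable" in df:
        mask &= df["usable"].astype(bool)
    ycol = "ohd" if "ohd" in df else "ohd3"
    mask &= df[ycol].notna() & df["month"].notna()
    for cov in set(spec.covariates) | set(spec.interactions):
        if cov not in df:
            raise FitError(f"covariate column {cov!r} not in table")
        mask &= df[cov].notna()
    df = df.loc[mask]
    if df.empty:
        raise FitError("no complete-case rows to fit")

    t = time_angle(df["month"], spec.period)
    cols: dict[str, np.ndarray] = {
        "const": np.ones(len(df)),
        "sin": np.sin(t),
        "cos": np.cos(t),
    }
    term_map: dict[str, list[str]] = {}
    for cov in dict.fromkeys((*spec.covariates, *spec.interactions)):
        term_map[cov] = []
        for term, x in expand_covariate(df[cov], cov):
            term_map[cov].append(term)
            if cov in spec.covariates:
                cols[term] = x
    for cov in spec.interactions:
        for term, x in expand_covariate(df[cov], cov):
            cols[f"{term}:sin"] = x * cols["sin"]
            cols[f"{term}:cos"] = x * cols["cos"]
    X = pd.DataFrame(cols, index=df.index)
    y = df[ycol].astype(float)
    return X, y, term_map


@dataclass
class CosinorFit:
    """An OLS cosinor fit: coefficients, covariance and bookkeeping."""

    params: pd.Series
    vcov: pd.DataFrame
    n_used: int
    df_resid: float
    residuals: pd.Series
    sigma_hat: float
    spec: CosinorSpec
    term_map: dict = field(default_factory=dict)
    X: Optional[pd.DataFrame] = None
    y: Optional[pd.Series] = None

    @property
    def fitted(self) -> pd.Series:
        return self.y - self.residuals

    def interaction_terms(self) -> list[str]:
        return [t for cov in self.spec.interactions for t in self.term_map[cov]]

    def to_dict(self) -> dict:
        return {
            "spec": {
                "covariates": list(self.spec.covariates),
                "interactions": list(self.spec.interactions),
                "period": self.spec.period,
            },
            "n_used": int(self.n_used),
            "sigma_hat": float(self.sigma_hat),
            "params": {k: float(v) for k, v in self.params.items()},
            "vcov": {
                "names": list(self.vcov.columns),
                "matrix": self.vcov.to_numpy().tolist(),
            },
        }


def fit_cosinor(
    table: pd.DataFrame, spec: CosinorSpec = CosinorSpec(), baseline_only: bool = True
) -> CosinorFit:
    """Fit the cosinor regression by ordinary least squares.

    Uses the classical homoskedastic covariance ``sigma^2 (X'X)^-1``.
    Raises :class:`FitError` on an empty complete-case set, too few rows,
    or a rank-deficient design (naming the collinear columns).
    """
    X, y, term_map = build_design(table, spec, baseline_only=baseline_only)
    if len(X) <= X.shape[1]:
        raise FitError(f"n_used={len(X)} too small for {X.shape[1]} parameters")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X.to_numpy())
        bad = [X.columns[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-8]
        raise FitError(f"rank-deficient design; collinear columns: {bad}")
    res = sm.OLS(y, X).fit()
    return CosinorFit(
        params=res.params,
        vcov=res.cov_params(),
        n_used=int(res.nobs),
        df_resid=float(res.df_resid),
        residuals=res.resid,
        sigma_hat=float(np.sqrt(res.mse_resid)),
        spec=spec,
        term_map=term_map,
        X=X,
        y=y,
    )


# ---------------------------------------------------------------------------
# covariate settings -> active design values


def setting_values(fit: CosinorFit, at: Optional[Mapping] = None) -> dict[str, float]:
    """Resolve a covariate setting to per-term indicator values.

    ``at`` maps covariate names to a level (for categoricals) or a
    numeric/boolean value.  Unnamed covariates sit at their reference
    level (all indicators 0).
    """
    at = dict(at or {})
    values: dict[str, float] = {}
    for cov, terms in fit.term_map.items():
        v = at.pop(cov, None)
        for term in terms:
            if v is None:
                values[term] = 0.0
            elif isinstance(v, str):
                values[term] = 1.0 if term == f"{cov}_{v}" else 0.0
            else:
                values[term] = float(v)
    if at:
        raise KeyError(f"setting names not in the fitted model: {sorted(at)}")
    return values


def _sin_cos_at(fit: CosinorFit, values: Mapping[str, float]) -> tuple[float, float]:
    b = fit.params
    s = float(b["sin"])
    c = float(b["cos"])
    for term in fit.interaction_terms():
        x = values.get(term, 0.0)
        s += x * float(b[f"{term}:sin"])
        c += x * float(b[f"{term}:cos"])
    return s, c


def _grad(fit: CosinorFit, entries: Mapping[str, float]) -> np.ndarray:
    g = np.zeros(len(fit.params))
    pos = {name: i for i, name in enumerate(fit.params.index)}
    for name, v in entries.items():
        g[pos[name]] = v
    return g


def _amp_grad_entries(fit, values, s, c, scale=1.0) -> dict[str, float]:
    A = math.hypot(s, c)
    ent = {"sin": scale * s / A, "cos": scale * c / A}
    for term in fit.interaction_terms():
        x = values.get(term, 0.0)
        ent[f"{term}:sin"] = scale * x * s / A
        ent[f"{term}:cos"] = scale * x * c / A
    return ent


def delta_se(
    fit: CosinorFit,
    which: str,
    at: Optional[Mapping] = None,
    reference: Optional[Mapping] = None,
) -> float:
    """Delta-method standard error of a nonlinear function of the fit.

    ``which`` is one of ``amplitude``, ``peak_trough``, ``phase`` (peak
    month, in months) or ``amplitude_contrast`` (peak-trough at ``at``
    minus peak-trough at ``reference``).  ``SE = sqrt(g' V g)`` with ``g``
    the analytic gradient at the estimate.
    """
    V = fit.vcov.to_numpy()
    values = setting_values(fit, at)
    s, c = _sin_cos_at(fit, values)
    A = math.hypot(s, c)
    if which in ("amplitude", "peak_trough"):
        if A == 0:
            raise FitError("amplitude is 0; delta gradient undefined")
        scale = 1.0 if which == "amplitude" else 2.0
        g = _grad(fit, _amp_grad_entries(fit, values, s, c, scale))
    elif which == "phase":
        if A == 0:
            raise FitError("phase undefined at zero amplitude")
        months = fit.spec.period / TWO_PI
        ent = {"sin": months * c / A**2, "cos": months * -s / A**2}
        for term in fit.interaction_terms():
            x = values.get(term, 0.0)
            ent[f"{term}:sin"] = months * x * c / A**2
            ent[f"{term}:cos"] = months * x * -s / A**2
        g = _grad(fit, ent)
    elif which == "amplitude_contrast":
        ref_values = setting_values(fit, reference)
        s0, c0 = _sin_cos_at(fit, ref_values)
        if A == 0 or math.hypot(s0, c0) == 0:
            raise FitError("zero amplitude in contrast; gradient undefined")
        e1 = _amp_grad_entries(fit, values, s, c, 2.0)
        e0 = _amp_grad_entries(fit, ref_values, s0, c0, 2.0)
        g = _grad(fit, {k: e1.get(k, 0.0) - e0.get(k, 0.0) for k in set(e1) | set(e0)})
    else:
        raise ValueError(f"unknown function tag {which!r}")
    return float(np.sqrt(g @ V @ g))


# ---------------------------------------------------------------------------
# seasonal summary


@dataclass
class SeasonalSummary:
    """MESOR, amplitude, peak-trough and peak month with Wald inference."""

    mesor: float
    amplitude: float
    peak_trough: float
    peak_month: Optional[float]
    trough_month: Optional[float]
    se_mesor: float
    se_amplitude: Optional[float]
    se_peak_trough: Optional[float]
    se_peak_month: Optional[float]
    ci_mesor: tuple
    ci_amplitude: Optional[tuple]
    ci_peak_trough: Optional[tuple]
    ci_peak_month: Optional[tuple]
    n_used: int
    phase_defined: bool = True

    def to_dict(self) -> dict:
        def _num(v):
            if v is None:
                return None
            if isinstance(v, tuple):
                return [float(x) for x in v]
            return float(v)

        return {k: _num(v) for k, v in self.__dict__.items()
                if k not in ("n_used", "phase_defined")} | {
            "n_used": int(self.n_used), "phase_defined": bool(self.phase_defined)}


def seasonal_summary(fit: CosinorFit, at: Optional[Mapping] = None) -> SeasonalSummary:
    """Summarise the fitted seasonal curve at a covariate setting.

    The peak month is continuous on [0, 12) with month 1 = January; by
    symmetry the trough lies 6 months from the peak.  Peak-trough is
    exactly twice the amplitude.  When the amplitude is numerically zero
    the phase is flagged undefined and no phase/amplitude SE is reported.
    """
    values = setting_values(fit, at)
    b = fit.params
    mesor = float(b["const"])
    g_mesor = {"const": 1.0}
    for cov in fit.spec.covariates:
        for term in fit.term_map[cov]:
            x = values.get(term, 0.0)
            mesor += x * float(b[term])
            g_mesor[term] = x
    V = fit.vcov.to_numpy()
    se_mesor = float(np.sqrt(_grad(fit, g_mesor) @ V @ _grad(fit, g_mesor)))

    s, c = _sin_cos_at(fit, values)
    A = math.hypot(s, c)
    period = fit.spec.period
    degenerate = A < 1e-12
    if degenerate:
        peak = trough = None
        se_A = se_pt = se_peak = None
    else:
        peak = (math.atan2(s, c) * period / TWO_PI) % period
        trough = (peak + period / 2) % period
        se_A = delta_se(fit, "amplitude", at)
        se_pt = 2.0 * se_A
        se_peak = delta_se(fit, "phase", at)

    def ci(est, se):
        return None if se is None else (est - Z95 * se, est + Z95 * se)

    return SeasonalSummary(
        mesor=mesor,
        amplitude=A,
        peak_trough=2.0 * A,
        peak_month=peak,
        trough_month=trough,
        se_mesor=se_mesor,
        se_amplitude=se_A,
        se_peak_trough=se_pt,
        se_peak_month=se_peak,
        ci_mesor=ci(mesor, se_mesor),
        ci_amplitude=ci(A, se_A),
        ci_peak_trough=ci(2.0 * A, se_pt),
        ci_peak_month=ci(peak, se_peak) if peak is not None else None,
        n_used=fit.n_used,
        phase_defined=not degenerate,
    )


def curve_value(fit: CosinorFit, month, at: Optional[Mapping] = None) -> np.ndarray:
    """Seasonal component ``s*sin(t) + c*cos(t)`` at given month(s),
    excluding the MESOR and level shifts."""
    values = setting_values(fit, at)
    s, c = _sin_cos_at(fit, values)
    t = time_angle(month, fit.spec.period)
    return s * np.sin(t) + c * np.cos(t)


# ---------------------------------------------------------------------------
# curve arithmetic helpers


def amplitude_from_peak_trough(peak_trough: float) -> float:
    """Amplitude is half the total peak-to-trough seasonal variation."""
    return peak_trough / 2.0


def relative_seasonal_variation(peak_trough: float, annual_mean: float) -> float:
    """Peak-trough seasonal variation as a percentage of the annual mean."""
    return 100.0 * peak_trough / annual_mean


def required_peak_concentration(threshold: float, peak_trough: float) -> float:
    """Concentration needed at the seasonal peak so that the trough value,
    one half-period later, still meets the sufficiency threshold."""
    return threshold + peak_trough


def summary_report(fit: CosinorFit, at: Optional[Mapping] = None) -> str:
    """Plain-text report of a fit and its seasonal summary."""
    sm_ = seasonal_summary(fit, at)
    lines = [
        f"cosinor fit: n={fit.n_used}, sigma_hat={fit.sigma_hat:.2f} nmol/l",
        f"  annual mean (MESOR): {sm_.mesor:.1f}  (95% CI {sm_.ci_mesor[0]:.1f}, {sm_.ci_mesor[1]:.1f})",
        f"  amplitude:           {sm_.amplitude:.1f}  peak-trough: {sm_.peak_trough:.1f}",
    ]
    if sm_.phase_defined:
        lines.append(
            f"  peak month:          {sm_.peak_month:.1f}  trough month: {sm_.trough_month:.1f}"
        )
    else:
        lines.append("  phase: undefined (zero amplitude)")
    return "\n".join(lines)


def fit_to_json(fit: CosinorFit, at: Optional[Mapping] = None) -> str:
    """Machine-readable fit + seasonal summary."""
    return json.dumps(
        {"fit": fit.to_dict(), "seasonal_summary": seasonal_summary(fit, at).to_dict()},
        indent=2,
    )
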
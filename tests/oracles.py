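"""Independent oracles used by the test suite.

These deliberately avoid the package's fitting code: a brute-force SSE
minimiser in (MESOR, amplitude, phase) parameterisation, a grid-search
peak locator, a nonparametric bootstrap for the amplitude SE, and a
closed-form estimand for a cosinor fit on LLOQ-left-truncated Gaussian
mixtures (what the synthetic generator plus the LLOQ exclusion rule
actually produce).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import optimize, stats

from cosinorvd.synthetic import (
    CONTINUOUS_COVARIATES,
    DEFAULT_AMPLITUDE_EFFECTS,
    DEFAULT_COVARIATE_EFFECTS,
    DEFAULT_PREVALENCES,
)

TWO_PI = 2.0 * math.pi


def brute_force_cosinor(months, y, period=12.0):
    """Minimise SSE of y ~ M + A*cos(t - phi) by direct numeric search.

    Multi-start Nelder-Mead over (M, A, phi); returns fitted values.
    """
    months = np.asarray(months, dtype=float)
    y = np.asarray(y, dtype=float)
    t = TWO_PI * months / period

    def fitted(p):
        M, A, phi = p
        return M + A * np.cos(t - phi)

    def sse(p):
        return float(np.sum((y - fitted(p)) ** 2))

    best = None
    for phi0 in np.linspace(0, TWO_PI, 8, endpoint=False):
        x0 = np.array([y.mean(), max(y.std(), 1e-3), phi0])
        res = optimize.minimize(sse, x0, method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14,
                                         "maxiter": 20000, "maxfev": 20000})
        if best is None or res.fun < best.fun:
            best = res
    return fitted(best.x), best.fun


def grid_peak_month(s, c, period=12.0, step=0.001):
    """Peak location of s*sin(t)+c*cos(t) by brute grid search over [0, period)."""
    m = np.arange(0.0, period, step)
    t = TWO_PI * m / period
    return float(m[np.argmax(s * np.sin(t) + c * np.cos(t))])


def bootstrap_amplitude_se(months, y, n_boot=2000, seed=0, period=12.0):
    """Nonparametric bootstrap SE of the cosinor amplitude.

    Resamples rows and refits the 3-column OLS by normal equations.
    """
    months = np.asarray(months, dtype=float)
    y = np.asarray(y, dtype=float)
    t = TWO_PI * months / period
    X = np.column_stack([np.ones_like(t), np.sin(t), np.cos(t)])
    rng = np.random.default_rng(seed)
    n = len(y)
    amps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        Xb, yb = X[idx], y[idx]
        beta = np.linalg.solve(Xb.T @ Xb, Xb.T @ yb)
        amps[b] = math.hypot(beta[1], beta[2])
    return float(amps.std(ddof=1))


def _analytic_prevalence(name):
    if name == "age_ge62":
        mu, sd = CONTINUOUS_COVARIATES["age"]
        return float(stats.norm.sf((62 - mu) / sd))
    return DEFAULT_PREVALENCES[name]


def censored_cosinor_estimand(
    mesor=59.6,
    amplitude=7.9,
    peak_month=7.5,
    sigma=19.0,
    lloq=6.6,
    with_covariates=True,
):
    """Closed-form OLS estimand of the unadjusted cosinor fit when values
    below the LLOQ are excluded.

    For each covariate cell (analytic prevalence-product weights, effects
    centred as the generator centres them) and month, the retained mean is
    the left-truncated normal mean and the retention probability reweights
    the month distribution; the estimand solves the weighted normal
    equations of the [1, sin, cos] design.  Returns (mesor*, amplitude*,
    peak_month*).
    """
    mu_b, sd_b = CONTINUOUS_COVARIATES["bmi"]
    p_lt25 = stats.norm.cdf((25 - mu_b) / sd_b)
    p_2530 = stats.norm.cdf((30 - mu_b) / sd_b) - p_lt25
    p_gt30 = 1 - p_lt25 - p_2530

    cells = []
    if with_covariates:
        bins = ["female", "age_ge62", "site_stavanger", "smoker",
                "activity_ge2h", "supplements", "diabetes"]
        prev = {b: _analytic_prevalence(b) for b in bins}
        bmi_levels = (("lt25", p_lt25, 0, 0), ("25to30", p_2530, 1, 0),
                      ("gt30", p_gt30, 0, 1))
        for combo in itertools.product((0, 1), repeat=len(bins)):
            w0 = np.prod([prev[b] if x else 1 - prev[b] for b, x in zip(bins, combo)])
            for _, pw, x2530, xgt30 in bmi_levels:
                mu = mesor
                for b, x in zip(bins, combo):
                    mu += DEFAULT_COVARIATE_EFFECTS[b] * (x - prev[b])
                mu += DEFAULT_COVARIATE_EFFECTS["bmi_group_25to30"] * (x2530 - p_2530)
                mu += DEFAULT_COVARIATE_EFFECTS["bmi_group_gt30"] * (xgt30 - p_gt30)
                age = combo[bins.index("age_ge62")]
                A = amplitude + (DEFAULT_AMPLITUDE_EFFECTS["age_ge62"] / 2.0) * (
                    age - prev["age_ge62"])
                cells.append((w0 * pw, mu, A))
    else:
        cells = [(1.0, mesor, amplitude)]

    months = np.arange(1, 13)
    t = TWO_PI * months / 12.0
    X = np.column_stack([np.ones(12), np.sin(t), np.cos(t)])
    g_num = np.zeros(12)
    q = np.zeros(12)
    for w, mu, A in cells:
        m_mu = mu + A * np.cos(TWO_PI * (months - peak_month) / 12.0)
        alpha = (lloq - m_mu) / sigma
        keep = stats.norm.sf(alpha)
        trunc_mean = m_mu + sigma * stats.norm.pdf(alpha) / keep
        g_num += w * keep * trunc_mean
        q += w * keep
    g = g_num / q
    W = np.diag(q / q.sum())
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ g)
    amp = math.hypot(beta[1], beta[2])
    peak = (math.atan2(beta[1], beta[2]) * 12.0 / TWO_PI) % 12.0
    return float(beta[0]), amp, peak
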
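"""Synthetic cardiovascular-cohort generator with sinusoidal seasonality.

Emulates a two-centre Norwegian cohort of ~4116 baseline 25OHD
measurements plus ~528 follow-up measurements from a nested subgroup of
271 patients: a cosine seasonal mean peaking between July and August,
covariate shifts of the annual mean, an age-dependent reduction of the
seasonal swing, Gaussian residuals, and within-person correlation between
baseline and follow-up induced by a person-level random intercept.

The truth model for patient i measured in month m is::

    y_im = mesor + sum_k beta_k (x_ik - xbar_k)
           + A_i * cos(2*pi*(m - peak_month)/12) + b_i + e_im

    A_i  = amplitude + sum_k (gamma_k / 2) * (x_ik - xbar_k)

with ``b_i ~ N(0, residual_sd^2 - within_person_sd^2)`` shared across a
patient's visits and ``e_im ~ N(0, within_person_sd^2)`` per measurement;
the within-person noise of a follow-up keeps a geometrically decaying
serial correlation with the baseline noise (``noise_autocorr_1m`` per
month of offset), so short-interval repeats track baseline most closely.
Covariate effects ``beta_k`` (nmol/l) and peak-trough effects ``gamma_k``
are centred at the realised baseline prevalences ``xbar_k``, so the
cohort-level annual mean, seasonal amplitude and peak month equal the
configured ``mesor``, ``amplitude`` and ``peak_month`` exactly, while the
level-vs-reference contrasts equal the configured effects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import data_model

log = logging.getLogger("cosinorvd")

TWO_PI = 2.0 * math.pi

#: annual-mean shifts per covariate level, nmol/l (adjusted-model estimates)
DEFAULT_COVARIATE_EFFECTS = {
    "female": -2.2,
    "age_ge62": 1.9,
    "site_stavanger": -5.3,
    "smoker": -3.4,
    "bmi_group_25to30": -2.3,
    "bmi_group_gt30": -8.6,
    "activity_ge2h": 4.1,
    "supplements": 8.4,
    "diabetes": -1.9,
}

#: peak-trough (2*amplitude) change per covariate level, nmol/l
DEFAULT_AMPLITUDE_EFFECTS = {"age_ge62": -6.3}

#: marginal prevalence of each Bernoulli covariate
DEFAULT_PREVALENCES = {
    "female": 0.281,
    "site_stavanger": 0.181,
    "smoker": 0.317,
    "activity_ge2h": 0.688,
    "supplements": 0.336,
    "diabetes": 0.119,
    "crp_gt10": 0.068,
}

#: fraction of missing values per covariate column (self-report items)
DEFAULT_MISSING_RATES = {"activity_ge2h": 0.247, "supplements": 0.127}

#: (mean, sd) of the continuous covariates
CONTINUOUS_COVARIATES = {
    "age": (61.8, 10.4),
    "bmi": (26.8, 4.0),
    "egfr": (87.8, 17.2),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic cohort."""

    n_baseline: int = 4116
    n_nested: int = 271
    followup_offsets_months: tuple = (1, 12)
    #: attendance probability per follow-up exam; 528/542 gives an
    #: expected total of 528 follow-up measurements from 271 patients
    followup_attendance: float = 528.0 / 542.0
    mesor: float = 59.6
    amplitude: float = 7.9
    peak_month: float = 7.5
    residual_sd: float = 19.0
    within_person_sd: float = 10.0
    #: serial correlation of the within-person noise across 1 month
    #: (decays geometrically with the follow-up offset), so short-interval
    #: repeat measurements track the baseline more closely than distant ones
    noise_autocorr_1m: float = 0.3
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    amplitude_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDE_EFFECTS))
    covariate_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES))
    missing_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    month_distribution: tuple = tuple([1.0 / 12] * 12)
    seed: int = 0
    #: optional joint covariate sampler ``f(n, rng) -> DataFrame`` overriding
    #: the independent draws
    covariate_sampler: Optional[Callable] = None

    def __post_init__(self):
        if self.amplitude < 0 or self.residual_sd < 0 or self.within_person_sd < 0:
            raise ValueError("amplitude and SDs must be non-negative")
        if self.within_person_sd > self.residual_sd:
            raise ValueError("within_person_sd cannot exceed residual_sd")
        if not 0 <= self.followup_attendance <= 1:
            raise ValueError("followup_attendance must be a probability")
        if not 0 <= self.noise_autocorr_1m < 1:
            raise ValueError("noise_autocorr_1m must be in [0, 1)")
        if any(not 0 <= p <= 1 for p in self.covariate_prevalences.values()):
            raise ValueError("prevalences must be in [0, 1]")
        md = np.asarray(self.month_distribution, dtype=float)
        if md.shape != (12,) or not math.isclose(md.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("month_distribution must be 12 probabilities summing to 1")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "followup_offsets_months" in raw:
            raw["followup_offsets_months"] = tuple(raw["followup_offsets_months"])
        if "month_distribution" in raw:
            raw["month_distribution"] = tuple(raw["month_distribution"])
        return cls(**raw)


def _wrap_month(month: np.ndarray) -> np.ndarray:
    return (month - 1) % 12 + 1


def _draw_covariates(cfg: GeneratorConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    if cfg.covariate_sampler is not None:
        return cfg.covariate_sampler(n, rng)
    cols: dict[str, np.ndarray] = {}
    for name, (mu, sd) in CONTINUOUS_COVARIATES.items():
        cols[name] = rng.normal(mu, sd, n)
    prev = cfg.covariate_prevalences
    for name, p in prev.items():
        if name == "site_stavanger":
            continue
        cols[name] = rng.binomial(1, p, n).astype(float)
    cols["site"] = np.where(
        rng.random(n) < prev.get("site_stavanger", 0.0), "stavanger", "bergen"
    ).astype(object)
    return pd.DataFrame(cols)


_TERM_SOURCES = {
    "female": ("female", None),
    "age_ge62": ("age_ge62", None),
    "site_stavanger": ("site", "stavanger"),
    "smoker": ("smoker", None),
    "bmi_group_25to30": ("bmi_group", "25to30"),
    "bmi_group_gt30": ("bmi_group", "gt30"),
    "activity_ge2h": ("activity_ge2h", None),
    "supplements": ("supplements", None),
    "diabetes": ("diabetes", None),
    "egfr_le60": ("egfr_le60", None),
    "crp_gt10": ("crp_gt10", None),
}


def _term_indicator(df: pd.DataFrame, term: str) -> np.ndarray:
    col, level = _TERM_SOURCES.get(term, (term, None))
    if col not in df:
        raise ValueError(f"effect term {term!r} has no source column in the cohort")
    v = df[col]
    if level is not None:
        return (v == level).to_numpy(dtype=float)
    return v.to_numpy(dtype=float)


def generate_cohort(
    config: GeneratorConfig = GeneratorConfig(),
    seed: Optional[int] = None,
    include_truth: bool = False,
) -> pd.DataFrame:
    """Draw a full synthetic cohort (baseline + follow-up rows).

    Fully reproducible from ``seed`` (falls back to ``config.seed``).
    With ``include_truth`` the frame carries hidden ``_truth_*`` columns
    (per-row annual mean, amplitude and seasonal mean) for oracle checks;
    these are never written by :func:`cosinorvd.data_model.write_cohort`.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_baseline
    cov = _draw_covariates(config, n, rng)
    cov["patient_id"] = np.array([f"P{i + 1:05d}" for i in range(n)], dtype=object)
    cov = data_model.add_derived(
        cov.assign(month=1, ohd2=np.nan, ohd3=np.nan)
    ).drop(columns=["month", "ohd2", "ohd3", "ohd", "usable", "season", "period", "visit"])

    month = rng.choice(np.arange(1, 13), size=n, p=np.asarray(config.month_distribution))

    # centred effects: cohort mean/amplitude equal the configured values
    mu = np.full(n, config.mesor)
    amp = np.full(n, config.amplitude)
    centres: dict[str, float] = {}
    for term, eff in config.covariate_effects.items():
        x = _term_indicator(cov, term)
        centres[term] = float(x.mean())
        mu = mu + eff * (x - centres[term])
    for term, eff in config.amplitude_effects.items():
        x = _term_indicator(cov, term)
        amp = amp + (eff / 2.0) * (x - float(x.mean()))
    if amp.min() < 0:
        raise ValueError(
            f"amplitude_effects imply a negative amplitude ({amp.min():.2f}) for some stratum"
        )

    between_sd = math.sqrt(config.residual_sd**2 - config.within_person_sd**2)
    b = rng.normal(0.0, between_sd, n)

    # MCAR missingness per patient (the truth above uses the actual values)
    for col, rate in config.missing_rates.items():
        mask = rng.random(n) < rate
        cov.loc[mask, col] = np.nan

    def seasonal(months_arr, amps):
        return amps * np.cos(TWO_PI * (months_arr - config.peak_month) / 12.0)

    e_base = rng.normal(0.0, config.within_person_sd, n)
    y = mu + seasonal(month, amp) + b + e_base

    base = cov.copy()
    base["visit"] = "baseline"
    base["month"] = month
    base["ohd2"] = 0.0
    base["ohd3"] = y
    if include_truth:
        base["_truth_annual"] = mu
        base["_truth_amplitude"] = amp
        base["_truth_seasonal"] = seasonal(month, amp)

    # nested subgroup with follow-up visits sharing the person intercept
    nested = rng.choice(n, size=min(config.n_nested, n), replace=False)
    fup_frames = []
    for k, offset in enumerate(config.followup_offsets_months, start=1):
        attend = nested[rng.random(len(nested)) < config.followup_attendance]
        if len(attend) == 0:
            continue
        fm = _wrap_month(month[attend] + offset)
        rho = config.noise_autocorr_1m ** offset
        e_f = rho * e_base[attend] + math.sqrt(1 - rho**2) * rng.normal(
            0.0, config.within_person_sd, len(attend)
        )
        fy = mu[attend] + seasonal(fm, amp[attend]) + b[attend] + e_f
        f = cov.iloc[attend].copy()
        f["visit"] = f"followup{k}"
        f["month"] = fm
        f["ohd2"] = 0.0
        f["ohd3"] = fy
        if include_truth:
            f["_truth_annual"] = mu[attend]
            f["_truth_amplitude"] = amp[attend]
            f["_truth_seasonal"] = seasonal(fm, amp[attend])
        fup_frames.append(f)

    df = pd.concat([base, *fup_frames], ignore_index=True)
    n_neg = int((df["ohd3"] < 0).sum())
    if n_neg:
        log.warning("generate_cohort: truncated %d negative concentration(s) at 0", n_neg)
        df["ohd3"] = df["ohd3"].clip(lower=0.0)
    df = data_model.add_derived(df)
    df.attrs["generator_centres"] = centres
    return df


def make_fixture(size_tag: str, path, seed: int = 0) -> pd.DataFrame:
    """Write a deterministic CSV fixture and return the frame.

    ``tiny``: 24 hand-checkable rows, two per month, values exactly on the
    default seasonal curve (rounded to 0.01 nmol/l) with alternating
    covariates.  ``paper-scale``: a full default cohort.
    """
    if size_tag == "tiny":
        months = np.tile(np.arange(1, 13), 2)
        curve = 59.6 + 7.9 * np.cos(TWO_PI * (months - 7.5) / 12.0)
        df = pd.DataFrame(
            {
                "patient_id": [f"T{i + 1:02d}" for i in range(24)],
                "visit": "baseline",
                "month": months,
                "ohd2": 0.0,
                "ohd3": np.round(curve, 2),
                "age": np.where(np.arange(24) % 2 == 0, 55.0, 70.0),
                "female": (np.arange(24) % 3 == 0).astype(float),
                "site": np.where(np.arange(24) % 4 == 0, "stavanger", "bergen"),
                "smoker": (np.arange(24) % 5 == 0).astype(float),
                "bmi": 26.0,
                "activity_ge2h": 1.0,
                "supplements": (np.arange(24) % 2).astype(float),
                "diabetes": 0.0,
                "egfr": 88.0,
                "crp_gt10": 0.0,
            }
        )
        df = data_model.add_derived(df)
    elif size_tag == "paper-scale":
        df = generate_cohort(GeneratorConfig(seed=seed))
    else:
        raise ValueError(f"unknown fixture size {size_tag!r}")
    data_model.write_cohort(df, path)
    return df
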
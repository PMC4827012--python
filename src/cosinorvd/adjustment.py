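"""Season-adjusted annual 25OHD values and sufficiency reclassification.

A participant's *annual value* removes the seasonal component from their
single measurement: the deviation of the measured value from the fitted
seasonal curve (at the participant's month and covariates) is added to
the cohort annual mean.  Classifying participants as vitamin D sufficient
(>= 50 nmol/l) or insufficient with measured versus annual values yields
a 2x2 cross-classification, tabulated for the whole year and separately
within the dark (October-March) and bright (April-September) periods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import data_model
from .cosinor import CosinorFit

log = logging.getLogger("cosinorvd")

STATUS = ("sufficient", "insufficient")


def annual_mean(fit: CosinorFit) -> float:
    """Cohort annual mean: the average fitted value with the seasonal
    (sine/cosine and interaction) columns zeroed.

    For a model without covariates this is exactly the intercept.
    """
    X = fit.X.copy()
    seasonal = [c for c in X.columns if c in ("sin", "cos") or c.endswith((":sin", ":cos"))]
    X[seasonal] = 0.0
    return float((X.to_numpy() @ fit.params.to_numpy()).mean())


def annualize(fit: CosinorFit) -> pd.DataFrame:
    """Season-adjusted annual value per fitted observation.

    ``annual = annual_mean + (measured - fitted)``; for the unadjusted
    model the mean of the annual values equals the annual mean exactly,
    because OLS residuals sum to zero.
    """
    am = annual_mean(fit)
    out = pd.DataFrame(
        {
            "measured": fit.y,
            "fitted_seasonal": fit.fitted,
            "annual": am + fit.residuals,
        },
        index=fit.y.index,
    )
    out.attrs["annual_mean"] = am
    return out


def classify(values, threshold: float = data_model.SUFFICIENCY_THRESHOLD) -> np.ndarray:
    """Sufficiency status: True (sufficient) iff value >= threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return np.asarray(values, dtype=float) >= threshold


@dataclass
class ReclassificationTable:
    """2x2 cross-classification of measured vs annual sufficiency status.

    ``counts[i, j]`` holds measured status i x annual status j with the
    order (sufficient, insufficient); off-diagonal cells are reclassified
    participants.  Percentages are kept unrounded; round only for display.
    """

    stratum: str
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2):
            raise ValueError("counts must be 2x2")

    @classmethod
    def from_counts(cls, suff_suff, suff_insuff, insuff_suff, insuff_insuff,
                    stratum="all_year"):
        return cls(stratum, np.array([[suff_suff, suff_insuff],
                                      [insuff_suff, insuff_insuff]]))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def n_reclassified(self) -> int:
        return int(self.counts[0, 1] + self.counts[1, 0])

    @property
    def total_reclassified_pct(self) -> float:
        return 100.0 * self.n_reclassified / self.n

    @property
    def row_reclassified_pct(self) -> np.ndarray:
        """Per measured-status row: % moved to the other annual status."""
        off = np.array([self.counts[0, 1], self.counts[1, 0]], dtype=float)
        return 100.0 * off / self.counts.sum(axis=1)

    @property
    def pct_measured_insufficient(self) -> float:
        return 100.0 * self.counts[1].sum() / self.n

    @property
    def pct_annual_insufficient(self) -> float:
        return 100.0 * self.counts[:, 1].sum() / self.n

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "n": self.n,
            "counts": self.counts.tolist(),
            "n_reclassified": self.n_reclassified,
            "total_reclassified_pct": self.total_reclassified_pct,
            "row_reclassified_pct": self.row_reclassified_pct.tolist(),
            "pct_measured_insufficient": self.pct_measured_insufficient,
            "pct_annual_insufficient": self.pct_annual_insufficient,
        }

    def format(self) -> str:
        r = self.row_reclassified_pct
        return "\n".join(
            [
                f"{self.stratum} (n={self.n})",
                "  measured \\ annual   sufficient  insufficient  reclassified%",
                f"  sufficient          {self.counts[0,0]:>10d}  {self.counts[0,1]:>12d}  {r[0]:>12.1f}",
                f"  insufficient        {self.counts[1,0]:>10d}  {self.counts[1,1]:>12d}  {r[1]:>12.1f}",
                f"  total reclassified: {self.total_reclassified_pct:.1f}%",
            ]
        )


def reclassification(
    measured_status,
    annual_status,
    months,
    strata: tuple = ("all_year", "dark", "bright"),
) -> dict[str, ReclassificationTable]:
    """Cross-classify sufficiency status overall and by dark/bright period.

    ``measured_status`` and ``annual_status`` are boolean arrays (True =
    sufficient) aligned per participant; ``months`` gives each blood-draw
    month.  Records with a missing month are excluded from the period
    strata with a warning (they still count in ``all_year``).
    """
    ms = np.asarray(measured_status, dtype=bool)
    an = np.asarray(annual_status, dtype=bool)
    mo = np.asarray(months, dtype=float)
    if not (len(ms) == len(an) == len(mo)):
        raise ValueError("status and month arrays must be aligned")
    n_missing = int(np.isnan(mo).sum())
    if n_missing:
        log.warning("reclassification: %d record(s) lack a month; excluded from period strata",
                    n_missing)
    period = data_model.period_of(np.where(np.isnan(mo), 1, mo))
    out = {}
    for stratum in strata:
        if stratum == "all_year":
            sel = np.ones(len(ms), dtype=bool)
        else:
            sel = (period == stratum) & ~np.isnan(mo)
        counts = np.array(
            [
                [np.sum(sel & ms & an), np.sum(sel & ms & ~an)],
                [np.sum(sel & ~ms & an), np.sum(sel & ~ms & ~an)],
            ]
        )
        out[stratum] = ReclassificationTable(stratum, counts)
    return out


def reclassify_cohort(
    fit: CosinorFit,
    table: pd.DataFrame,
    threshold: float = data_model.SUFFICIENCY_THRESHOLD,
) -> dict[str, ReclassificationTable]:
    """End-to-end Table-4-style analysis for a fitted cohort."""
    ann = annualize(fit)
    months = table.loc[ann.index, "month"]
    return reclassification(
        classify(ann["measured"], threshold),
        classify(ann["annual"], threshold),
        months,
    )
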
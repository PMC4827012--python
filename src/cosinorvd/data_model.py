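"""Cohort table I/O, preprocessing rules and calendar strata.

The cohort is held as a :class:`pandas.DataFrame` with one row per
measurement (baseline or follow-up visit).  Concentrations are in nmol/l
and time is the calendar month of blood draw, an integer 1-12.

Canonical column names (the shipped default schema; a YAML config can map
arbitrary file headers onto these):

==============  ======================================================
column          meaning
==============  ======================================================
patient_id      opaque identifier, shared across a patient's visits
visit           ``baseline`` / ``followup1`` / ``followup2``
month           calendar month of blood draw, 1-12
ohd2            25-hydroxyvitamin D2, nmol/l (may be absent)
ohd3            25-hydroxyvitamin D3, nmol/l (may be absent)
age             years
female          1 = female, 0 = male
site            ``bergen`` / ``stavanger``
smoker          1 = smoker (self-report, recent quit or cotinine rule)
bmi             body mass index, kg/m^2
activity_ge2h   1 = physical activity >= 2 h/week, 0 = <= 1 h/week
supplements     1 = regular/daily vitamin D supplement use
diabetes        1 = diabetes mellitus type 1 or 2
egfr            estimated glomerular filtration rate, ml/min/1.73m^2
crp             C-reactive protein, mg/l (``crp_gt10`` accepted instead)
==============  ======================================================

Derived columns added on read: ``ohd`` (total 25OHD after the LLOQ rule),
``usable``, ``age_ge62``, ``bmi_group``, ``egfr_le60``, ``crp_gt10``,
``season`` and ``period``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("cosinorvd")

#: assay lower limit of quantification, nmol/l
DEFAULT_LLOQ = 6.6
#: vitamin D sufficiency threshold, nmol/l (>= threshold is sufficient)
SUFFICIENCY_THRESHOLD = 50.0

VISITS = ("baseline", "followup1", "followup2")

SEASONS = ("JanMar", "AprJun", "JulSep", "OctDec")
#: months of negligible cutaneous vitamin D synthesis at ~60 degrees North
DARK_MONTHS = frozenset({10, 11, 12, 1, 2, 3})

BASE_COLUMNS = [
    "patient_id", "visit", "month", "ohd2", "ohd3",
    "age", "female", "site", "smoker", "bmi", "activity_ge2h",
    "supplements", "diabetes", "egfr", "crp", "crp_gt10",
    "sbp", "dbp", "antihypertensive",
]
MANDATORY_COLUMNS = ["patient_id", "month", "ohd3"]
NUMERIC_COLUMNS = [
    "month", "ohd2", "ohd3", "age", "female", "smoker", "bmi",
    "activity_ge2h", "supplements", "diabetes", "egfr", "crp",
    "crp_gt10", "sbp", "dbp", "antihypertensive",
]
DERIVED_COLUMNS = [
    "ohd", "usable", "age_ge62", "bmi_group", "egfr_le60", "crp_gt10",
    "season", "period",
]


class SchemaError(ValueError):
    """A mandatory column is missing or the schema config is invalid."""


class ValidationError(ValueError):
    """A record violates a hard constraint (e.g. negative concentration)."""


# ---------------------------------------------------------------------------
# calendar strata


@dataclass(frozen=True)
class CalendarStratum:
    """Quarter-of-year season and dark/bright half-year of a blood draw."""

    season: str
    period: str


def assign_calendar(month: int) -> CalendarStratum:
    """Map a calendar month to its season quarter and dark/bright period.

    Quarters are January-March, April-June, July-September and
    October-December; the dark period is October-March (negligible
    cutaneous vitamin D synthesis) and the bright period April-September.
    """
    m = int(month)
    if m != month or not 1 <= m <= 12:
        raise ValidationError(f"month must be an integer in 1..12, got {month!r}")
    return CalendarStratum(
        season=SEASONS[(m - 1) // 3],
        period="dark" if m in DARK_MONTHS else "bright",
    )


def season_of(months) -> np.ndarray:
    """Vectorised quarter labels for an array of months 1-12."""
    m = np.asarray(months, dtype=float)
    out = np.empty(m.shape, dtype=object)
    valid = np.isfinite(m)
    out[~valid] = None
    idx = ((m[valid].astype(int) - 1) // 3).clip(0, 3)
    out[valid] = np.array(SEASONS, dtype=object)[idx]
    return out


def period_of(months) -> np.ndarray:
    """Vectorised dark/bright labels for an array of months 1-12."""
    m = np.asarray(months, dtype=float)
    out = np.empty(m.shape, dtype=object)
    valid = np.isfinite(m)
    out[~valid] = None
    out[valid] = np.where(
        np.isin(m[valid].astype(int), list(DARK_MONTHS)), "dark", "bright"
    )
    return out


# ---------------------------------------------------------------------------
# per-record rules


@dataclass(frozen=True)
class MeasurementRecord:
    """A single 25OHD measurement with its component concentrations."""

    patient_id: str
    month: int
    ohd2: Optional[float] = None
    ohd3: Optional[float] = None
    ohd_total: Optional[float] = None
    visit: str = "baseline"
    usable: bool = True


def apply_lloq_and_sum(
    record: MeasurementRecord, lloq: float = DEFAULT_LLOQ
) -> MeasurementRecord:
    """Apply the assay LLOQ rule and sum D2 + D3 into total 25OHD.

    Components strictly below ``lloq`` are set absent (they contribute
    nothing to the total).  A record whose D3 component is absent after
    filtering carries no usable total and is flagged unusable.  The
    operation is idempotent.
    """
    if lloq <= 0:
        raise ValidationError(f"lloq must be positive, got {lloq}")
    for name in ("ohd2", "ohd3"):
        v = getattr(record, name)
        if v is not None and v < 0:
            raise ValidationError(f"negative concentration {name}={v}")
    ohd2 = record.ohd2 if record.ohd2 is not None and record.ohd2 >= lloq else None
    ohd3 = record.ohd3 if record.ohd3 is not None and record.ohd3 >= lloq else None
    if ohd3 is None:
        return replace(record, ohd2=ohd2, ohd3=None, ohd_total=None, usable=False)
    total = ohd3 + (ohd2 if ohd2 is not None else 0.0)
    return replace(record, ohd2=ohd2, ohd3=ohd3, ohd_total=total, usable=True)


def derive_smoking(
    self_report_smoker: Optional[bool] = None,
    days_since_quit: Optional[float] = None,
    cotinine: Optional[float] = None,
) -> Optional[bool]:
    """Smoking status: self-report, quit <= 90 days ago, or cotinine > 85 nmol/l.

    Returns ``None`` when every input is absent.
    """
    if self_report_smoker is None and days_since_quit is None and cotinine is None:
        return None
    return bool(
        (self_report_smoker is not None and self_report_smoker)
        or (days_since_quit is not None and days_since_quit <= 90)
        or (cotinine is not None and cotinine > 85)
    )


def derive_hypertension(
    sbp: Optional[float] = None,
    dbp: Optional[float] = None,
    on_antihypertensive: Optional[bool] = None,
) -> Optional[bool]:
    """Hypertension: SBP > 140 and/or DBP > 90 mm Hg and/or drug treatment."""
    if sbp is None and dbp is None and on_antihypertensive is None:
        return None
    return bool(
        (sbp is not None and sbp > 140)
        or (dbp is not None and dbp > 90)
        or (on_antihypertensive is not None and on_antihypertensive)
    )


# ---------------------------------------------------------------------------
# schema and table-level I/O


@dataclass
class CohortSchema:
    """File-to-canonical column mapping plus preprocessing constants."""

    columns: Mapping[str, str] = field(default_factory=dict)
    delimiter: str = ","
    lloq: float = DEFAULT_LLOQ
    threshold: float = SUFFICIENCY_THRESHOLD

    @classmethod
    def from_yaml(cls, path) -> "CohortSchema":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {"columns", "delimiter", "lloq", "threshold"}
        if unknown:
            raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
        cols = raw.get("columns", {}) or {}
        bad = set(cols) - set(BASE_COLUMNS)
        if bad:
            raise SchemaError(f"unknown canonical columns in mapping: {sorted(bad)}")
        return cls(
            columns=cols,
            delimiter=raw.get("delimiter", ","),
            lloq=float(raw.get("lloq", DEFAULT_LLOQ)),
            threshold=float(raw.get("threshold", SUFFICIENCY_THRESHOLD)),
        )


def add_derived(table: pd.DataFrame, lloq: float = DEFAULT_LLOQ) -> pd.DataFrame:
    """Apply the LLOQ rule and add total 25OHD, group and calendar columns.

    Idempotent; returns a new frame.  Group columns are only derived from
    their continuous source when not already present (so a file may supply
    e.g. ``crp_gt10`` directly).
    """
    df = table.copy()
    for comp in ("ohd2", "ohd3"):
        if comp in df:
            below = df[comp].notna() & (df[comp] < lloq)
            df.loc[below, comp] = np.nan
        else:
            df[comp] = np.nan
    df["ohd"] = np.where(
        df["ohd3"].notna(), df["ohd3"] + df["ohd2"].fillna(0.0), np.nan
    )
    month_ok = df["month"].notna() & df["month"].isin(range(1, 13))
    df["usable"] = df["ohd3"].notna() & month_ok

    if "age" in df:
        df["age_ge62"] = _indicator(df["age"] >= 62, df["age"])
    if "bmi" in df:
        df["bmi_group"] = np.select(
            [df["bmi"] < 25, df["bmi"] <= 30, df["bmi"] > 30],
            ["lt25", "25to30", "gt30"],
            default=None,
        )
    if "egfr" in df:
        df["egfr_le60"] = _indicator(df["egfr"] <= 60, df["egfr"])
    if "crp" in df and "crp_gt10" not in df:
        df["crp_gt10"] = _indicator(df["crp"] > 10, df["crp"])
    df["season"] = season_of(df["month"])
    df["period"] = period_of(df["month"])
    if "visit" not in df:
        df["visit"] = "baseline"
    return df


def _indicator(cond: pd.Series, source: pd.Series) -> pd.Series:
    out = cond.astype(float)
    out[source.isna()] = np.nan
    return out


def read_cohort(path, schema: Optional[CohortSchema] = None) -> pd.DataFrame:
    """Read a delimited cohort file, validate rows and derive columns.

    Rows with an unparseable or out-of-range month, missing patient id, or
    a negative concentration are dropped; drop counts are logged to stderr
    and kept in ``DataFrame.attrs['n_dropped']``.  Per-column missing-value
    counts are reported in ``attrs['missing_counts']``.
    """
    schema = schema or CohortSchema()
    df = pd.read_csv(path, sep=schema.delimiter, dtype={0: str})
    rename = {v: k for k, v in schema.columns.items()}
    df = df.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")

    n0 = len(df)
    dropped: dict[str, int] = {}
    for col in NUMERIC_COLUMNS:
        if col in df:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df["patient_id"] = df["patient_id"].astype(str)

    bad_month = ~(df["month"].notna() & df["month"].isin(range(1, 13)))
    _drop(df, bad_month, dropped, "invalid_month")
    df = df[~bad_month]
    neg = pd.Series(False, index=df.index)
    for comp in ("ohd2", "ohd3"):
        if comp in df:
            neg |= df[comp].notna() & (df[comp] < 0)
    _drop(df, neg, dropped, "negative_concentration")
    df = df[~neg]
    df["month"] = df["month"].astype(int)

    df = add_derived(df, lloq=schema.lloq)
    n_unusable = int((~df["usable"]).sum())
    if n_unusable:
        log.warning("read_cohort: %d record(s) unusable after LLOQ filtering", n_unusable)
    df.attrs["n_dropped"] = n0 - len(df)
    df.attrs["drop_reasons"] = dropped
    df.attrs["missing_counts"] = {
        c: int(df[c].isna().sum()) for c in df.columns if c not in ("season", "period")
    }
    if df.attrs["n_dropped"]:
        log.warning(
            "read_cohort: dropped %d of %d rows (%s)",
            df.attrs["n_dropped"], n0, dropped,
        )
    return df.reset_index(drop=True)


def _drop(df, mask, dropped, reason):
    n = int(mask.sum())
    if n:
        dropped[reason] = n


def write_cohort(table: pd.DataFrame, path, schema: Optional[CohortSchema] = None) -> None:
    """Write the base (non-derived) columns as delimited text.

    Reading the file back with the same schema reproduces the values
    (derived columns are recomputed).
    """
    schema = schema or CohortSchema()
    cols = [c for c in BASE_COLUMNS if c in table.columns]
    out = table[cols].rename(columns=dict(schema.columns))
    out.to_csv(path, sep=schema.delimiter, index=False)
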
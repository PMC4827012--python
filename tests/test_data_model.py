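import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from cosinorvd import data_model as dm
from cosinorvd.synthetic import make_fixture


class TestLloqAndSum:
    @pytest.mark.parametrize(
        "ohd2,ohd3,total,ohd2_absent,usable",
        [
            (3.0, 60.0, 60.0, True, True),   # D2 below LLOQ contributes nothing
            (10.0, 50.0, 60.0, False, True),  # both quantifiable: plain sum
            (None, 6.5, None, True, False),   # sole component below LLOQ
            (None, 6.6, 6.6, True, True),     # LLOQ boundary is retained
        ],
    )
    def test_component_filtering_and_sum(self, ohd2, ohd3, total, ohd2_absent, usable):
        rec = dm.MeasurementRecord("p1", month=3, ohd2=ohd2, ohd3=ohd3)
        out = dm.apply_lloq_and_sum(rec)
        assert out.ohd_total == total
        assert (out.ohd2 is None) == ohd2_absent
        assert out.usable is usable

    def test_negative_concentration_rejected(self):
        rec = dm.MeasurementRecord("p1", month=3, ohd2=-1.0, ohd3=50.0)
        with pytest.raises(dm.ValidationError):
            dm.apply_lloq_and_sum(rec)

    @given(
        ohd2=st_h.one_of(st_h.none(), st_h.floats(0, 200)),
        ohd3=st_h.one_of(st_h.none(), st_h.floats(0, 200)),
    )
    @settings(max_examples=50, derandomize=True)
    def test_idempotent(self, ohd2, ohd3):
        rec = dm.MeasurementRecord("p1", month=6, ohd2=ohd2, ohd3=ohd3)
        once = dm.apply_lloq_and_sum(rec)
        assert dm.apply_lloq_and_sum(once) == once


class TestCovariateRules:
    @pytest.mark.parametrize(
        "self_report,quit_days,cotinine,expected",
        [
            (False, None, 90.0, True),    # cotinine strictly above 85 nmol/l
            (False, None, 85.0, False),   # boundary: rule is strict >
            (False, 91.0, 10.0, False),   # quit outside the 90-day window
            (False, 90.0, 10.0, True),    # quit exactly 90 days ago counts
            (True, None, None, True),
            (None, None, None, None),
        ],
    )
    def test_smoking_rule(self, self_report, quit_days, cotinine, expected):
        assert dm.derive_smoking(self_report, quit_days, cotinine) is expected

    @pytest.mark.parametrize(
        "sbp,dbp,drug,expected",
        [
            (141, 80, False, True),    # SBP strictly above 140
            (140, 90, False, False),   # both boundaries: strict inequalities
            (120, 70, True, True),     # drug use alone suffices
            (120, 91, False, True),
            (None, None, None, None),
        ],
    )
    def test_hypertension_rule(self, sbp, dbp, drug, expected):
        assert dm.derive_hypertension(sbp, dbp, drug) is expected


class TestCalendar:
    @pytest.mark.parametrize(
        "month,season,period",
        [(3, "JanMar", "dark"), (4, "AprJun", "bright"), (10, "OctDec", "dark"),
         (9, "JulSep", "bright"), (1, "JanMar", "dark")],
    )
    def test_examples(self, month, season, period):
        stratum = dm.assign_calendar(month)
        assert (stratum.season, stratum.period) == (season, period)

    def test_partition_of_the_year(self):
        strata = [dm.assign_calendar(m) for m in range(1, 13)]
        dark = {m for m, s in zip(range(1, 13), strata) if s.period == "dark"}
        bright = {m for m, s in zip(range(1, 13), strata) if s.period == "bright"}
        assert dark | bright == set(range(1, 13)) and not dark & bright
        assert dark == {10, 11, 12, 1, 2, 3}

    @pytest.mark.parametrize("month", [0, 13, 6.5])
    def test_out_of_range_rejected(self, month):
        with pytest.raises(dm.ValidationError):
            dm.assign_calendar(month)


class TestCohortIO:
    def test_round_trip(self, tmp_path):
        table = make_fixture("tiny", tmp_path / "tiny.csv")
        back = dm.read_cohort(tmp_path / "tiny.csv")
        assert len(back) == 24
        pd.testing.assert_frame_equal(
            back[["patient_id", "month", "ohd3", "age", "site"]],
            table[["patient_id", "month", "ohd3", "age", "site"]],
        )

    def test_missing_mandatory_column_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("patient_id,ohd3\na,50\n")
        with pytest.raises(dm.SchemaError, match="month"):
            dm.read_cohort(p)

    def test_lloq_and_validation_on_read(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "patient_id,month,ohd2,ohd3\n"
            "a,1,3.0,60.0\n"   # D2 below LLOQ
            "b,2,,6.5\n"       # D3 below LLOQ: unusable
            "c,13,,50.0\n"     # invalid month: dropped
            "d,3,,-5.0\n"      # negative: dropped
            "e,4,,55.0\n"
        )
        df = dm.read_cohort(p)
        assert df.attrs["n_dropped"] == 2
        assert df["usable"].sum() == 2
        assert df.loc[df.patient_id == "a", "ohd"].item() == 60.0
        assert np.isnan(df.loc[df.patient_id == "a", "ohd2"].item())

    def test_schema_config_maps_columns(self, tmp_path):
        cfg = tmp_path / "schema.yaml"
        cfg.write_text("columns:\n  patient_id: id\n  month: mnd\n  ohd3: d3\nlloq: 10\n")
        schema = dm.CohortSchema.from_yaml(cfg)
        p = tmp_path / "c.csv"
        p.write_text("id,mnd,d3\na,1,9.0\nb,2,50.0\n")
        df = dm.read_cohort(p, schema)
        assert list(df["patient_id"]) == ["a", "b"]
        assert df["usable"].tolist() == [False, True]  # 9.0 below configured LLOQ

    def test_missing_counts_reported(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("patient_id,month,ohd3,supplements\na,1,50,\nb,2,60,1\n")
        df = dm.read_cohort(p)
        assert df.attrs["missing_counts"]["supplements"] == 1
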
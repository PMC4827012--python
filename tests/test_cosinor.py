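import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from cosinorvd import (
    CosinorFit,
    CosinorSpec,
    FitError,
    build_design,
    delta_se,
    fit_cosinor,
    seasonal_summary,
)
from cosinorvd.cosinor import (
    amplitude_from_peak_trough,
    relative_seasonal_variation,
    required_peak_concentration,
)

from conftest import toy_table
from oracles import grid_peak_month

TWO_PI = 2 * math.pi


def curve(months, mesor=60.0, bs=5.0, bc=0.0):
    t = TWO_PI * np.asarray(months) / 12.0
    return mesor + bs * np.sin(t) + bc * np.cos(t)


def synthetic_fit(params, vcov):
    """Hand-built fit object for checking the Delta-method algebra."""
    names = list(params)
    return CosinorFit(
        params=pd.Series(params),
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        n_used=100,
        df_resid=97.0,
        residuals=pd.Series(dtype=float),
        sigma_hat=1.0,
        spec=CosinorSpec(),
    )


class TestDesign:
    def test_trig_columns_exact(self):
        table = toy_table([3, 12, 6], [60, 60, 60])
        X, y, _ = build_design(table, CosinorSpec())
        assert list(X.columns) == ["const", "sin", "cos"]
        np.testing.assert_allclose(X.iloc[0], [1, 1, 0], atol=1e-15)   # month 3
        np.testing.assert_allclose(X.iloc[1], [1, 0, 1], atol=1e-15)   # month 12
        np.testing.assert_allclose(X.iloc[2], [1, 0, -1], atol=1e-15)  # month 6

    def test_interaction_columns(self):
        table = toy_table([6, 6], [60, 60], age=[70.0, 50.0])
        X, _, tm = build_design(
            table, CosinorSpec(covariates=("age_ge62",), interactions=("age_ge62",))
        )
        assert tm["age_ge62"] == ["age_ge62"]
        row = X.iloc[0]
        assert row["age_ge62"] == 1.0
        assert row["age_ge62:sin"] == pytest.approx(0.0, abs=1e-15)  # sin(pi) = 0
        assert row["age_ge62:cos"] == pytest.approx(-1.0)

    def test_complete_case_filtering(self):
        table = toy_table([1, 2, 3], [60, 60, 60], supplements=[1.0, np.nan, 0.0])
        X, _, _ = build_design(table, CosinorSpec(covariates=("supplements",)))
        assert len(X) == 2


class TestFit:
    def test_noiseless_recovery_exact(self):
        months = np.tile(np.arange(1, 13), 3)
        fit = fit_cosinor(toy_table(months, curve(months)), CosinorSpec())
        np.testing.assert_allclose(
            fit.params, [60.0, 5.0, 0.0], atol=1e-10
        )
        assert abs(fit.residuals.sum()) < 1e-9

    def test_constant_data(self):
        months = np.arange(1, 13)
        fit = fit_cosinor(toy_table(months, np.full(12, 50.0)), CosinorSpec())
        np.testing.assert_allclose(fit.params, [50.0, 0.0, 0.0], atol=1e-10)

    def test_rank_deficiency_names_columns(self):
        table = toy_table([1, 2, 3, 4, 5, 6, 7, 8], np.full(8, 60.0),
                          supplements=np.ones(8))
        with pytest.raises(FitError, match="supplements"):
            fit_cosinor(table, CosinorSpec(covariates=("supplements",)))

    def test_vcov_symmetric_psd(self, small_cohort):
        fit = fit_cosinor(small_cohort, CosinorSpec())
        V = fit.vcov.to_numpy()
        np.testing.assert_allclose(V, V.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(V) > -1e-12)

    # k bounded below so shifted values stay above the LLOQ (otherwise the
    # exclusion rule changes the fitted rows and equivariance need not hold)
    @given(
        k=st_h.floats(-25, 40),
        shift=st_h.integers(1, 11),
        seed=st_h.integers(0, 10_000),
    )
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_shift_and_rotation_equivariance(self, k, shift, seed):
        """Adding k to y moves only the MESOR; rotating months rotates the
        peak by the same amount and leaves the amplitude unchanged."""
        rng = np.random.default_rng(seed)
        months = rng.integers(1, 13, 40)
        y = curve(months, 58.0, 4.0, -3.0) + rng.normal(0, 5, 40)
        base = seasonal_summary(fit_cosinor(toy_table(months, y), CosinorSpec()))

        shifted = seasonal_summary(fit_cosinor(toy_table(months, y + k), CosinorSpec()))
        assert shifted.mesor == pytest.approx(base.mesor + k, abs=1e-8)
        assert shifted.amplitude == pytest.approx(base.amplitude, abs=1e-8)
        assert shifted.peak_month == pytest.approx(base.peak_month, abs=1e-8)

        rotated_months = (months + shift - 1) % 12 + 1
        rotated = seasonal_summary(
            fit_cosinor(toy_table(rotated_months, y), CosinorSpec())
        )
        assert rotated.amplitude == pytest.approx(base.amplitude, abs=1e-8)
        assert rotated.peak_month % 12 == pytest.approx(
            (base.peak_month + shift) % 12, abs=1e-8
        )


class TestSeasonalSummary:
    def test_pure_sine_peak_in_march(self):
        months = np.tile(np.arange(1, 13), 2)
        fit = fit_cosinor(toy_table(months, curve(months, 60, 5, 0)), CosinorSpec())
        s = seasonal_summary(fit)
        assert s.amplitude == pytest.approx(5.0, abs=1e-9)
        assert s.peak_trough == pytest.approx(2 * s.amplitude)
        assert s.peak_month == pytest.approx(3.0, abs=1e-9)
        assert (s.peak_month - s.trough_month) % 12 == pytest.approx(6.0)

    def test_zero_amplitude_phase_flagged(self):
        months = np.arange(1, 13)
        fit = fit_cosinor(toy_table(months, np.full(12, 50.0)), CosinorSpec())
        s = seasonal_summary(fit)
        assert s.amplitude == pytest.approx(0.0, abs=1e-10)
        assert not s.phase_defined
        assert s.peak_month is None and s.se_amplitude is None

    def test_peak_matches_grid_search(self):
        months = np.tile(np.arange(1, 13), 2)
        fit = fit_cosinor(toy_table(months, curve(months, 60, 3, 4)), CosinorSpec())
        s = seasonal_summary(fit)
        assert s.amplitude == pytest.approx(5.0, abs=1e-9)
        assert s.peak_month == pytest.approx(grid_peak_month(3, 4), abs=0.002)

    def test_summary_at_interacted_level(self):
        months = np.tile(np.arange(1, 13), 4)
        old = np.repeat([0.0, 1.0], 24)
        y = curve(months, 60, 5, 0) - old * curve(months, 0, 2, 0)  # old: amp 3
        table = toy_table(months, y, age=np.where(old == 1, 70.0, 50.0))
        fit = fit_cosinor(
            table, CosinorSpec(covariates=("age_ge62",), interactions=("age_ge62",))
        )
        assert seasonal_summary(fit).amplitude == pytest.approx(5.0, abs=1e-9)
        assert seasonal_summary(fit, at={"age_ge62": 1}).amplitude == pytest.approx(
            3.0, abs=1e-9
        )


class TestDeltaMethod:
    def test_unit_gradient_norm(self):
        fit = synthetic_fit({"const": 60.0, "sin": 3.0, "cos": 4.0}, np.eye(3))
        # dA/d(sin,cos) = (0.6, 0.8); with identity covariance SE(A) = 1
        assert delta_se(fit, "amplitude") == pytest.approx(1.0)
        assert delta_se(fit, "peak_trough") == pytest.approx(2.0)

    def test_zero_covariance_gives_zero_se(self):
        fit = synthetic_fit({"const": 60.0, "sin": 3.0, "cos": 4.0}, np.zeros((3, 3)))
        assert delta_se(fit, "amplitude") == 0.0
        assert delta_se(fit, "phase") == 0.0

    def test_zero_amplitude_raises_for_phase(self):
        fit = synthetic_fit({"const": 60.0, "sin": 0.0, "cos": 0.0}, np.eye(3))
        with pytest.raises(FitError):
            delta_se(fit, "phase")

    def test_ci_is_wald(self, small_cohort):
        s = seasonal_summary(fit_cosinor(small_cohort, CosinorSpec()))
        lo, hi = s.ci_amplitude
        assert lo == pytest.approx(s.amplitude - 1.96 * s.se_amplitude, abs=1e-3)
        assert hi == pytest.approx(s.amplitude + 1.96 * s.se_amplitude, abs=1e-3)


class TestCurveArithmetic:
    def test_helpers(self):
        assert amplitude_from_peak_trough(15.8) == pytest.approx(7.9)
        assert required_peak_concentration(50.0, 15.8) == pytest.approx(65.8)
        assert relative_seasonal_variation(15.8, 59.6) == pytest.approx(26.5, abs=0.05)
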
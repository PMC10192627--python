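"""Kinetic model curves and DT endpoint back-calculation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from minkin import (
    KineticParameters,
    ModelId,
    dt_x_closed_form,
    dt_x_numeric,
    fomc_curve,
    hs_curve,
    model_curve,
    sfo_curve,
)
from tests.conftest import random_params


class TestCurveValues:
    def test_sfo_point_values(self):
        p = KineticParameters(model_id=ModelId.SFO, k1=0.02)
        assert sfo_curve(0.0, p) == 0.0
        assert sfo_curve(math.log(2) / 0.02, p) == pytest.approx(50.0, rel=1e-12)
        slow = KineticParameters(model_id=ModelId.SFO, k1=1.2e-3)
        assert sfo_curve(120.0, slow) == pytest.approx(13.42, abs=0.01)

    def test_fomc_point_values(self):
        p = KineticParameters(model_id=ModelId.FOMC, alpha=1.0, beta=30.0)
        assert fomc_curve(0.0, p) == 0.0
        assert fomc_curve(30.0, p) == pytest.approx(50.0, rel=1e-12)
        cr = KineticParameters(model_id=ModelId.FOMC, alpha=2.0, beta=64.4)
        assert fomc_curve(26.675353, cr) == pytest.approx(50.0, abs=1e-4)

    def test_hs_point_values(self):
        p = KineticParameters(model_id=ModelId.HS, k1=1.4e-2, k2=7.2e-4, tb=12.3)
        # first phase identical to SFO with k1
        sfo = KineticParameters(model_id=ModelId.SFO, k1=1.4e-2)
        t_early = np.array([0.0, 3.0, 12.3])
        np.testing.assert_allclose(hs_curve(t_early, p), sfo_curve(t_early, sfo))
        assert hs_curve(120.0, p) == pytest.approx(22.10, abs=0.01)

    def test_negative_time_rejected(self, sfo_params, fomc_params, hs_params):
        for p in (sfo_params, fomc_params, hs_params):
            with pytest.raises(ValueError):
                model_curve(-1.0, p)

    def test_hs_equals_sfo_when_rates_equal(self):
        hs = KineticParameters(model_id=ModelId.HS, k1=0.01, k2=0.01, tb=7.0)
        sfo = KineticParameters(model_id=ModelId.SFO, k1=0.01)
        t = np.linspace(0, 200, 97)
        np.testing.assert_allclose(hs_curve(t, hs), sfo_curve(t, sfo), rtol=1e-14)

    def test_fomc_sfo_limit(self):
        """alpha = k*beta with huge beta collapses FOMC onto SFO."""
        k = 0.05
        beta = 1e6
        fomc = KineticParameters(model_id=ModelId.FOMC, alpha=k * beta, beta=beta)
        sfo = KineticParameters(model_id=ModelId.SFO, k1=k)
        t = np.linspace(0, 120, 241)
        assert np.max(np.abs(fomc_curve(t, fomc) - sfo_curve(t, sfo))) < 1e-3


class TestParameterValidation:
    def test_missing_required_parameter(self):
        with pytest.raises(ValueError):
            KineticParameters(model_id=ModelId.SFO)
        with pytest.raises(ValueError):
            KineticParameters(model_id=ModelId.HS, k1=0.01, k2=0.001)

    def test_foreign_parameter_rejected(self):
        with pytest.raises(ValueError):
            KineticParameters(model_id=ModelId.SFO, k1=0.01, alpha=1.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(model_id=ModelId.SFO, k1=-0.01),
            dict(model_id=ModelId.FOMC, alpha=0.0, beta=1.0),
            dict(model_id=ModelId.HS, k1=0.01, k2=0.001, tb=0.0),
            dict(model_id=ModelId.SFO, k1=0.01, m_max=0.0),
            dict(model_id=ModelId.SFO, k1=0.01, m_max=101.0),
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            KineticParameters(**kwargs)

    def test_zero_rate_allowed_for_sterile_controls(self):
        p = KineticParameters(model_id=ModelId.SFO, k1=0.0)
        assert sfo_curve(120.0, p) == 0.0


class TestDtClosedForm:
    @pytest.mark.parametrize(
        "params, printed_dt50",
        [
            (dict(model_id=ModelId.SFO, k1=3.0e-4), 2307.0),
            (dict(model_id=ModelId.FOMC, alpha=2.0, beta=64.4), 26.4),
            (dict(model_id=ModelId.HS, k1=5.7e-2, k2=1.7e-3, tb=14.2), 12.1),
        ],
    )
    def test_published_half_lives(self, params, printed_dt50):
        """Closed forms reproduce published DT50s from their rate constants."""
        est = dt_x_closed_form(KineticParameters(**params))
        assert est.value == pytest.approx(printed_dt50, rel=0.025)

    def test_hs_second_phase_branch(self):
        p = KineticParameters(model_id=ModelId.HS, k1=2.7e-2, k2=7.3e-4, tb=12.2)
        est = dt_x_closed_form(p)
        expected = 12.2 + (math.log(2) - 2.7e-2 * 12.2) / 7.3e-4
        assert est.value == pytest.approx(expected, rel=1e-12)
        assert est.value == pytest.approx(510.4, abs=0.1)

    def test_unreachable_target_is_infinite(self):
        p = KineticParameters(model_id=ModelId.HS, k1=0.01, k2=0.0, tb=10.0)
        with pytest.warns(UserWarning):
            est = dt_x_closed_form(p, 50.0)
        assert math.isinf(est.value)
        with pytest.warns(UserWarning):
            est_num = dt_x_numeric(p, 50.0)
        assert math.isinf(est_num.value)

    def test_invalid_target_fraction(self, sfo_params):
        for x in (0.0, 100.0, -5.0):
            with pytest.raises(ValueError):
                dt_x_closed_form(sfo_params, x)

    def test_dt50_below_dt90(self, sfo_params, fomc_params, hs_params):
        for p in (sfo_params, fomc_params, hs_params):
            assert dt_x_closed_form(p, 50).value < dt_x_closed_form(p, 90).value

    def test_applied_and_plateau_bases_coincide(self, hs_params):
        applied = dt_x_closed_form(hs_params, 50, basis="applied")
        plateau = dt_x_numeric(hs_params, 50, basis="plateau")
        assert plateau.value == pytest.approx(applied.value, rel=1e-8)


class TestNumericOracle:
    def test_sfo_half_life_identity(self):
        p = KineticParameters(model_id=ModelId.SFO, k1=0.02)
        assert dt_x_numeric(p, 50).value == pytest.approx(math.log(2) / 0.02, abs=1e-6)

    @pytest.mark.parametrize("model_id", list(ModelId))
    def test_closed_form_matches_root_finding(self, model_id):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            p = random_params(rng, model_id)
            cf = dt_x_closed_form(p, 50).value
            num = dt_x_numeric(p, 50).value
            assert abs(num - cf) / cf <= 1e-8


@settings(max_examples=60, derandomize=True)
@given(
    model_idx=st.integers(0, 2),
    draw_seed=st.integers(0, 2**31 - 1),
    t1=st.floats(0, 200),
    dt=st.floats(0.001, 200),
)
def test_curves_start_at_zero_and_increase(model_idx, draw_seed, t1, dt):
    """M(0)=0 and monotone non-decreasing for any valid parameters."""
    model_id = list(ModelId)[model_idx]
    p = random_params(np.random.default_rng(draw_seed), model_id)
    assert model_curve(0.0, p) == 0.0
    m1, m2 = model_curve(t1, p), model_curve(t1 + dt, p)
    assert m2 >= m1
    assert 0.0 <= m1 < p.m_max + 1e-12
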
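"""Unit and property tests for the closed-form respiration equations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nightresp.models import (DeclineParams, JulesRespParams, Q10Spec,
                              decline_fraction, growth_resp, jules_leaf_resp,
                              maintenance_resp, new_formulation, standard_model,
                              tdq10)


class TestStandardModel:
    @pytest.mark.parametrize(
        "r_ref, q10, T, T_ref, expected",
        [
            (2.5, 2.0, 25.0, 25.0, 2.5),            # identity at reference T
            (2.5, 2.0, 15.0, 25.0, 1.25),           # halving per 10 degC
            (1.0, 2.0, 20.0, 25.0, 2.0 ** -0.5),    # arithmetic oracle
        ],
    )
    def test_values(self, r_ref, q10, T, T_ref, expected):
        got = standard_model(r_ref, Q10Spec(q10_fixed=q10), T, T_ref)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonpositive_reference(self):
        with pytest.raises(ValueError):
            standard_model(0.0, Q10Spec(), 20.0, 25.0)
        with pytest.raises(ValueError):
            standard_model(-1.0, Q10Spec(), 20.0, 25.0)

    def test_identity_at_reference_for_any_spec(self):
        for spec in (Q10Spec(), Q10Spec(q10_fixed=3.1),
                     Q10Spec(mode="temperature_dependent")):
            assert standard_model(1.7, spec, 25.0, 25.0) == pytest.approx(1.7, abs=0)

    def test_strictly_increasing_in_T(self):
        T = np.linspace(0, 40, 50)
        r = standard_model(1.0, Q10Spec(q10_fixed=2.0), T, 25.0)
        assert np.all(np.diff(r) > 0)


class TestTDQ10:
    @pytest.mark.parametrize("T, expected", [(0.0, 3.09), (25.0, 2.0025), (10.0, 2.655)])
    def test_linear_values(self, T, expected):
        assert tdq10(T) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_warns_only(self):
        with pytest.warns(RuntimeWarning):
            val = tdq10(60.0)
        assert val == pytest.approx(3.09 - 0.0435 * 60.0)


class TestDeclineFraction:
    def test_unity_at_darkness_onset(self):
        assert decline_fraction(0.0) == 1.0

    def test_quarter_decrease_after_8h(self):
        # the universal decline predicts a ~25% decrease after 8 h of darkness
        assert decline_fraction(8.0) == pytest.approx(1 - 0.08 * 8**0.54, abs=1e-15)
        assert 100 * (1 - decline_fraction(8.0)) == pytest.approx(25.0, abs=0.5)

    def test_one_hour_value(self):
        assert decline_fraction(1.0) == pytest.approx(0.92, abs=1e-12)

    def test_negative_hours_rejected(self):
        with pytest.raises(ValueError):
            decline_fraction(-0.1)

    def test_disabled_returns_unity(self):
        p = DeclineParams.disabled()
        h = np.linspace(0, 16, 30)
        assert np.all(decline_fraction(h, p) == 1.0)

    def test_clamped_at_zero(self):
        assert decline_fraction(1000.0) == 0.0

    @settings(derandomize=True, max_examples=60)
    @given(h1=st.floats(0, 16), h2=st.floats(0, 16),
           a=st.floats(0, 0.3), b=st.floats(0.1, 1.5))
    def test_monotone_nonincreasing_and_bounded(self, h1, h2, a, b):
        p = DeclineParams(a=a, b=b)
        lo, hi = sorted((h1, h2))
        d_lo, d_hi = decline_fraction(lo, p), decline_fraction(hi, p)
        assert 0.0 <= d_hi <= d_lo <= 1.0


class TestNewFormulation:
    def test_sunset_identity(self):
        assert new_formulation(2.5, Q10Spec(), 18.0, 18.0, 0.0) == pytest.approx(2.5)

    def test_cooling_night_oracle(self):
        # 0.5 degC/h for 8 h from the Fig-2d-style parameter set
        expected = 2.5 * 2 ** (-0.4) * (1 - 0.08 * 8**0.54)
        got = new_formulation(2.5, Q10Spec(), 14.0, 18.0, 8.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1.429, abs=5e-4)

    def test_decline_disabled_reduces_to_standard(self):
        p = DeclineParams.disabled()
        q = Q10Spec(q10_fixed=2.3)
        for T_t, T_s, h in [(10.0, 18.0, 5.0), (18.0, 18.0, 12.0), (25.0, 20.0, 0.0)]:
            assert new_formulation(1.7, q, T_t, T_s, h, p) == pytest.approx(
                standard_model(1.7, q, T_t, T_s), abs=1e-12
            )


class TestJulesLeafResp:
    def test_half_at_upper_limit(self):
        p = JulesRespParams(T_low=-40.0, T_upp=36.0)
        std = standard_model(1.0, Q10Spec(), 36.0, p.T_ref)
        got = jules_leaf_resp(1.0, Q10Spec(), 36.0, p)
        assert got == pytest.approx(std / 2, rel=1e-6)

    def test_half_at_lower_limit(self):
        p = JulesRespParams(T_low=0.0, T_upp=80.0)
        std = standard_model(1.0, Q10Spec(), 0.0, p.T_ref)
        assert jules_leaf_resp(1.0, Q10Spec(), 0.0, p) == pytest.approx(std / 2, rel=1e-6)

    def test_midrange_logistic_oracle(self):
        # both logistic factors evaluated by direct arithmetic
        p = JulesRespParams(T_low=0.0, T_upp=36.0)
        factor = 1.0 / ((1 + np.exp(0.3 * (18 - 36))) * (1 + np.exp(0.3 * (0 - 18))))
        std = standard_model(1.0, Q10Spec(), 18.0, p.T_ref)
        assert jules_leaf_resp(1.0, Q10Spec(), 18.0, p) == pytest.approx(
            factor * std, rel=1e-12
        )
        assert factor == pytest.approx(0.991028, abs=1e-6)

    def test_never_exceeds_standard(self):
        p = JulesRespParams()
        T = np.linspace(-10, 45, 111)
        assert np.all(
            jules_leaf_resp(1.0, Q10Spec(), T, p)
            <= standard_model(1.0, Q10Spec(), T, p.T_ref)
        )

    def test_invalid_limits_rejected(self):
        with pytest.raises(ValueError):
            JulesRespParams(T_low=40.0, T_upp=36.0)


class TestMaintenanceAndGrowth:
    @pytest.mark.parametrize(
        "r, N_r, N_s, N_l, beta, expected",
        [
            (1.0, 0.0, 0.0, 1.0, 1.0, 1.0),
            (1.0, 0.5, 0.5, 1.0, 1.0, 2.0),
            (2.0, 0.5, 0.5, 2.0, 0.8, 2.6),
        ],
    )
    def test_maintenance_values(self, r, N_r, N_s, N_l, beta, expected):
        p = JulesRespParams(N_r=N_r, N_s=N_s, N_l=N_l, beta_sw=beta)
        assert maintenance_resp(r, p) == pytest.approx(expected, abs=1e-12)

    def test_maintenance_homogeneous_degree_one(self):
        p = JulesRespParams(N_r=0.3, N_s=0.7, N_l=1.3, beta_sw=0.6)
        for scale in (0.1, 3.0, 50.0):
            assert maintenance_resp(scale * 1.7, p) == pytest.approx(
                scale * maintenance_resp(1.7, p), rel=1e-14
            )

    def test_invalid_leaf_nitrogen(self):
        with pytest.raises(ValueError):
            JulesRespParams(N_l=0.0)

    @pytest.mark.parametrize(
        "gpp, r_m, expected",
        [(2.0, 2.0, 0.0), (0.0, 1.0, 0.0), (10.0, 2.0, 2.0)],
    )
    def test_growth_values(self, gpp, r_m, expected):
        assert growth_resp(gpp, r_m) == pytest.approx(expected, abs=1e-14)
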
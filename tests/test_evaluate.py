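"""Tests for the four-formulation evaluation statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from nightresp.evaluate import (FORMULATIONS, Formulation, evaluate_trace,
                                one_to_one_stats, simulate_trace,
                                standardized_residuals, taylor_stats)
from nightresp.models import tdq10
from nightresp.synthetic import CoolingSchedule, SpeciesProfile, gen_field_trace, gen_lab_trace

PROFILE = SpeciesProfile(name="sp", true_a=0.08, true_b=0.54,
                         r_initial_mean=2.5, replicate_cv=0.0, q10_inh_true=2.0)
SCHED = CoolingSchedule(kind="linear", T_start=18.0, rate=0.5)


class TestSimulateTrace:
    def test_self_consistency_of_new_formulation(self):
        obs = gen_field_trace(PROFILE, SCHED, duration=8, sampling_min=30,
                              noise_sd=0.0, seed=0)
        sim = simulate_trace(obs, Formulation.from_name("new"))
        np.testing.assert_allclose(sim["predicted"], sim["observed"], atol=1e-12)
        assert sim["predicted"].iloc[0] == 1.0

    def test_standard_on_constant_T_is_flat(self):
        obs = gen_lab_trace(PROFILE, noise_sd=0.0, seed=0)
        sim = simulate_trace(obs, Formulation.from_name("standard"))
        np.testing.assert_allclose(sim["predicted"], 1.0)

    def test_standard_modified_is_tdq10_curve(self):
        obs = gen_field_trace(PROFILE, SCHED, duration=8, sampling_min=60,
                              noise_sd=0.0, seed=0)
        sim = simulate_trace(obs, Formulation.from_name("standard-modified"))
        T = sim["temperature_C"].to_numpy()
        expected = tdq10(T) ** (0.1 * (T - T[0]))
        np.testing.assert_allclose(sim["predicted"], expected, rtol=1e-12)

    def test_missing_temperature_rejected(self):
        obs = gen_lab_trace(PROFILE, noise_sd=0.0, seed=0)
        obs.samples.loc[2, "temperature_C"] = np.nan
        with pytest.raises(ValueError):
            simulate_trace(obs, Formulation.from_name("standard"))


class TestOneToOne:
    def test_identical_series(self):
        obs = 1 - 0.08 * np.arange(9.0) ** 0.54
        res = one_to_one_stats(obs, obs)
        assert res.slope == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)
        assert res.rmse == pytest.approx(0.0, abs=1e-14)

    def test_constant_offset(self):
        obs = 1 - 0.08 * np.arange(9.0) ** 0.54
        res = one_to_one_stats(obs + 0.1, obs)
        assert res.rmse == pytest.approx(0.1, abs=1e-12)
        assert res.slope == pytest.approx(1.0)

    def test_new_formulation_beats_standard_on_decline_traces(self):
        obs = gen_field_trace(PROFILE, SCHED, duration=10, sampling_min=30,
                              noise_sd=0.02, seed=12)
        report = evaluate_trace(obs)
        assert (report.one_to_one["new"].rmse
                < report.one_to_one["standard"].rmse)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            one_to_one_stats([1.0, 0.9, 0.8], [1.0, 0.9, 0.8])  # 2 after exclusion


class TestStandardizedResiduals:
    def test_perfect_prediction_all_zero(self):
        obs = 1 - 0.08 * np.arange(6.0) ** 0.54
        assert np.all(standardized_residuals(obs, obs) == 0.0)

    @pytest.mark.parametrize("N, j, delta", [(5, 2, 0.1), (10, 7, -0.03)])
    def test_single_residual_algebra(self, N, j, delta):
        obs = np.ones(N)
        pred = np.ones(N)
        pred[j] += delta
        S = standardized_residuals(pred, obs)
        # one residual r among zeros with df = N-1 standardizes to ±sqrt(N-1)
        assert S[j] == pytest.approx(np.sign(delta) * np.sqrt(N - 1), rel=1e-12)
        assert np.all(S[np.arange(N) != j] == 0.0)

    def test_no_trend_when_model_matches_generator(self):
        obs = gen_field_trace(PROFILE, SCHED, duration=10, sampling_min=15,
                              noise_sd=0.03, seed=21)
        sim = simulate_trace(obs, Formulation.from_name("new"))
        S = standardized_residuals(sim["predicted"].to_numpy(),
                                   sim["observed"].to_numpy())
        reg = stats.linregress(sim["h"].to_numpy(), S)
        assert abs(reg.slope) < 2 * reg.stderr + 1e-12


class TestTaylor:
    def test_identical_series(self):
        obs = 1 - 0.08 * np.arange(8.0) ** 0.54
        t = taylor_stats(obs, obs)
        assert (t.correlation, t.sd_ratio, t.crmse) == pytest.approx((1.0, 1.0, 0.0))

    def test_scaled_series(self):
        obs = 1 - 0.08 * np.arange(8.0) ** 0.54
        t = taylor_stats(2 * obs, obs)
        assert t.correlation == pytest.approx(1.0)
        assert t.sd_ratio == pytest.approx(2.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            taylor_stats(np.ones(5), np.arange(5.0))

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_taylor_identity(self, seed):
        rng = np.random.default_rng(seed)
        pred, obs = rng.normal(size=12), rng.normal(size=12)
        t = taylor_stats(pred, obs)
        lhs = t.crmse**2
        sd_o = obs.std()
        sd_p = t.sd_ratio * sd_o
        rhs = sd_p**2 + sd_o**2 - 2 * sd_p * sd_o * t.correlation
        assert lhs == pytest.approx(rhs, abs=1e-12)


class TestFormulationSeparation:
    def test_each_formulation_fits_its_own_traces_only(self):
        # noiseless traces generated under each variant; RMSE is zero for the
        # generating variant and positive for every other one
        obs_base = gen_field_trace(PROFILE, SCHED, duration=8, sampling_min=30,
                                   noise_sd=0.0, seed=0)
        for gen_f in FORMULATIONS:
            sim = simulate_trace(obs_base, gen_f)
            synthetic_obs = obs_base.with_samples(
                obs_base.samples.assign(
                    respiration=2.5 * sim["predicted"].to_numpy())
            )
            for test_f in FORMULATIONS:
                rmse = one_to_one_stats(
                    simulate_trace(synthetic_obs, test_f)["predicted"],
                    simulate_trace(synthetic_obs, test_f)["observed"],
                ).rmse
                if test_f.name == gen_f.name:
                    assert rmse == pytest.approx(0.0, abs=1e-10)
                else:
                    assert rmse > 1e-4
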
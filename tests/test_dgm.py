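"""Data-generating mechanism: moment matching, allocation, daily means."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from actitrial import (DesignConfig, EffectScenario, Participant,
                       allocate_arms, assign_winter, daily_mean,
                       moment_match_lognormal, simulate_trial)
from actitrial.exceptions import DesignError, InvalidParameterError


class TestMomentMatching:
    def test_degenerate_point_mass(self):
        assert moment_match_lognormal(1.0, 0.0) == (0.0, 0.0)

    def test_baseline_parameters(self):
        # closed form: s^2 = ln(1 + (52/77)^2), m = ln 77 - s^2/2
        m, s = moment_match_lognormal(77.0, 52.0)
        assert m == pytest.approx(4.155937, abs=1e-5)
        assert s == pytest.approx(0.612973, abs=1e-5)

    @pytest.mark.parametrize("mean,sd", [(77, 52), (46, 46), (10, 2), (200, 30)])
    def test_draws_reproduce_natural_moments(self, mean, sd, rng):
        m, s = moment_match_lognormal(mean, sd)
        x = rng.lognormal(m, s, size=1_000_000)
        assert x.mean() == pytest.approx(mean, rel=0.01)
        assert x.std() == pytest.approx(sd, rel=0.01)

    @given(mean=st.floats(0.5, 500), sd=st.floats(0, 200))
    def test_algebraic_inverse_identity(self, mean, sd):
        m, s = moment_match_lognormal(mean, sd)
        assert np.exp(m + s**2 / 2) == pytest.approx(mean, rel=1e-12)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(InvalidParameterError):
            moment_match_lognormal(0.0, 10.0)
        with pytest.raises(InvalidParameterError):
            moment_match_lognormal(-5.0, 10.0)

    def test_array_input(self):
        m, s = moment_match_lognormal(np.array([77.0, 46.0]), 46.0)
        assert m.shape == (2,)
        np.testing.assert_allclose(np.exp(m + s**2 / 2), [77.0, 46.0])


class TestAllocation:
    @pytest.mark.parametrize("n,ratio,expected_treat", [
        (44, (2, 1), 29),   # round(88/3) = 29, half away from zero
        (44, (1, 1), 22),
        (3, (2, 1), 2),
    ])
    def test_exact_arm_counts(self, n, ratio, expected_treat, rng):
        arm = allocate_arms(n, ratio, rng)
        assert arm.sum() == expected_treat
        assert len(arm) == n

    def test_empty_arm_rejected(self, rng):
        with pytest.raises(DesignError):
            allocate_arms(2, (5, 1), rng)

    def test_assignment_order_is_random(self, rng):
        draws = {tuple(allocate_arms(6, (1, 1), rng)) for _ in range(50)}
        assert len(draws) > 1


class TestWinterAssignment:
    @pytest.mark.parametrize("n,prop,expected", [
        (44, 0.5, 22),
        (44, 0.1, 4),   # round(4.4) = 4
        (44, 0.0, 0),
        (44, 1.0, 44),
    ])
    def test_exact_counts(self, n, prop, expected, rng):
        assert assign_winter(n, prop, rng).sum() == expected

    def test_invalid_proportion(self, rng):
        with pytest.raises(InvalidParameterError):
            assign_winter(10, 1.5, rng)


class TestDailyMean:
    def _participant(self, arm=1, winter=0, baseline=77.0, alpha=0.0):
        return Participant(id=0, arm=arm, winter=winter, baseline=baseline,
                           random_effect=alpha)

    def test_treatment_effect_only(self):
        scen = EffectScenario(delta1=12.5)
        assert daily_mean(self._participant(arm=1), 10, scen) == 89.5

    def test_control_after_week1_is_baseline(self):
        scen = EffectScenario(delta1=12.5, delta2=10, delta3=1, delta4=10, delta5=1)
        assert daily_mean(self._participant(arm=0), 10, scen) == 77.0

    def test_all_effects_sum(self):
        # 77 + 12.5 + 10 + 1 + 10 + 1 within week 1 for a treated winter patient
        scen = EffectScenario(delta1=12.5, delta2=10, delta3=1, delta4=10, delta5=1)
        p = self._participant(arm=1, winter=1)
        assert daily_mean(p, 3, scen) == 111.5

    def test_week1_boundary(self):
        scen = EffectScenario(delta1=0.0, delta4=10)
        p = self._participant(arm=0)
        assert daily_mean(p, 7, scen) == 87.0
        assert daily_mean(p, 8, scen) == 77.0

    def test_floor_applies(self):
        scen = EffectScenario(delta1=0.0)
        p = self._participant(arm=0, baseline=0.5, alpha=-3.0)
        assert daily_mean(p, 10, scen) == 1.0


class TestSimulateTrial:
    def test_default_shape_and_positivity(self, trial):
        assert trial.daily.shape == (44, 28)
        assert (trial.daily > 0).all()
        assert trial.observed_mask.all()
        assert trial.arm.sum() == 29
        assert (trial.baseline > 0).all()

    def test_determinism(self, default_design, null_scenario):
        a = simulate_trial(default_design, null_scenario, seed=42)
        b = simulate_trial(default_design, null_scenario, seed=42)
        np.testing.assert_array_equal(a.daily, b.daily)
        np.testing.assert_array_equal(a.arm, b.arm)
        np.testing.assert_array_equal(a.baseline, b.baseline)
        c = simulate_trial(default_design, null_scenario, seed=43)
        assert not np.array_equal(a.daily, c.daily)

    def test_grand_mean_matches_baselines_under_null(self):
        # all deltas zero, no random effect: E[y_ij | baseline_i] = baseline_i
        design = DesignConfig(n_participants=2000, random_effect_var=1e-12)
        scen = EffectScenario(delta1=0.0)
        ds = simulate_trial(design, scen, seed=11)
        # grand-mean error SD ~ (46/sqrt(28))/sqrt(2000) ~ 0.19
        assert abs(ds.daily.mean() - ds.baseline.mean()) < 3 * 0.2

    def test_expectation_linear_in_effects(self):
        # random_effect_var -> 0: each participant's day-mean converges to mu_i
        design = DesignConfig(n_participants=2, n_followup_days=5000,
                              random_effect_var=1e-12)
        scen = EffectScenario(delta1=12.5)
        ds = simulate_trial(design, scen, seed=5)
        tol = 3 * 46 / np.sqrt(5000)
        for i in range(2):
            expected = ds.baseline[i] + 12.5 * ds.arm[i]
            assert ds.daily[i].mean() == pytest.approx(expected, abs=tol)

    def test_long_frame_roundtrip(self, trial):
        df = trial.to_long_frame()
        assert len(df) == 44 * 28
        assert set(df.columns) == {"participant_id", "arm", "winter", "baseline",
                                   "day", "value", "observed"}
        row = df[(df.participant_id == 3) & (df.day == 5)].iloc[0]
        assert row.value == trial.daily[3, 4]


class TestValidation:
    def test_invalid_design_parameters(self):
        with pytest.raises(InvalidParameterError):
            DesignConfig(n_participants=1)
        with pytest.raises(InvalidParameterError):
            DesignConfig(baseline_sd=0.0)
        with pytest.raises(InvalidParameterError):
            DesignConfig(allocation_ratio=(2, 0))

    def test_interaction_convention(self):
        scen = EffectScenario.with_interaction(delta2=10.0, delta4=4.0)
        assert scen.delta3 == pytest.approx(1.0)
        assert scen.delta5 == pytest.approx(0.4)

    def test_negative_nuisance_effect_flagged(self):
        with pytest.warns(UserWarning):
            EffectScenario(delta2=-1.0)
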
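"""Follow-up summary and the baseline-adjusted ANCOVA fit."""

import numpy as np
import pytest

from actitrial import (ComplianceRule, FollowUpSummary, fit_primary_model,
                       summaries_to_frame, summarize_followup)
from actitrial.exceptions import AnalysisError, EstimabilityError
from tests.test_missingness import make_dataset


def make_rows(y, baseline, arm):
    return [
        FollowUpSummary(participant_id=i, ybar=float(y[i]), n_compliant_days=28,
                        baseline=float(baseline[i]), arm=int(arm[i]))
        for i in range(len(y))
    ]


class TestSummarizeFollowup:
    def test_mean_of_observed_days(self):
        ds = make_dataset([[10.0, 20.0, 30.0, 40.0]] * 4)
        ds.observed_mask[0] = [True, True, True, False]
        rows = summarize_followup(ds, ComplianceRule(min_compliant_days=2))
        assert rows[0].ybar == pytest.approx(20.0)
        assert rows[0].n_compliant_days == 3
        assert rows[1].ybar == pytest.approx(25.0)

    def test_constant_series(self):
        ds = make_dataset(np.full((4, 6), 7.5))
        for row in summarize_followup(ds):
            assert row.ybar == pytest.approx(7.5)

    def test_period_window_restriction(self, trial):
        rows = summarize_followup(trial, ComplianceRule(), period_days=14)
        expected = trial.daily[:, :14].mean(axis=1)
        for row in rows:
            assert row.ybar == pytest.approx(expected[row.participant_id])

    def test_noncompliant_omitted(self, trial):
        trial.observed_mask[5, :] = False
        rows = summarize_followup(trial, ComplianceRule())
        assert len(rows) == 43
        assert all(r.participant_id != 5 for r in rows)

    def test_frame_schema(self, trial):
        df = summaries_to_frame(summarize_followup(trial))
        assert list(df.columns) == ["participant_id", "arm", "winter",
                                    "baseline", "ybar", "n_compliant_days"]
        assert len(df) == 44


class TestPrimaryModel:
    def test_exact_interpolation(self, rng):
        baseline = rng.lognormal(4.0, 0.5, size=20)
        arm = np.r_[np.ones(10), np.zeros(10)]
        y = 5.0 + 1.0 * baseline + 12.5 * arm
        res = fit_primary_model(make_rows(y, baseline, arm))
        assert res.beta0 == pytest.approx(5.0, abs=1e-8)
        assert res.beta1 == pytest.approx(1.0, abs=1e-10)
        assert res.beta2 == pytest.approx(12.5, abs=1e-8)
        assert res.residual_var == pytest.approx(0.0, abs=1e-12)

    def test_identical_outcomes_give_zero_effect(self):
        baseline = np.arange(1.0, 9.0)
        arm = np.r_[np.ones(4), np.zeros(4)]
        y = np.full(8, 50.0)
        res = fit_primary_model(make_rows(y, baseline, arm))
        assert res.beta2 == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(100):
            n = 10
            baseline = rng.lognormal(4.3, 0.6, size=n)
            arm = rng.permutation(np.r_[np.ones(n // 2), np.zeros(n - n // 2)])
            y = 3 + 0.9 * baseline + 10 * arm + rng.normal(0, 5, size=n)
            res = fit_primary_model(make_rows(y, baseline, arm))
            X = np.column_stack([np.ones(n), baseline, arm])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            s2 = ((y - X @ beta) ** 2).sum() / (n - 3)
            se2 = np.sqrt(s2 * np.linalg.inv(X.T @ X)[2, 2])
            assert res.beta2 == pytest.approx(beta[2], rel=1e-8)
            assert res.beta0 == pytest.approx(beta[0], rel=1e-8)
            assert res.se_beta2 == pytest.approx(se2, rel=1e-8)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 30
        baseline = rng.lognormal(4.3, 0.6, size=n)
        arm = rng.permutation(np.r_[np.ones(20), np.zeros(10)])
        y = 3 + 0.9 * baseline + 10 * arm + rng.normal(0, 5, size=n)
        res = fit_primary_model(make_rows(y, baseline, arm))
        X = sm.add_constant(np.column_stack([baseline, arm]))
        fit = sm.OLS(y, X).fit()
        assert res.beta2 == pytest.approx(fit.params[2], rel=1e-10)
        assert res.se_beta2 == pytest.approx(fit.bse[2], rel=1e-10)
        assert res.residual_var == pytest.approx(fit.mse_resid, rel=1e-10)

    def test_order_invariance(self, rng):
        baseline = rng.lognormal(4.3, 0.6, size=12)
        arm = np.r_[np.ones(6), np.zeros(6)]
        y = 3 + baseline + 12 * arm + rng.normal(0, 5, size=12)
        rows = make_rows(y, baseline, arm)
        res1 = fit_primary_model(rows)
        res2 = fit_primary_model(rows[::-1])
        assert res1.beta2 == pytest.approx(res2.beta2, rel=1e-12)
        assert res1.se_beta2 == pytest.approx(res2.se_beta2, rel=1e-12)

    def test_constant_shift_moves_intercept_only(self, rng):
        baseline = rng.lognormal(4.3, 0.6, size=12)
        arm = np.r_[np.ones(6), np.zeros(6)]
        y = 3 + baseline + 12 * arm + rng.normal(0, 5, size=12)
        res = fit_primary_model(make_rows(y, baseline, arm))
        shifted = fit_primary_model(make_rows(y + 100.0, baseline, arm))
        assert shifted.beta0 == pytest.approx(res.beta0 + 100.0, rel=1e-9)
        assert shifted.beta1 == pytest.approx(res.beta1, rel=1e-9)
        assert shifted.beta2 == pytest.approx(res.beta2, rel=1e-9)

    def test_single_arm_rejected(self, rng):
        baseline = rng.lognormal(4.3, 0.6, size=8)
        y = baseline + rng.normal(0, 1, 8)
        with pytest.raises(EstimabilityError):
            fit_primary_model(make_rows(y, baseline, np.ones(8)))

    def test_too_few_rows_rejected(self):
        with pytest.raises(AnalysisError):
            fit_primary_model(make_rows([1.0, 2.0], [1.0, 2.0], [0, 1]))
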
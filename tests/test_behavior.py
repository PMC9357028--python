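"""Trial cleaning, binomial exclusion, SSRT, scoring and transformation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triarchy import behavior


def make_trials(rts, subject=0, task="stroop", condition="congruent", correct=True):
    n = len(rts)
    return pd.DataFrame(
        {
            "subject": subject,
            "task": task,
            "trial": range(n),
            "condition": condition,
            "rt_ms": rts,
            "correct": correct,
            "ssd_ms": np.nan,
        }
    )


class TestExclusionThreshold:
    @pytest.mark.parametrize(
        "n,rate,expected",
        [
            (90, 0.5, 53),  # enumerated binomial CDF: smallest k with P(X<=k) >= 0.95
            (1, 0.5, 1),
            (50, 1e-9, 0),
        ],
    )
    def test_matches_exact_cdf(self, n, rate, expected):
        assert behavior.exclusion_threshold(n, rate) == expected

    def test_matches_brute_force_enumeration(self):
        n, r = 40, 0.25
        cdf = np.cumsum([stats.binom.pmf(k, n, r) for k in range(n + 1)])
        brute = int(np.argmax(cdf >= 0.95))
        assert behavior.exclusion_threshold(n, r) == brute

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            behavior.exclusion_threshold(0, 0.5)
        with pytest.raises(ValueError):
            behavior.exclusion_threshold(10, 1.5)


class TestCleanTrials:
    def test_fast_and_fence_removal(self):
        # {90, 300, 320, 340, 5000}: 90 goes by the 100 ms rule; 5000 by the fences
        trials = make_trials([90.0, 300.0, 320.0, 340.0, 5000.0])
        cleaned, report = behavior.clean_trials(trials, "stroop")
        assert report.n_removed_fast == 1
        kept = cleaned["rt_ms"].tolist()
        q1, q3 = np.percentile([300, 320, 340, 5000], [25, 75])
        iqr = q3 - q1
        expect_5000_removed = 5000 > q3 + 1.5 * iqr
        assert (5000.0 not in kept) == expect_5000_removed

    def test_equal_rts_degenerate_fences(self):
        trials = make_trials([400.0] * 20)
        cleaned, report = behavior.clean_trials(trials, "stroop")
        assert report.n_removed_iqr == 0
        assert len(cleaned) == 20

    def test_no_response_exclusion(self):
        rts = [300.0] * 15 + [np.nan] * 5  # 25% missing responses
        trials = make_trials(rts)
        _, report = behavior.clean_trials(trials, "stroop")
        assert 0 in report.excluded_no_response

    def test_below_chance_subject_flagged(self):
        rng = np.random.default_rng(0)
        trials = make_trials(rng.uniform(300, 600, 90).tolist(), correct=False)
        trials["correct"] = rng.random(90) < 0.3  # below the 50% chance level
        _, report = behavior.clean_trials(trials, "number_letter")
        assert 0 in report.excluded_accuracy

    def test_empty_input_warns(self):
        out, report = behavior.clean_trials(make_trials([]), "stroop")
        assert out.empty and report.warnings


class TestSSRT:
    def _stop_frame(self, go_rts, n_nogo_resp, n_nogo, ssd):
        rows = []
        for i, rt in enumerate(go_rts):
            rows.append((0, "stop_signal", i, "go", rt, True, np.nan))
        for i in range(n_nogo):
            responded = i < n_nogo_resp
            rows.append((0, "stop_signal", 100 + i, "nogo",
                         400.0 if responded else np.nan, not responded, ssd))
        return pd.DataFrame(rows, columns=["subject", "task", "trial", "condition",
                                           "rt_ms", "correct", "ssd_ms"])

    def test_worked_example(self):
        # p = 0.4 -> 2nd of 5 sorted Go RTs (nearest rank) = 400; SSRT = 400 - 200
        trials = self._stop_frame([300, 400, 500, 600, 700], n_nogo_resp=4, n_nogo=10, ssd=200)
        ssrt, warns = behavior.compute_ssrt(trials)
        assert ssrt == pytest.approx(200.0)
        assert not warns

    def test_zero_when_percentile_equals_delay(self):
        trials = self._stop_frame([250, 250, 250], n_nogo_resp=2, n_nogo=4, ssd=250)
        ssrt, _ = behavior.compute_ssrt(trials)
        assert ssrt == pytest.approx(0.0)

    def test_degenerate_stop_rate_warns(self):
        trials = self._stop_frame([300, 400], n_nogo_resp=0, n_nogo=5, ssd=200)
        _, warns = behavior.compute_ssrt(trials)
        assert warns

    def test_requires_both_trial_types(self):
        with pytest.raises(ValueError):
            behavior.compute_ssrt(self._stop_frame([], n_nogo_resp=1, n_nogo=2, ssd=100))


class TestScoring:
    def test_dprime_worked_example(self):
        assert behavior.dprime(0.8, 0.2, 30, 60) == pytest.approx(1.683, abs=5e-4)

    def test_dprime_zero_when_rates_equal(self):
        assert behavior.dprime(0.4, 0.4, 30, 60) == pytest.approx(0.0)

    def test_switch_cost_arithmetic(self):
        rows = []
        for i in range(10):
            rows.append((0, "number_letter", i, "switch", 900.0, True, np.nan))
            rows.append((0, "number_letter", 10 + i, "repeat", 800.0, True, np.nan))
        trials = pd.DataFrame(rows, columns=["subject", "task", "trial", "condition",
                                             "rt_ms", "correct", "ssd_ms"])
        s = behavior.score_task(trials, "number_letter")
        assert s[0] == pytest.approx(100.0)

    def test_rt_uses_correct_trials_only(self):
        rows = [
            (0, "number_letter", 0, "switch", 900.0, True, np.nan),
            (0, "number_letter", 1, "switch", 5000.0, False, np.nan),
            (0, "number_letter", 2, "repeat", 800.0, True, np.nan),
        ]
        trials = pd.DataFrame(rows, columns=["subject", "task", "trial", "condition",
                                             "rt_ms", "correct", "ssd_ms"])
        assert behavior.score_task(trials, "number_letter")[0] == pytest.approx(100.0)

    def test_missing_condition_gives_nan(self):
        trials = make_trials([300.0] * 5, task="number_letter", condition="switch")
        assert np.isnan(behavior.score_task(trials, "number_letter")[0])


class TestFinalize:
    def test_arcsine_boundary(self):
        raw = pd.DataFrame({"antisaccade": [0.0, 0.5]})  # error rates
        out = behavior.finalize_scores(raw)
        assert out["antisaccade"].iloc[0] == pytest.approx(np.pi / 2)

    def test_keeptrack_logit_midpoint(self):
        raw = pd.DataFrame({"keep_track": [18.0, 10.0, 30.0]})  # 18/36 -> prop 0.5
        out = behavior.finalize_scores(raw, keep_track_max=36)
        assert out["keep_track"].iloc[0] == pytest.approx(
            np.log(18.5 / 37 / (1 - 18.5 / 37))
        )

    def test_truncation_at_median_fences(self):
        col = pd.Series([-1.0, 0.0, 1.0, 5.0])
        out = behavior._truncate_column(col)
        med = col.median()
        q1, q3 = col.quantile([0.25, 0.75])
        hi = med + 1.5 * (q3 - q1)
        assert out.max() == pytest.approx(hi)

    def test_rt_measures_negated(self):
        raw = pd.DataFrame({"ssrt": [200.0, 250.0]})
        out = behavior.finalize_scores(raw)
        assert out["ssrt"].iloc[0] > out["ssrt"].iloc[1]

    def test_idempotent_on_truncated_data(self):
        rng = np.random.default_rng(3)
        raw = pd.DataFrame({"ssrt": rng.normal(200, 30, 200)})
        once = behavior.finalize_scores(raw)
        # feed the already-negated values back through truncation only
        twice = once.apply(behavior._truncate_column)
        pd.testing.assert_frame_equal(once, twice)


class TestResidualize:
    def test_output_standardized(self):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame({"a": rng.normal(size=300), "b": rng.normal(size=300)})
        cov = pd.DataFrame({"age": rng.uniform(17, 31, 300), "sex": rng.integers(0, 2, 300)})
        out = behavior.residualize_scores(scores, cov)
        assert abs(out["a"].mean()) < 1e-10 and abs(out["a"].std(ddof=0) - 1) < 1e-10

    def test_residual_uncorrelated_with_covariate(self):
        rng = np.random.default_rng(1)
        cov = pd.DataFrame({"age": rng.uniform(17, 31, 500), "sex": rng.integers(0, 2, 500)})
        scores = pd.DataFrame({"a": 2.0 * cov["age"] + rng.normal(size=500)})
        out = behavior.residualize_scores(scores, cov)
        assert abs(np.corrcoef(out["a"], cov["age"])[0, 1]) < 1e-10

    def test_pure_covariate_score_degenerates(self):
        cov = pd.DataFrame({"age": np.linspace(17, 31, 100), "sex": np.tile([0, 1], 50)})
        scores = pd.DataFrame({"a": 2.0 * cov["age"]})
        out = behavior.residualize_scores(scores, cov)
        assert np.nanmax(np.abs(out["a"])) < 1e-8

    def test_rank_deficient_rejected(self):
        cov = pd.DataFrame({"age": np.ones(50), "sex": np.ones(50)})
        with pytest.raises(ValueError):
            behavior.residualize_scores(pd.DataFrame({"a": np.zeros(50)}), cov)

    def test_missing_entries_passed_through(self):
        rng = np.random.default_rng(2)
        scores = pd.DataFrame({"a": rng.normal(size=100)})
        scores.loc[::10, "a"] = np.nan
        cov = pd.DataFrame({"age": rng.uniform(17, 31, 100), "sex": rng.integers(0, 2, 100)})
        out = behavior.residualize_scores(scores, cov)
        assert out["a"].isna().sum() == scores["a"].isna().sum()
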
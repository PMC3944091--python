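"""Kaplan-Meier, log-rank, Cox PH, and DMFS endpoint encoding."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter

from prolifsig import (
    cox_fit,
    cox_forward_wald,
    encode_dmfs,
    event_free_percent,
    km_estimate,
    logrank_test,
    survival_at,
)
from prolifsig.survival import CoxConvergenceError
from oracles import cox_grid_oracle, km_oracle, logrank_oracle


def records(times, events, ids=None):
    ids = ids or [f"p{i}" for i in range(len(times))]
    return pd.DataFrame({"time": np.asarray(times, float), "event": events}, index=ids)


class TestEncodeDmfs:
    def test_precoded_table_passthrough(self):
        clin = pd.DataFrame({"follow_up": [10.0, 20.0], "dmfs_event": [1, 0]},
                            index=["a", "b"])
        rec = encode_dmfs(clin)
        assert rec.loc["a", "event"] == 1 and rec.loc["b", "event"] == 0

    def test_other_cause_death_censors_at_that_date(self):
        clin = pd.DataFrame(
            {"follow_up": [55.0], "event_type": ["other_death"]}, index=["a"]
        )
        rec = encode_dmfs(clin)
        assert rec.loc["a", "event"] == 0
        assert rec.loc["a", "time"] == 55.0

    def test_metastasis_without_recurrence_date_uses_last_followup(self):
        clin = pd.DataFrame(
            {
                "follow_up": [80.0, 90.0],
                "event_type": ["distant_metastasis", "distant_metastasis"],
                "recurrence_time": [np.nan, 60.0],
            },
            index=["a", "b"],
        )
        rec = encode_dmfs(clin)
        assert rec.loc["a", "event"] == 1 and rec.loc["a", "time"] == 80.0
        assert rec.loc["b", "event"] == 1 and rec.loc["b", "time"] == 60.0

    @pytest.mark.parametrize(
        "etype", ["locoregional", "second_primary", "contralateral", "none"]
    )
    def test_non_distant_events_censor(self, etype):
        clin = pd.DataFrame({"follow_up": [33.0], "event_type": [etype]}, index=["a"])
        assert encode_dmfs(clin).loc["a", "event"] == 0

    def test_missing_followup_listed(self):
        clin = pd.DataFrame({"follow_up": [np.nan], "dmfs_event": [1]}, index=["bad1"])
        with pytest.raises(ValueError, match="bad1"):
            encode_dmfs(clin)

    def test_synthetic_cohort_events_match_generator_truth(self, small_cohort):
        rec = encode_dmfs(small_cohort.clinical)
        observed = rec[rec["event"] == 1]
        # where the generator recorded an event, the observed time is the
        # true (uncensored) event time
        truth = small_cohort.truth.loc[observed.index, "true_event_time"]
        assert np.allclose(observed["time"], truth, atol=1e-3)


class TestKaplanMeier:
    def test_two_events_halve_then_zero(self):
        curve = km_estimate(records([1.0, 2.0], [1, 1]))
        assert curve.survival.tolist() == [0.5, 0.0]

    def test_event_then_censor_keeps_half(self):
        curve = km_estimate(records([1.0, 2.0], [1, 0]))
        assert curve.survival.tolist() == [0.5]
        assert survival_at(curve, 2.0) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(records([], []))

    def test_matches_independent_product_limit_oracle(self, toy_records):
        curve = km_estimate(toy_records)
        o_t, o_s = km_oracle(toy_records["time"], toy_records["event"])
        assert np.allclose(curve.event_times, o_t)
        assert np.allclose(curve.survival, o_s, atol=1e-12)

    def test_matches_lifelines(self, toy_records):
        curve = km_estimate(toy_records)
        kmf = KaplanMeierFitter().fit(toy_records["time"], toy_records["event"])
        for t, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(float(kmf.survival_function_at_times(t).iloc[0]))

    def test_at_risk_counts_non_increasing(self, toy_records):
        curve = km_estimate(toy_records)
        assert np.all(np.diff(curve.at_risk) <= 0)


class TestSurvivalAt:
    def test_before_first_event_is_one(self, toy_records):
        curve = km_estimate(toy_records)
        assert survival_at(curve, 0.0) == 1.0
        assert survival_at(curve, curve.event_times[0] - 0.5) == 1.0

    def test_beyond_last_event_is_last_step(self, toy_records):
        curve = km_estimate(toy_records)
        assert survival_at(curve, 1e9) == pytest.approx(curve.survival[-1])

    def test_no_censoring_identity(self):
        # all-event data: survival beyond last event equals 1 - events/n
        times = [3.0, 1.0, 7.0, 2.0, 9.0, 4.0]
        curve = km_estimate(records(times, [1] * 6))
        assert survival_at(curve, 100.0) == pytest.approx(0.0)
        # partial events, but no censoring before the last event time
        curve = km_estimate(records([1, 2, 3, 4, 50, 60], [1, 1, 1, 1, 0, 0]))
        assert survival_at(curve, 10.0) == pytest.approx(1 - 4 / 6)


class TestLogrank:
    def test_identical_groups_give_zero_chi2(self):
        g = records([5.0, 8.0, 12.0, 20.0], [1, 0, 1, 0])
        chi2, p = logrank_test([g, g.copy()])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_hypergeometric_accumulation(self, rng):
        t1 = rng.exponential(30, 15).round() + 1
        t2 = rng.exponential(15, 15).round() + 1
        e1 = rng.integers(0, 2, 15)
        e2 = rng.integers(0, 2, 15)
        e1[0] = e2[0] = 1
        chi2, _ = logrank_test([records(t1, e1), records(t2, e2)])
        assert chi2 == pytest.approx(logrank_oracle(t1, e1, t2, e2), abs=1e-8)

    def test_invariant_under_group_relabeling(self, toy_records):
        a, b = toy_records.iloc[:10], toy_records.iloc[10:]
        chi2_ab, _ = logrank_test([a, b])
        chi2_ba, _ = logrank_test([b, a])
        assert chi2_ab == pytest.approx(chi2_ba, abs=1e-12)

    def test_empty_group_rejected(self, toy_records):
        with pytest.raises(ValueError):
            logrank_test([toy_records, toy_records.iloc[:0]])


class TestCoxFit:
    def test_mirror_groups_give_null_coefficient(self):
        rec = records([1, 2, 3, 4, 1, 2, 3, 4], [1, 1, 0, 1, 1, 1, 0, 1])
        cov = pd.DataFrame({"x": [0, 0, 0, 0, 1, 1, 1, 1]}, index=rec.index, dtype=float)
        fit = cox_fit(cov, rec)
        assert fit.coefficients["x"] == pytest.approx(0.0, abs=1e-8)
        assert fit.hr["x"] == pytest.approx(1.0, abs=1e-8)

    def test_eight_records_match_grid_search_oracle(self):
        times = np.array([5.0, 8.0, 12.0, 16.0, 20.0, 24.0, 30.0, 40.0])
        events = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        x = np.array([1.2, -0.5, 0.5, 0.8, -0.1, -0.4, 0.3, -0.9])
        rec = records(times, events)
        cov = pd.DataFrame({"x": x}, index=rec.index)
        fit = cox_fit(cov, rec)
        oracle = cox_grid_oracle(x, times, events)
        assert fit.coefficients["x"] == pytest.approx(oracle, abs=1e-4)

    def test_matches_lifelines_on_tie_free_data(self, rng):
        n = 80
        x = rng.normal(size=n)
        t = rng.exponential(scale=np.exp(-0.8 * x))
        e = (t < np.quantile(t, 0.8)).astype(int)
        rec = records(t, e)
        cov = pd.DataFrame({"x": x}, index=rec.index)
        fit = cox_fit(cov, rec)  # no ties: Breslow == Efron
        df = pd.DataFrame({"t": t, "e": e, "x": x})
        ll = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert fit.coefficients["x"] == pytest.approx(ll.params_["x"], abs=1e-5)
        assert fit.se["x"] == pytest.approx(ll.standard_errors_["x"], abs=1e-5)
        assert fit.ci95.loc["x", "lower"] == pytest.approx(
            np.exp(ll.params_["x"] - 1.96 * ll.standard_errors_["x"]), rel=1e-4
        )

    def test_efron_option_matches_lifelines_with_ties(self, rng):
        n = 60
        x = rng.normal(size=n)
        t = np.ceil(rng.exponential(scale=10 * np.exp(-0.5 * x)))
        e = rng.integers(0, 2, n)
        e[:10] = 1
        rec = records(t, e)
        cov = pd.DataFrame({"x": x}, index=rec.index)
        fit = cox_fit(cov, rec, ties="efron")
        df = pd.DataFrame({"t": t, "e": e, "x": x})
        ll = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert fit.coefficients["x"] == pytest.approx(ll.params_["x"], abs=1e-4)

    def test_constant_covariate_rejected(self, toy_records):
        cov = pd.DataFrame({"x": 1.0}, index=toy_records.index)
        with pytest.raises(ValueError, match="x"):
            cox_fit(cov, toy_records)

    def test_complete_separation_detected(self):
        # the covariate perfectly orders events before censorings
        rec = records([1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 0])
        cov = pd.DataFrame({"x": [1, 1, 1, 0, 0, 0]}, index=rec.index, dtype=float)
        with pytest.raises(CoxConvergenceError):
            cox_fit(cov, rec)


class TestStepwise:
    def _sim(self, rng, n=150):
        strong = rng.normal(size=n)
        null = rng.normal(size=n)
        t = rng.exponential(scale=np.exp(-1.0 * strong))
        e = (t < np.quantile(t, 0.7)).astype(int)
        rec = records(t, e)
        cov = pd.DataFrame({"strong": strong, "null": null}, index=rec.index)
        return cov, rec

    def test_forward_keeps_only_the_real_predictor(self, rng):
        cov, rec = self._sim(rng)
        fit = cox_forward_wald(cov, rec, p_enter=0.05, direction="forward")
        assert fit.included == ["strong"]
        assert fit.trace and fit.trace[0].startswith("+strong")

    def test_backward_drops_the_null_predictor(self, rng):
        cov, rec = self._sim(rng)
        fit = cox_forward_wald(cov, rec, p_enter=0.05, direction="backward")
        assert fit.included == ["strong"]

    def test_empty_candidates_rejected(self, toy_records):
        with pytest.raises(ValueError):
            cox_forward_wald(pd.DataFrame(index=toy_records.index), toy_records)

    def test_all_null_candidates_rarely_enter(self, rng):
        entered = 0
        reps = 30
        for _ in range(reps):
            n = 60
            t = rng.exponential(size=n)
            e = np.ones(n, dtype=int)
            rec = records(t, e)
            cov = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)},
                               index=rec.index)
            try:
                cox_forward_wald(cov, rec, p_enter=0.05)
                entered += 1
            except CoxConvergenceError:
                pass
        # familywise null entry rate for two candidates is ~10%; allow slack
        assert entered <= reps * 0.35


class TestEventFreePercent:
    @pytest.mark.parametrize(
        "events,at_risk,expected",
        [(6, 45, 87), (17, 49, 65), (0, 10, 100), (1, 8, 88), (10, 10, 0)],
    )
    def test_values(self, events, at_risk, expected):
        assert event_free_percent(events, at_risk) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            event_free_percent(1, 0)
        with pytest.raises(ValueError):
            event_free_percent(5, 4)
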
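"""Survival-analysis tests against from-definition oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from melatil.config import GeneratorConfig
from melatil.generator import simulate_cohort
from melatil.survival import (
    cox_fit,
    km_fit,
    km_survival_at,
    logrank_test,
    reverse_km_median_followup,
    subgroup_analysis,
)

from oracles import (
    cox_binary_profile_oracle,
    km_product_oracle,
    logrank_permutation_distribution,
    logrank_score_oracle,
)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        curve = km_fit([1, 2, 3, 4], [1, 1, 0, 1])
        assert list(curve.event_times) == [1, 2, 4]
        assert curve.survival == pytest.approx([0.75, 0.50, 0.0])

    def test_all_censored_is_flat_one(self):
        curve = km_fit([1, 2, 3], [0, 0, 0])
        assert curve.event_times.size == 0
        est, _ = km_survival_at(curve, 2.5)
        assert est == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_fit([], [])

    def test_survival_at_lookup(self):
        curve = km_fit([1, 2, 3, 4], [1, 1, 0, 1])
        assert km_survival_at(curve, 0.0)[0] == 1.0
        assert km_survival_at(curve, 2.5)[0] == pytest.approx(0.50)
        est, (lo, hi) = km_survival_at(curve, 1.0)
        assert est == pytest.approx(0.75)
        assert 0 <= lo <= est <= hi <= 1

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, data):
        n = data.draw(st.integers(1, 12))
        times = data.draw(
            st.lists(st.integers(1, 8), min_size=n, max_size=n)
        )
        events = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        if sum(events) == 0:
            events[0] = 1
        curve = km_fit([float(t) for t in times], events)
        o_times, o_surv = km_product_oracle(times, events)
        assert curve.event_times == pytest.approx(o_times)
        assert curve.survival == pytest.approx(o_surv)

    def test_greenwood_ci_brackets_estimate(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5, 200)
        e = (rng.random(200) < 0.7).astype(int)
        curve = km_fit(t, e)
        assert np.all(curve.ci_lower <= curve.survival + 1e-9)
        assert np.all(curve.survival <= curve.ci_upper + 1e-9)
        assert np.all((curve.ci_lower >= 0) & (curve.ci_upper <= 1))
        assert np.all(curve.variance >= 0)
        assert np.all(np.diff(curve.survival) <= 1e-12)

    def test_brisk_beats_absent_at_five_years(self, default_cohort):
        sub = default_cohort
        brisk = sub[sub.til_grade == "brisk"]
        absent = sub[sub.til_grade == "absent"]
        s_brisk, _ = km_survival_at(km_fit(brisk.os_years, brisk.event), 5.0)
        s_absent, _ = km_survival_at(km_fit(absent.os_years, absent.event), 5.0)
        assert s_brisk > s_absent


class TestLogRank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 4.0, 5.0]
        e = [1, 0, 1, 1, 0]
        res = logrank_test([(t, e), (t, e)])
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)
        assert res.df == 1

    def test_matches_score_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n1, n2 = rng.integers(3, 9, 2)
            t1 = rng.exponential(3, n1).round(1) + 0.1
            t2 = rng.exponential(5, n2).round(1) + 0.1
            e1 = (rng.random(n1) < 0.8).astype(int)
            e2 = (rng.random(n2) < 0.8).astype(int)
            if e1.sum() + e2.sum() == 0:
                continue
            res = logrank_test([(t1, e1), (t2, e2)])
            oracle = logrank_score_oracle(t1, e1, t2, e2)
            assert res.chi2 == pytest.approx(oracle, rel=1e-6, abs=1e-9)

    def test_exhaustive_permutation_oracle_small_n(self):
        """On n<=8 instances the observed statistic equals the oracle's
        value for the observed labeling and sits inside the exhaustive
        permutation distribution."""
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        events = [1, 1, 0, 1, 1, 0, 1, 1]
        n1 = 4
        obs = logrank_test([(times[:n1], events[:n1]), (times[n1:], events[n1:])])
        dist = logrank_permutation_distribution(times, events, n1)
        oracle_obs = logrank_score_oracle(
            times[:n1], events[:n1], times[n1:], events[n1:]
        )
        assert obs.chi2 == pytest.approx(oracle_obs, rel=1e-6)
        assert min(dist) - 1e-9 <= obs.chi2 <= max(dist) + 1e-9

    def test_three_group_df(self):
        rng = np.random.default_rng(2)
        groups = [
            (rng.exponential(3, 20), np.ones(20, dtype=int)) for _ in range(3)
        ]
        res = logrank_test(groups)
        assert res.df == 2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([([1.0], [1]), ([], [])])


class TestReverseKM:
    def test_all_censored_at_three_years(self):
        fu = reverse_km_median_followup([3.0] * 10, [0] * 10)
        assert fu.median_followup_years == pytest.approx(3.0)

    def test_toy_inverted_indicator(self):
        # censoring-distribution KM: censorings at 1,2 are its events;
        # deaths at 3,4 are censored for it. G(1)=0.75, G(2)=0.5 -> median 2
        fu = reverse_km_median_followup([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1])
        assert fu.median_followup_years == pytest.approx(2.0)

    def test_default_cohort_near_three_years(self, default_cohort):
        fu = reverse_km_median_followup(
            default_cohort.os_years, default_cohort.event
        )
        assert abs(fu.median_followup_years - 3.1) <= 0.5


class TestCox:
    def test_single_binary_recovery(self):
        cfg = GeneratorConfig(n_patients=1, seed=0)
        rng = np.random.default_rng(4)
        n = 10000
        x = rng.random(n) < 0.5
        rate = 0.1 * np.exp(math.log(2.0) * x)
        t = rng.exponential(1 / rate)
        cohort = pd.DataFrame(
            {
                "sex": np.where(x, "male", "female"),
                "os_years": t,
                "event": 1,
            }
        )
        res = cox_fit(cohort, ["sex"], adjustment="univariable")
        term = res.terms["sex_male"]
        assert abs(term.coef - math.log(2.0)) <= 3 * term.se
        assert term.ci_lower < term.hr < term.ci_upper

    def test_matches_profile_oracle_small_n(self):
        """On tiny tie-free instances the fit equals the closed-form score
        root for a single binary covariate."""
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 8:
            n = int(rng.integers(4, 7))
            t = np.round(rng.exponential(3, n), 3)
            if len(set(t)) < n:
                continue
            x = (rng.random(n) < 0.5).astype(int)
            if x.sum() in (0, n):
                continue
            beta = cox_binary_profile_oracle(t, np.ones(n, dtype=int), x)
            if not np.isfinite(beta) or abs(beta) > 5:
                continue
            cohort = pd.DataFrame(
                {
                    "sex": np.where(x == 1, "male", "female"),
                    "os_years": t,
                    "event": 1,
                }
            )
            res = cox_fit(cohort, ["sex"], adjustment="univariable")
            # lifelines' Newton stop rule leaves ~1e-4 slack around the root
            assert res.terms["sex_male"].coef == pytest.approx(beta, abs=1e-3)
            checked += 1

    def test_null_covariate_ci_coverage(self):
        """A covariate independent of hazard: 95% CI covers HR=1 in at
        least 92 of 100 replicates."""
        rng = np.random.default_rng(6)
        covered = 0
        for _ in range(100):
            n = 300
            x = rng.random(n) < 0.5
            t = rng.exponential(5, n)
            c = rng.exponential(8, n)
            cohort = pd.DataFrame(
                {
                    "sex": np.where(x, "male", "female"),
                    "os_years": np.minimum(t, c),
                    "event": (t <= c).astype(int),
                }
            )
            term = cox_fit(cohort, ["sex"], adjustment="univariable").terms["sex_male"]
            covered += term.ci_lower <= 1.0 <= term.ci_upper
        assert covered >= 92

    def test_multivariable_drops_unknown_breslow(self, default_cohort):
        res = cox_fit(default_cohort, [], adjustment="multivariable")
        expected_n = int(
            (default_cohort.breslow_mm.notna() & default_cohort.mitotic_rate.notna()).sum()
        )
        assert res.n_used == expected_n
        assert res.terms["til_brisk"].hr < 1.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cox_fit(pd.DataFrame(), [], adjustment="multivariable")


class TestSubgroups:
    def test_single_stratum_unadjusted(self, default_cohort):
        cohort = default_cohort.assign(constant="all")
        res = subgroup_analysis(cohort, "constant")
        assert len(res) == 1
        assert res[0].p_adjusted == pytest.approx(res[0].logrank.p)

    def test_bonferroni_arithmetic(self, default_cohort):
        strata = subgroup_analysis(default_cohort, "t_stage_true")
        m = len(strata)
        assert m >= 2
        for s in strata:
            assert s.p_adjusted == pytest.approx(min(1.0, m * s.logrank.p))

    def test_sex_strata_both_tested(self, default_cohort):
        strata = subgroup_analysis(default_cohort, "sex")
        assert {s.stratum for s in strata} == {"female", "male"}
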
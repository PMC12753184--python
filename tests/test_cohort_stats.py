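"""Tests of the survival / matched case-control statistics.

Brute-force oracles: the conditional-logistic likelihood is maximised by
golden-section search per test, and small-sample rank tests are checked
against explicit enumeration.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from dcistil.cohort_stats import (
    conditional_logistic,
    cox_fit,
    crosstab_summary,
    interaction_test,
    km_estimate,
    lrt_compare,
    match_case_control,
    rank_tests,
    spearman,
)
from dcistil.exceptions import (
    InsufficientDataError,
    NonNestedModelError,
    UndefinedORError,
    UnknownFieldError,
)
from dcistil.synthetic_cohort import CohortSimSpec, simulate_cohort


def _cohort_two_groups(rng, n_per_arm, rate_low, rate_high, censor=np.inf):
    """Exponential two-group survival data as a minimal cohort table."""
    t_low = rng.exponential(1 / rate_low, n_per_arm)
    t_high = rng.exponential(1 / rate_high, n_per_arm)
    times = np.concatenate([t_low, t_high])
    observed = np.minimum(times, censor)
    event = np.where(times <= censor, "DCIS-IBE", "none")
    return pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(2 * n_per_arm)],
        "category": ["low"] * n_per_arm + ["high"] * n_per_arm,
        "time": observed, "event": event})


class TestKaplanMeier:
    def test_hand_product_limit(self):
        """Events at 1, 2, 3 and a censor at 4: S(3) = (3/4)(2/3)(1/2)."""
        km = km_estimate([1, 2, 3, 4], [1, 1, 1, 0], horizon=3)
        assert km.survival_at_horizon == 0.25
        assert km.event_rate == 0.75

    def test_no_events_flat_curve(self):
        km = km_estimate([2, 3, 5], [0, 0, 0], horizon=4)
        assert km.survival_at_horizon == 1.0

    def test_all_events_at_one(self):
        km = km_estimate([1, 1, 1], [1, 1, 1], horizon=1)
        assert km.survival_at_horizon == 0.0

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(2.0, 40)
        km = km_estimate(times, np.ones(40), horizon=float(np.median(times)))
        empirical = (times > np.median(times)).mean()
        assert km.survival_at_horizon == pytest.approx(empirical, abs=1e-12)

    def test_horizon_beyond_follow_up_flagged(self):
        km = km_estimate([1, 2], [1, 0], horizon=10)
        assert km.horizon_truncated


class TestCoxFit:
    def test_exponential_rate_ratio_recovery(self, rng):
        """Two-group exponential data with rates lambda and 2*lambda gives
        an HR estimate near 2 (closed-form rate ratio)."""
        cohort = _cohort_two_groups(rng, 2000, 0.1, 0.2)
        fit = cox_fit(cohort, "DCIS-IBE", ["category"])
        assert 1.85 <= fit.terms[0].hr <= 2.16

    def test_null_ci_contains_one(self, rng):
        cohort = _cohort_two_groups(rng, 2000, 0.1, 0.1)
        term = cox_fit(cohort, "DCIS-IBE", ["category"]).terms[0]
        assert term.ci_low <= 1.0 <= term.ci_high

    def test_orthogonal_noise_covariate_collapsible(self, rng):
        """An independent noise covariate moves the TIL HR by < 5%."""
        cohort = _cohort_two_groups(rng, 2500, 0.1, 0.2)
        cohort["noise"] = rng.normal(size=len(cohort))
        hr_alone = cox_fit(cohort, "DCIS-IBE", ["category"]).terms[0].hr
        hr_joint = cox_fit(cohort, "DCIS-IBE",
                           ["category", "noise"]).term("category_high").hr
        assert abs(hr_joint - hr_alone) / hr_alone < 0.05

    def test_too_few_events_rejected(self):
        df = pd.DataFrame({"patient_id": ["a", "b"],
                           "category": ["low", "high"],
                           "time": [1.0, 2.0], "event": ["none", "none"]})
        with pytest.raises(InsufficientDataError):
            cox_fit(df, "IBE", ["category"])

    def test_constant_covariate_rejected(self, rng):
        cohort = _cohort_two_groups(rng, 50, 0.1, 0.2)
        cohort["category"] = "high"
        with pytest.raises(InsufficientDataError):
            cox_fit(cohort, "DCIS-IBE", ["category"])

    def test_cause_specific_censoring(self, rng):
        """Events of the competing cause count as censored, so each
        cause-specific fit sees only its own events."""
        spec = CohortSimSpec(n=800, seed=11)
        cohort, truth = simulate_cohort(spec)
        fit_d = cox_fit(cohort, "DCIS-IBE", ["category"])
        fit_i = cox_fit(cohort, "I-IBE", ["category"])
        assert fit_d.n_events == truth.n_events_dcis
        assert fit_i.n_events == truth.n_events_invasive


class TestLRT:
    def test_identical_models_zero(self, rng):
        cohort = _cohort_two_groups(rng, 200, 0.1, 0.2)
        fit = cox_fit(cohort, "DCIS-IBE", ["category"])
        res = lrt_compare(fit, fit)
        assert res.delta_chi2 == 0.0
        assert res.p == 1.0

    def test_df_counts_added_terms(self, rng):
        cohort = _cohort_two_groups(rng, 300, 0.1, 0.2)
        cohort["noise"] = rng.normal(size=len(cohort))
        reduced = cox_fit(cohort, "DCIS-IBE", ["noise"])
        full = cox_fit(cohort, "DCIS-IBE", ["noise", "category"])
        assert lrt_compare(full, reduced).df == 1

    def test_additivity_over_nested_chain(self, rng):
        """chi2(A->C) = chi2(A->B) + chi2(B->C) for nested A in B in C."""
        cohort = _cohort_two_groups(rng, 400, 0.1, 0.2)
        cohort["x1"] = rng.normal(size=len(cohort))
        cohort["x2"] = rng.normal(size=len(cohort))
        fa = cox_fit(cohort, "DCIS-IBE", ["category"])
        fb = cox_fit(cohort, "DCIS-IBE", ["category", "x1"])
        fc = cox_fit(cohort, "DCIS-IBE", ["category", "x1", "x2"])
        ab = lrt_compare(fb, fa).delta_chi2
        bc = lrt_compare(fc, fb).delta_chi2
        ac = lrt_compare(fc, fa).delta_chi2
        assert ac == pytest.approx(ab + bc, abs=1e-6)

    def test_power_under_planted_alternative(self, rng):
        """Median delta-chi2 over repeated simulations with a planted
        effect exceeds the 3.84 significance bar."""
        deltas = []
        for rep in range(60):
            cohort = _cohort_two_groups(
                np.random.default_rng(rep), 150, 0.1, 0.2)
            cohort["noise"] = np.random.default_rng(1000 + rep).normal(
                size=len(cohort))
            reduced = cox_fit(cohort, "DCIS-IBE", ["noise"])
            full = cox_fit(cohort, "DCIS-IBE", ["noise", "category"])
            deltas.append(lrt_compare(full, reduced).delta_chi2)
        assert np.median(deltas) > 3.84

    def test_non_nested_rejected(self, rng):
        cohort = _cohort_two_groups(rng, 200, 0.1, 0.2)
        cohort["noise"] = rng.normal(size=len(cohort))
        f1 = cox_fit(cohort, "DCIS-IBE", ["category"])
        f2 = cox_fit(cohort, "DCIS-IBE", ["noise"])
        with pytest.raises(NonNestedModelError):
            lrt_compare(f1, f2)


class TestInteraction:
    def test_subgroup_matches_joint_model(self):
        """Stratified subgroup HRs agree with exp(beta_b) and
        exp(beta_b + beta_ab) from the joint model within 2%."""
        spec = CohortSimSpec(
            n=3000, seed=21,
            log_hr_dcis={"category": 0.4, "radiotherapy": -0.8},
            log_hr_invasive={"category": 0.4, "radiotherapy": -0.8},
            interaction_dcis=-0.7, interaction_invasive=-0.7)
        cohort, _ = simulate_cohort(spec)
        res = interaction_test(cohort, "IBE", "category", "radiotherapy")
        for key in ("category=low", "category=high"):
            assert res.subgroup_hrs[key].hr == pytest.approx(
                res.joint_hrs[key], rel=0.02)

    def test_planted_interaction_detected(self):
        spec = CohortSimSpec(
            n=4000, seed=5,
            log_hr_dcis={"radiotherapy": float(np.log(0.8))},
            log_hr_invasive={"radiotherapy": float(np.log(0.8))},
            interaction_dcis=float(np.log(0.4)),
            interaction_invasive=float(np.log(0.4)))
        cohort, _ = simulate_cohort(spec)
        res = interaction_test(cohort, "IBE", "category", "radiotherapy")
        assert res.p_interaction < 0.05

    def test_empty_subgroup_named(self, rng):
        cohort = _cohort_two_groups(rng, 100, 0.1, 0.2)
        cohort["radiotherapy"] = rng.integers(0, 2, len(cohort))
        cohort = cohort[cohort["category"] == "low"]
        with pytest.raises((InsufficientDataError, ValueError)):
            interaction_test(cohort, "DCIS-IBE", "category", "radiotherapy")


def _build_sets(patterns):
    """Matched sets from (case_exposed, control_exposures...) tuples."""
    rows = []
    for sid, pat in enumerate(patterns):
        rows.append((sid, 1, pat[0]))
        rows.extend((sid, 0, e) for e in pat[1:])
    df = pd.DataFrame(rows, columns=["set_id", "is_case", "exposed"])
    df["category"] = np.where(df["exposed"] == 1, "high", "low")
    return df


def _oracle_conditional_or(df):
    """Brute-force conditional-likelihood maximiser (golden section)."""
    groups = [g for _, g in df.groupby("set_id")]

    def neg_loglik(beta):
        ll = 0.0
        for g in groups:
            x = g["exposed"].to_numpy(float)
            case_x = x[g["is_case"].to_numpy(bool)][0]
            ll += beta * case_x - np.logaddexp.reduce(beta * x)
        return -ll

    res = minimize_scalar(neg_loglik, bounds=(-8, 8), method="bounded",
                          options={"xatol": 1e-10})
    return float(np.exp(res.x))


class TestMatching:
    def _toy_cohort(self):
        rows = [
            # one case with event at t=5
            ("case1", 60.0, 1, 0, 5.0, "I-IBE"),
            # control censored at 4 < 5: ineligible (risk-set rule)
            ("shortfu", 60.0, 1, 0, 4.0, "none"),
            # control 8 years older: ineligible (age caliper)
            ("tooold", 68.0, 1, 0, 12.0, "none"),
            # different treatment arm: ineligible
            ("otherarm", 60.0, 0, 0, 12.0, "none"),
            # two eligible controls
            ("ok1", 55.0, 1, 0, 9.0, "none"),
            ("ok2", 66.0, 1, 0, 6.0, "none"),
        ]
        return pd.DataFrame(rows, columns=[
            "patient_id", "age", "tamoxifen", "radiotherapy", "time",
            "event"])

    def test_eligibility_rules(self):
        sets = match_case_control(self._toy_cohort(), ratio=2, seed=0)
        chosen = set(sets.data.loc[~sets.data["is_case"], "patient_id"])
        assert chosen == {"ok1", "ok2"}
        assert sets.n_sets == 1

    def test_simulated_sets_satisfy_constraints(self):
        cohort, _ = simulate_cohort(CohortSimSpec(n=600, seed=3))
        sets = match_case_control(cohort, ratio=2, seed=1)
        for _, g in sets.data.groupby("set_id"):
            case = g[g["is_case"]].iloc[0]
            ctrls = g[~g["is_case"]]
            assert len(ctrls) <= 2
            assert (ctrls["tamoxifen"] == case["tamoxifen"]).all()
            assert (ctrls["radiotherapy"] == case["radiotherapy"]).all()
            assert ((ctrls["age"] - case["age"]).abs() <= 7).all()
            assert (ctrls["time"] >= case["time"]).all()

    def test_controls_never_reused(self):
        cohort, _ = simulate_cohort(CohortSimSpec(n=600, seed=3))
        sets = match_case_control(cohort, ratio=2, seed=1)
        ctrl_ids = sets.data.loc[~sets.data["is_case"], "patient_id"]
        assert ctrl_ids.is_unique

    def test_deterministic_under_seed(self):
        cohort, _ = simulate_cohort(CohortSimSpec(n=400, seed=3))
        s1 = match_case_control(cohort, seed=9)
        s2 = match_case_control(cohort, seed=9)
        pd.testing.assert_frame_equal(s1.data, s2.data)


class TestConditionalLogistic:
    def test_matches_bruteforce_oracle_on_1_2_sets(self, rng):
        """40 hand-built 1:2 sets: the fitted OR equals the brute-force
        conditional-likelihood maximiser within 1e-4."""
        patterns = [tuple(rng.integers(0, 2, 3)) for _ in range(40)]
        if all(len(set(p)) == 1 for p in patterns):  # force discordance
            patterns[0] = (1, 0, 0)
        df = _build_sets(patterns)
        fit = conditional_logistic(df, exposure="category")
        assert fit.odds_ratio == pytest.approx(
            _oracle_conditional_or(df), abs=1e-4)

    def test_1_1_sets_equal_discordant_pair_ratio(self):
        """On 1:1 sets the matched OR is the classical b/c ratio."""
        patterns = [(1, 0)] * 12 + [(0, 1)] * 5 + [(1, 1)] * 7 + [(0, 0)] * 6
        fit = conditional_logistic(_build_sets(patterns), exposure="category")
        assert fit.odds_ratio == pytest.approx(12 / 5, abs=1e-8)

    def test_concordant_sets_rejected(self):
        df = _build_sets([(1, 1, 1), (0, 0, 0)])
        with pytest.raises(UndefinedORError):
            conditional_logistic(df, exposure="category")

    def test_planted_log_or_recovered(self, rng):
        """Sets simulated with conditional log-OR = log 2 recover an OR
        estimate near 2."""
        beta = np.log(2.0)
        rows = []
        for sid in range(500):
            x = rng.integers(0, 2, 3).astype(float)
            p = np.exp(beta * x) / np.exp(beta * x).sum()
            case = rng.choice(3, p=p)
            for j in range(3):
                rows.append((sid, int(j == case), x[j]))
        df = pd.DataFrame(rows, columns=["set_id", "is_case", "exposed"])
        df["category"] = np.where(df["exposed"] == 1, "high", "low")
        fit = conditional_logistic(df, exposure="category")
        assert 1.6 <= fit.odds_ratio <= 2.5


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman([1, 2, 3, 5], [2, 4, 9, 11]).rho == 1.0
        assert spearman([1, 2, 3, 5], [11, 9, 4, 2]).rho == -1.0

    def test_midrank_ties_against_hand_formula(self):
        """x=(1,2,2,4), y=(1,3,2,4): rho from explicit mid-rank Pearson."""
        res = spearman([1, 2, 2, 4], [1, 3, 2, 4])
        assert res.rho == pytest.approx(4.5 / np.sqrt(22.5), abs=1e-12)

    def test_constant_vector_flagged(self):
        res = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert not res.defined
        assert np.isnan(res.rho)


class TestRankTests:
    def test_exact_two_group_enumeration(self):
        """(1,2) vs (3,4): all 6 rank splits give two-sided p = 1/3."""
        res = rank_tests([[1, 2], [3, 4]])
        assert res.exact
        assert res.p == pytest.approx(1 / 3)

    def test_kw_two_groups_equals_mw_approximation(self, rng):
        x, y = rng.normal(size=25), rng.normal(size=30)
        mw = rank_tests([x, y])
        kw = stats.kruskal(x, y)
        assert mw.p == pytest.approx(float(kw.pvalue), abs=1e-6)

    def test_exact_kruskal_small_sample(self):
        """Exact 3-group enumeration agrees with a direct count of
        assignments with H >= observed."""
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0], [6.0, 7.0]]
        res = rank_tests(groups)
        assert res.exact
        assert res.test == "kruskal-wallis"
        assert 0 < res.p <= 0.05

    def test_type_one_error_calibrated(self):
        """Identical distributions: rejection rate at alpha=0.05 stays in
        [0.03, 0.07] over 1000 simulations."""
        rejections = 0
        for rep in range(1000):
            r = np.random.default_rng(rep)
            p = rank_tests([r.normal(size=50), r.normal(size=50)]).p
            rejections += p <= 0.05
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            rank_tests([[1, 2], []])


class TestCrosstab:
    def _cohort(self):
        cohort, _ = simulate_cohort(CohortSimSpec(n=500, seed=8))
        return cohort

    def test_column_percentages_sum_to_100(self):
        ct = crosstab_summary(self._cohort(), "grade")
        assert ct.table["low_pct"].sum() == pytest.approx(100.0)
        assert ct.table["high_pct"].sum() == pytest.approx(100.0)

    def test_continuous_covariate_uses_mann_whitney(self):
        ct = crosstab_summary(self._cohort(), "age")
        assert ct.kind == "continuous"
        assert ct.test == "mann-whitney"

    def test_missing_values_excluded_and_counted(self):
        cohort = self._cohort()
        ct = crosstab_summary(cohort, "er")
        n_missing_er = int((cohort["er"] == "missing").sum())
        assert ct.n_missing == n_missing_er
        assert ct.n == len(cohort) - n_missing_er

    def test_unknown_covariate_rejected(self):
        with pytest.raises(UnknownFieldError):
            crosstab_summary(self._cohort(), "bmi")
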
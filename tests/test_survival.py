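import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from lifelines import KaplanMeierFitter
from lifelines.utils import concordance_index as lifelines_cindex

from conftest import brute_force_cindex, newton_raphson_cox
from scsurv.containers import SurvivalCohort
from scsurv.survival import (
    concordance_index,
    cox_partial_loglik,
    cross_validated_cindex,
    fit_lasso_cox,
    hazard_ratio_table,
    km_estimate,
    logrank_test,
    risk_stratify,
    stratified_folds,
)
from scsurv.simulate import SurvSimSpec, simulate_survival_cohort


class TestConcordanceIndex:
    def test_perfect_concordance_and_anticoncordance(self):
        t = np.array([1.0, 2.0, 3.0])
        d = np.ones(3, dtype=int)
        assert concordance_index(t, d, np.array([3.0, 2.0, 1.0])) == 1.0
        assert concordance_index(t, d, np.array([1.0, 2.0, 3.0])) == 0.0

    def test_censoring_example_against_enumeration(self):
        t = np.array([2.0, 5.0, 7.0, 9.0])
        d = np.array([1, 1, 0, 1])
        r = np.array([4.0, 3.0, 2.0, 1.0])
        assert concordance_index(t, d, r) == 1.0
        assert concordance_index(t, d, r) == brute_force_cindex(t, d, r)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        t = rng.exponential(10, n)
        d = rng.integers(0, 2, n)
        if d.sum() == 0:
            d[0] = 1
        r = rng.normal(size=n)
        if seed % 2:  # exercise tied risk scores too
            r = np.round(r, 1)
        assert concordance_index(t, d, r) == pytest.approx(
            brute_force_cindex(t, d, r), abs=1e-12
        )

    def test_agrees_with_lifelines_without_ties(self, rng):
        t = rng.exponential(10, 40)
        d = rng.integers(0, 2, 40)
        d[0] = 1
        r = rng.normal(size=40)
        # lifelines scores predicted survival time (higher = longer), so
        # pass -r to compare against our risk-score orientation
        assert concordance_index(t, d, r) == pytest.approx(
            lifelines_cindex(t, -r, d), abs=1e-12
        )

    def test_reversal_identity(self, rng):
        t = rng.exponential(10, 25)
        d = rng.integers(0, 2, 25)
        d[:3] = 1
        r = rng.normal(size=25)  # continuous, so no ties
        c1 = concordance_index(t, d, r)
        c2 = concordance_index(t, d, -r)
        assert c1 + c2 == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_monotone_transform_of_risk(self, rng):
        t = rng.exponential(10, 25)
        d = np.ones(25, dtype=int)
        r = rng.normal(size=25)
        assert concordance_index(t, d, r) == concordance_index(t, d, np.exp(r))

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance_index(np.array([1.0, 2.0]), np.array([0, 1]),
                              np.array([1.0, 2.0]))


class TestFitLassoCox:
    def _cohort(self, n=100, seed=0, betas=None):
        cohort, _ = simulate_survival_cohort(
            SurvSimSpec(n_patients=n,
                        signature_betas=betas or {"gA": 1.0},
                        n_noise_genes=3, censor_rate=0.2, seed=seed)
        )
        return cohort

    def test_large_lambda_shrinks_all_to_zero(self):
        cohort = self._cohort()
        model = fit_lasso_cox(cohort, list(cohort.covariates.columns), lam=10.0)
        assert (model.beta == 0).all()
        assert model.active_set == []

    def test_lambda_zero_matches_newton_raphson_oracle(self):
        # 6 patients, one covariate, distinct times, no penalty
        rng = np.random.default_rng(5)
        x = rng.normal(size=6)
        time = np.array([3.0, 1.0, 4.0, 2.0, 6.0, 5.0])
        event = np.array([1, 1, 0, 1, 1, 1])
        cov = pd.DataFrame({"x": x}, index=[f"p{i}" for i in range(6)])
        cohort = SurvivalCohort(
            patient_ids=list(cov.index), time=time, event=event, covariates=cov
        )
        model = fit_lasso_cox(cohort, ["x"], lam=0.0)
        z = (x - x.mean()) / x.std()
        b_oracle = newton_raphson_cox(z, time, event)
        assert model.beta["x"] == pytest.approx(b_oracle, abs=1e-6)

    def test_signal_gene_dominates_null_gene(self):
        hits = 0
        for seed in range(20):
            cohort = self._cohort(n=300, seed=seed, betas={"gA": 1.0})
            model = fit_lasso_cox(cohort, ["gA", "noise000"], lam=0.02)
            if model.beta["gA"] > 0 and abs(model.beta["gA"]) > abs(model.beta["noise000"]):
                hits += 1
        assert hits >= 19  # >= 95% of replicates

    def test_zero_variance_gene_dropped_with_warning(self):
        cohort = self._cohort()
        cohort.covariates = cohort.covariates.assign(flat=1.0)
        with pytest.warns(UserWarning, match="flat"):
            model = fit_lasso_cox(cohort, ["gA", "flat"], lam=0.01)
        assert model.beta["flat"] == 0.0

    def test_penalized_solution_beats_zero_vector(self):
        cohort = self._cohort(n=150, seed=3)
        genes = list(cohort.covariates.columns)
        lam = 0.05
        model = fit_lasso_cox(cohort, genes, lam)
        X = cohort.covariates[genes].to_numpy()
        Z = (X - X.mean(0)) / X.std(0)
        n = len(cohort.time)
        beta = model.beta.to_numpy()
        obj_hat = cox_partial_loglik(beta, Z, cohort.time, cohort.event) / n \
            - lam * np.abs(beta).sum()
        obj_zero = cox_partial_loglik(np.zeros_like(beta), Z,
                                      cohort.time, cohort.event) / n
        assert obj_hat >= obj_zero - 1e-9


class TestCrossValidation:
    def test_planted_signal_gives_high_cindex(self):
        cohort, _ = simulate_survival_cohort(
            SurvSimSpec(n_patients=300, signature_betas={"gA": 2.0},
                        n_noise_genes=2, censor_rate=0.1, seed=4)
        )
        _, mean_c = cross_validated_cindex(cohort, ["gA"], folds=5, seed=0, lam=0.001)
        assert mean_c > 0.8

    def test_null_covariates_center_on_half(self):
        means = []
        for seed in range(30):
            cohort, _ = simulate_survival_cohort(
                SurvSimSpec(n_patients=120, signature_betas={},
                            n_noise_genes=3, censor_rate=0.2, seed=seed)
            )
            _, mean_c = cross_validated_cindex(
                cohort, list(cohort.covariates.columns), folds=4, seed=0, lam=0.05
            )
            means.append(mean_c)
        assert np.mean(means) == pytest.approx(0.5, abs=0.05)

    def test_same_seed_identical_folds_and_values(self):
        cohort, _ = simulate_survival_cohort(
            SurvSimSpec(n_patients=150, signature_betas={"gA": 1.0}, seed=9)
        )
        f1 = stratified_folds(cohort.event, 5, seed=42)
        f2 = stratified_folds(cohort.event, 5, seed=42)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a, b)
        r1 = cross_validated_cindex(cohort, ["gA"], folds=5, seed=42, lam=0.01)
        r2 = cross_validated_cindex(cohort, ["gA"], folds=5, seed=42, lam=0.01)
        assert r1 == r2

    def test_folds_are_event_stratified(self):
        event = np.array([1] * 20 + [0] * 30)
        folds = stratified_folds(event, 5, seed=0)
        for f in folds:
            assert event[f].sum() == 4  # 20 events dealt evenly into 5 folds

    def test_cv_within_train_lambda_selection_runs(self):
        cohort, _ = simulate_survival_cohort(
            SurvSimSpec(n_patients=120, signature_betas={"gA": 1.5},
                        n_noise_genes=4, censor_rate=0.2, seed=2)
        )
        _, mean_c = cross_validated_cindex(
            cohort, list(cohort.covariates.columns), folds=3, seed=1,
            lambda_strategy="cv_within_train",
        )
        assert mean_c > 0.6


class TestKaplanMeier:
    def test_hand_computed_curve(self):
        curve = km_estimate(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
        np.testing.assert_array_equal(curve.times, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [3, 2, 1])

    def test_all_censored_curve_is_flat_one(self):
        curve = km_estimate(np.array([1.0, 2.0]), np.array([0, 0]))
        assert curve.times.size == 0  # no drops: survival identically 1

    def test_single_death(self):
        curve = km_estimate(np.array([5.0]), np.array([1]))
        np.testing.assert_allclose(curve.survival, [0.0])

    def test_equals_one_minus_ecdf_without_censoring(self, rng):
        t = rng.exponential(5, 40)
        curve = km_estimate(t, np.ones(40, dtype=int))
        for u, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(1 - np.mean(t <= u), abs=1e-12)

    def test_matches_lifelines_with_censoring(self, rng):
        t = rng.exponential(5, 60)
        d = rng.integers(0, 2, 60)
        d[0] = 1
        curve = km_estimate(t, d)
        kmf = KaplanMeierFitter().fit(t, d)
        for u, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(u).iloc[0]), abs=1e-10
            )


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        t = np.array([1.0, 2.0, 3.0])
        d = np.array([1, 1, 0])
        res = logrank_test((t, d), (t.copy(), d.copy()))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_two_by_two_tables(self):
        # A dies at 1, 2; B dies at 10, 20; no censoring
        tA, dA = np.array([1.0, 2.0]), np.array([1, 1])
        tB, dB = np.array([10.0, 20.0]), np.array([1, 1])
        res = logrank_test((tA, dA), (tB, dB))
        # time 1: nA=2,nB=2,d=1 -> EA=0.5 ; time 2: nA=1,nB=2,d=1 -> EA=1/3
        # time 10: nA=0,nB=2,d=1 -> EA=0 ; time 20: nA=0,nB=1,d=1 -> EA=0
        EA = 0.5 + 1 / 3
        EB = 4 - EA
        np.testing.assert_allclose(res.observed, [2, 2])
        np.testing.assert_allclose(res.expected, [EA, EB], atol=1e-12)
        expected_stat = (2 - EA) ** 2 / EA + (2 - EB) ** 2 / EB
        assert res.statistic == pytest.approx(expected_stat, abs=1e-9)

    def test_label_swap_symmetry(self, rng):
        tA = rng.exponential(5, 20)
        tB = rng.exponential(10, 25)
        dA = rng.integers(0, 2, 20)
        dB = rng.integers(0, 2, 25)
        dA[0] = dB[0] = 1
        r1 = logrank_test((tA, dA), (tB, dB))
        r2 = logrank_test((tB, dB), (tA, dA))
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)

    def test_time_rescaling_invariance(self, rng):
        tA = rng.exponential(5, 15)
        tB = rng.exponential(9, 15)
        dA = np.ones(15, dtype=int)
        dB = np.ones(15, dtype=int)
        r1 = logrank_test((tA, dA), (tB, dB))
        r2 = logrank_test((tA * 7.0, dA), (tB * 7.0, dB))
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)

    def test_observed_and_expected_totals_balance(self, rng):
        tA = rng.exponential(5, 30)
        tB = rng.exponential(5, 30)
        dA = rng.integers(0, 2, 30)
        dB = rng.integers(0, 2, 30)
        dA[0] = 1
        res = logrank_test((tA, dA), (tB, dB))
        assert res.observed.sum() == pytest.approx(res.expected.sum(), abs=1e-9)


class TestRiskStratification:
    def _fitted(self, seed=0):
        cohort, _ = simulate_survival_cohort(
            SurvSimSpec(n_patients=200, signature_betas={"gA": 1.5},
                        n_noise_genes=2, censor_rate=0.2, seed=seed)
        )
        model = fit_lasso_cox(cohort, list(cohort.covariates.columns), lam=0.01)
        return model, cohort

    def test_median_split_balanced_on_distinct_scores(self):
        model, cohort = self._fitted()
        sub = cohort.subset(np.arange(4))
        high, low, r = risk_stratify(model, sub)
        assert len(high) == 2 and len(low) == 2

    def test_power_to_separate_planted_risk(self):
        significant = 0
        n_reps = 20
        for seed in range(n_reps):
            model, cohort = self._fitted(seed=seed)
            high, low, _ = risk_stratify(model, cohort)
            idx = {p: i for i, p in enumerate(cohort.patient_ids)}
            hi = np.array([idx[p] for p in high])
            lo = np.array([idx[p] for p in low])
            res = logrank_test((cohort.time[hi], cohort.event[hi]),
                               (cohort.time[lo], cohort.event[lo]))
            if res.p_value < 0.05:
                significant += 1
        assert significant >= 0.9 * n_reps

    def test_constant_risk_raises(self):
        model, cohort = self._fitted()
        model.beta[:] = 0.0
        with pytest.raises(ValueError, match="constant"):
            risk_stratify(model, cohort)

    def test_duplicated_rows_split_identically(self):
        model, cohort = self._fitted()
        dup = SurvivalCohort(
            patient_ids=[p + "_b" for p in cohort.patient_ids] + cohort.patient_ids,
            time=np.tile(cohort.time, 2),
            event=np.tile(cohort.event, 2),
            covariates=pd.concat([
                cohort.covariates.set_axis([p + "_b" for p in cohort.patient_ids]),
                cohort.covariates,
            ]),
        )
        high, low, _ = risk_stratify(model, dup)
        high_set = set(high)
        for p in cohort.patient_ids:
            assert ((p in high_set) == (p + "_b" in high_set))


class TestHazardRatioTable:
    def test_classification_boundaries(self):
        model, _ = TestRiskStratification()._fitted()
        model.beta = pd.Series(
            {"zero": 0.0, "at2": np.log(2.0), "above2": np.log(2.0) + 0.01,
             "below_half": np.log(0.5) - 0.01},
        )
        model.genes = list(model.beta.index)
        table = hazard_ratio_table(model)
        assert table.loc["zero", "class"] == "neutral"
        assert table.loc["zero", "hazard_ratio"] == pytest.approx(1.0)
        assert table.loc["at2", "class"] == "neutral"  # strict inequality
        assert table.loc["above2", "class"] == "risk-increasing"
        assert table.loc["below_half", "class"] == "risk-decreasing"


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_cindex_reversal_property(seed):
    """With continuous risk scores, reversing their sign complements the C-index."""
    rng = np.random.default_rng(seed)
    n = 15
    t = rng.exponential(10, n)
    d = rng.integers(0, 2, n)
    d[0] = 1
    r = rng.normal(size=n)
    assert concordance_index(t, d, r) + concordance_index(t, d, -r) == pytest.approx(
        1.0, abs=1e-12
    )
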
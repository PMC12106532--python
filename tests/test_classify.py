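"""ROC machinery, logistic subset models, comparators, cohort table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunet.classify import (
    ModelSpec,
    SubsetLogit,
    cohort_summary,
    comparator_models,
    fit_model,
    predictive_values,
    rank_auc,
    roc_metrics,
    trapezoid_auc,
)

FOUR = ("CD15+CD14+ monocytes", "CD45RA-CX3CR1+CTLA4+CD4+ T",
        "CD45RA-IL17A+CD4+ T", "Ki67+ B")


class TestAUC:
    def test_perfect_separation_auc_one(self):
        scores = np.r_[np.ones(5), np.zeros(5)]
        labels = np.r_[np.ones(5), np.zeros(5)].astype(bool)
        assert trapezoid_auc(scores, labels) == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_trapezoid_equals_rank_estimator(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        scores = rng.choice(np.round(rng.random(30), 2), size=n)  # with ties
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        assert abs(trapezoid_auc(scores, labels) - rank_auc(scores, labels)) < 1e-12

    def test_null_scores_auc_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(2000)
        labels = rng.random(2000) < 0.5
        assert abs(trapezoid_auc(scores, labels) - 0.5) < 0.03

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_auc_complement_identity(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(50)
        labels = rng.random(50) < 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        assert trapezoid_auc(scores, labels) + trapezoid_auc(-scores, labels) == (
            pytest.approx(1.0, abs=1e-12)
        )

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.random(100)
        labels = rng.random(100) < 0.5
        a = trapezoid_auc(scores, labels)
        b = trapezoid_auc(np.exp(3 * scores), labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_metrics(np.random.default_rng(0).random(10), np.ones(10, dtype=bool))


class TestMetrics:
    def test_reported_rates_match_confusion_matrix(self):
        rng = np.random.default_rng(2)
        scores = rng.random(200)
        labels = (scores + 0.3 * rng.standard_normal(200)) > 0.5
        m = roc_metrics(scores, labels)
        c = m.confusion
        assert c["tp"] + c["fn"] == m.n_cases
        assert c["tn"] + c["fp"] == m.n_controls
        assert m.sensitivity == pytest.approx(c["tp"] / (c["tp"] + c["fn"]))
        assert m.specificity == pytest.approx(c["tn"] / (c["tn"] + c["fp"]))
        assert m.ppv == pytest.approx(c["tp"] / (c["tp"] + c["fp"]))
        assert m.npv == pytest.approx(c["tn"] / (c["tn"] + c["fn"]))

    def test_predictive_values_at_study_operating_point(self):
        # sens 87.2% / spec 79.0% on 39 cases vs 19 controls
        ppv, npv = predictive_values(0.872, 0.790, 39, 19)
        assert round(100 * ppv, 1) == 89.5
        assert round(100 * npv, 1) == 75.0

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(3)
        scores = rng.random(100)
        labels = (scores + 0.5 * rng.standard_normal(100)) > 0.5
        m = roc_metrics(scores, labels)
        assert m.auc_ci[0] <= m.auc <= m.auc_ci[1]
        assert 0 <= m.auc_ci[0] and m.auc_ci[1] <= 1


class TestSubsetLogit:
    def _tables(self, n=60, seed=0, outcome_from=0):
        rng = np.random.default_rng(seed)
        idx = [f"P{i}" for i in range(n)]
        freq = pd.DataFrame(
            rng.random((n, 4)) * 5, index=idx, columns=FOUR
        )
        latent = freq.iloc[:, outcome_from] + rng.standard_normal(n)
        group = np.where(latent > np.median(latent), "sepsis", "healthy")
        clinical = pd.DataFrame({
            "subject_id": idx, "group": group,
            "age_years": rng.uniform(0.1, 16, n),
            "picu_mortality": (group == "sepsis") & (rng.random(n) < 0.3),
        })
        return freq, clinical

    def test_single_predictor_scores_monotone_in_predictor(self):
        freq, clinical = self._tables()
        spec = ModelSpec("m", (FOUR[0],), "sepsis", adjust_age=False)
        res = fit_model(spec, freq, clinical)
        order_scores = np.argsort(res.scores.to_numpy())
        order_pred = np.argsort(freq[FOUR[0]].to_numpy())
        agree = np.array_equal(order_scores, order_pred)
        assert agree or np.array_equal(order_scores, order_pred[::-1])

    def test_refit_identical(self):
        freq, clinical = self._tables(seed=1)
        spec = ModelSpec("m", FOUR, "sepsis")
        a = fit_model(spec, freq, clinical)
        b = fit_model(spec, freq, clinical)
        pd.testing.assert_series_equal(a.params, b.params)

    def test_perfect_separation_penalized_fallback(self):
        idx = [f"P{i}" for i in range(20)]
        freq = pd.DataFrame(
            {FOUR[0]: np.r_[np.zeros(10), np.ones(10) * 10]}, index=idx
        )
        clinical = pd.DataFrame({
            "subject_id": idx,
            "group": ["healthy"] * 10 + ["sepsis"] * 10,
            "age_years": 5.0,
        })
        spec = ModelSpec("m", (FOUR[0],), "sepsis", adjust_age=False)
        res = fit_model(spec, freq, clinical)
        assert res.separation_flag
        assert res.metrics.auc == 1.0

    def test_unknown_outcome_rejected(self):
        with pytest.raises(ValueError, match="outcome"):
            ModelSpec("m", FOUR, "discharge")

    def test_combined_model_beats_single_subset_on_average(self, scenario):
        from immunet.simulate import simulate_frequency_table

        wins = 0
        n_runs = 40
        for s in range(n_runs):
            rng = np.random.default_rng(7000 + s)
            freq, groups, clinical = simulate_frequency_table(scenario, rng)
            four = fit_model(ModelSpec("4", FOUR, "sepsis"), freq, clinical)
            single = fit_model(
                ModelSpec("1", (FOUR[0],), "sepsis"), freq, clinical
            )
            if four.metrics.auc > single.metrics.auc:
                wins += 1
        assert wins / n_runs > 0.5

    def test_mortality_model_restricted_to_sepsis(self, freq_cohort):
        freq, groups, clinical = freq_cohort
        res = fit_model(ModelSpec("3", FOUR[:3], "picu_mortality"), freq, clinical)
        assert res.metrics.n_cases + res.metrics.n_controls == 39


class TestComparators:
    def test_constant_comparator_auc_half(self):
        clinical = pd.DataFrame({
            "subject_id": [f"P{i}" for i in range(40)],
            "group": "sepsis",
            "lactate": 2.0,
            "picu_mortality": [True] * 10 + [False] * 30,
        })
        out = comparator_models(clinical, variables=("lactate",))
        assert out["lactate"].auc == pytest.approx(0.5)

    def test_self_predictor_near_perfect(self):
        rng = np.random.default_rng(4)
        score = rng.random(60)
        clinical = pd.DataFrame({
            "subject_id": [f"P{i}" for i in range(60)],
            "group": "sepsis",
            "psofa": score * 20,
            "picu_mortality": score > 0.7,
        })
        out = comparator_models(clinical, variables=("psofa",))
        assert out["psofa"].auc == 1.0

    def test_all_missing_variable_skipped(self):
        clinical = pd.DataFrame({
            "subject_id": ["a", "b", "c", "d"],
            "group": "sepsis",
            "crp": np.nan,
            "picu_mortality": [True, False, True, False],
        })
        with pytest.warns(UserWarning, match="all-missing"):
            out = comparator_models(clinical, variables=("crp",))
        assert out == {}

    def test_subset_model_beats_lactate_for_mortality(self, scenario):
        # mortality is generated from subset frequencies; lactate only sees
        # it through the Th17 coupling, so the 3-subset model should win
        # in a clear majority of cohorts
        from immunet.simulate import simulate_frequency_table

        wins = trials = 0
        for s in range(40):
            rng = np.random.default_rng(8000 + s)
            freq, groups, clinical = simulate_frequency_table(scenario, rng)
            sep = clinical[clinical["group"] == "sepsis"]
            if sep["picu_mortality"].sum() < 2:
                continue
            model = fit_model(
                ModelSpec("3", FOUR[:3], "picu_mortality"), freq, clinical
            )
            comp = comparator_models(clinical, variables=("lactate",))
            trials += 1
            if model.metrics.auc > comp["lactate"].auc:
                wins += 1
        assert trials >= 20
        assert wins / trials >= 0.7


class TestCohortSummary:
    def test_percentages_match_printed_convention(self):
        n = 59
        clinical = pd.DataFrame({
            "subject_id": [f"P{i}" for i in range(n)],
            "group": "sepsis",
            "age_years": 5.0, "wbc": 9.5, "crp": 119.0,
            "procalcitonin": 6.1, "lactate": 1.6,
            "psofa": 8, "pim3": 3.4, "pelod2": 6,
            "picu_mortality": [True] * 8 + [False] * (n - 8),
            "multiorgan_dysfunction": [True] * 41 + [False] * (n - 41),
            "severe_sepsis": [True] * 44 + [False] * (n - 44),
            "septic_shock": [True] * 43 + [False] * (n - 43),
        })
        table = cohort_summary(clinical).set_index("variable")
        assert table.loc["picu_mortality", "value"] == "8 (13.6)"
        assert table.loc["multiorgan_dysfunction", "value"] == "41 (69.5)"
        assert table.loc["severe_sepsis", "value"] == "44 (74.6)"

    def test_empty_stratum_zero_counts(self):
        clinical = pd.DataFrame({
            "subject_id": ["a"], "group": "healthy",
            "age_years": 3.0, "wbc": np.nan, "crp": np.nan,
            "procalcitonin": np.nan, "lactate": np.nan,
            "psofa": np.nan, "pim3": np.nan, "pelod2": np.nan,
            "picu_mortality": False, "multiorgan_dysfunction": False,
            "severe_sepsis": False, "septic_shock": False,
        })
        table = cohort_summary(clinical).set_index("variable")
        assert table.loc["picu_mortality", "value"] == "0 (0.0)"
        assert table.loc["crp", "value"] == ""

    def test_generated_cohort_outcome_rates_near_targets(self, scenario):
        from immunet.simulate import SEPSIS, simulate_clinical, simulate_compositions

        rng = np.random.default_rng(9)
        comp = simulate_compositions(scenario, SEPSIS, rng, n=4000)
        clin = simulate_clinical(scenario, comp, SEPSIS, rng)
        assert abs(clin["severe_sepsis"].mean() - 0.746) < 0.05
        assert abs(clin["septic_shock"].mean() - 0.729) < 0.05
        assert abs(clin["picu_mortality"].mean() - 0.136) < 0.04
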
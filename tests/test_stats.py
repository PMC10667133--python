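"""Progression statistics: paired tests, logistic ORs, kappa, report tables."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ihrf import (
    CohortSpec,
    ProgressionModel,
    build_report,
    intergrader_agreement,
    logistic_multivariate,
    logistic_univariate,
    paired_count_test,
    simulate_cohort,
)


def _cohort_from_cells(cells):
    """Rows from (progressed, exposed_count, n) triples; exposure lives in slab 1."""
    rows = []
    for prog, count, n in cells:
        for _ in range(n):
            row = {f"base_{k}": 0 for k in range(1, 6)}
            row.update({f"fu_{k}": 0 for k in range(1, 6)})
            row["base_1"] = count
            row["fu_1"] = count
            row["progressed"] = bool(prog)
            rows.append(row)
    return pd.DataFrame(rows)


class TestPairedTest:
    def test_closed_form_on_small_vectors(self):
        r = paired_count_test([0, 2, 4], [1, 4, 5])
        # differences +1, +2, +1: mean 4/3, sd 1/sqrt(3) -> t = 4, df = 2
        assert r.t == pytest.approx(4.0)
        assert r.df == 2
        assert r.total_baseline == 6 and r.total_followup == 10

    def test_positive_t_means_counts_increased(self):
        r = paired_count_test([0, 1, 2, 5], [3, 2, 6, 7])
        assert r.t > 0

    def test_identical_vectors_are_the_null(self):
        r = paired_count_test([1, 2, 3], [1, 2, 3])
        assert (r.t, r.p) == (0.0, 1.0)

    def test_constant_shift_is_degenerate(self):
        r = paired_count_test([0, 2, 4], [1, 3, 5])
        assert r.status == "degenerate"
        assert math.isnan(r.p)


class TestLogisticUnivariate:
    def test_binary_predictor_or_equals_cross_product_ratio(self):
        df = _cohort_from_cells([(1, 1, 6), (0, 1, 4), (1, 0, 2), (0, 0, 8)])
        res = logistic_univariate(df, 1, coding="categorical")
        assert res.odds_ratio == pytest.approx((6 * 8) / (4 * 2), rel=1e-6)
        assert res.ci_low < res.odds_ratio < res.ci_high

    def test_no_contrast_is_inestimable(self):
        df = _cohort_from_cells([(1, 1, 6), (0, 1, 4)])  # everyone exposed
        res = logistic_univariate(df, 1, coding="categorical")
        assert res.status == "inestimable"

    def test_complete_separation_is_flagged_not_reported(self):
        df = _cohort_from_cells([(1, 3, 10), (0, 0, 10)])  # exposure predicts perfectly
        res = logistic_univariate(df, 1)
        assert res.status == "inestimable"
        assert "separation" in res.note

    def test_firth_penalization_estimates_under_separation(self):
        df = _cohort_from_cells([(1, 3, 10), (0, 0, 10)])
        res = logistic_univariate(df, 1, penalized=True)
        assert res.estimable and np.isfinite(res.odds_ratio)

    def test_profile_ci_brackets_the_estimate(self):
        df = simulate_cohort(CohortSpec(n_eyes=400, seed=8))
        wald = logistic_univariate(df, 1)
        prof = logistic_univariate(df, 1, ci_method="profile")
        assert prof.ci_low < prof.odds_ratio < prof.ci_high
        assert prof.odds_ratio == pytest.approx(wald.odds_ratio)
        assert prof.ci_low == pytest.approx(wald.ci_low, rel=0.2)

    def test_parameter_recovery_from_simulated_cohort(self):
        spec = CohortSpec(
            n_eyes=5000, beta_per_slab=(math.log(2.13), 0, 0, 0, 0), seed=17
        )
        res = logistic_univariate(simulate_cohort(spec), 1)
        assert 2.13 * 0.85 < res.odds_ratio < 2.13 * 1.15


class TestLogisticMultivariate:
    def test_single_predictor_equals_univariate(self):
        df = simulate_cohort(CohortSpec(n_eyes=300, seed=9))
        uni = logistic_univariate(df, 1)
        (multi,) = logistic_multivariate(df, [1])
        assert multi.odds_ratio == pytest.approx(uni.odds_ratio, rel=1e-6)
        assert multi.p == pytest.approx(uni.p, rel=1e-6)

    def test_null_predictor_adjusted_or_near_one(self):
        spec = CohortSpec(
            n_eyes=5000, beta_per_slab=(math.log(2.0), 0, 0, 0, 0), seed=10
        )
        results = logistic_multivariate(simulate_cohort(spec), [1, 2])
        by_label = {r.predictor: r for r in results}
        assert by_label["slab 2"].ci_low < 1.0 < by_label["slab 2"].ci_high
        assert abs(math.log(by_label["slab 2"].odds_ratio)) < 0.15

    def test_collinear_duplicate_is_flagged_and_rest_reported(self):
        df = simulate_cohort(CohortSpec(n_eyes=200, seed=11))
        df["base_3"] = df["base_1"]  # exact duplicate
        results = logistic_multivariate(df, [1, 3])
        by_label = {r.predictor: r for r in results}
        assert by_label["slab 3"].status == "inestimable"
        assert "collinear" in by_label["slab 3"].note
        assert by_label["slab 1"].estimable


class TestKappa:
    def test_perfect_agreement(self):
        k = intergrader_agreement([0, 1, 0, 1, 1], [0, 1, 0, 1, 1])
        assert k.kappa == pytest.approx(1.0)

    def test_hand_worked_2x2_table(self):
        # agreement table [[20, 5], [10, 15]]: po = 0.7, pe = 0.5 -> kappa = 0.4
        a = [0] * 25 + [1] * 25
        b = [0] * 20 + [1] * 5 + [0] * 10 + [1] * 15
        k = intergrader_agreement(a, b)
        assert k.kappa == pytest.approx(0.4, abs=1e-12)
        assert k.ci_low < 0.4 < k.ci_high

    def test_matches_sklearn_point_estimate(self):
        rng = np.random.default_rng(12)
        a = rng.integers(0, 3, 200)
        b = np.where(rng.random(200) < 0.7, a, rng.integers(0, 3, 200))
        from sklearn.metrics import cohen_kappa_score

        assert intergrader_agreement(a, b).kappa == pytest.approx(cohen_kappa_score(a, b))

    def test_independent_ratings_give_near_zero_kappa(self):
        rng = np.random.default_rng(13)
        a = rng.integers(0, 2, 5000)
        b = rng.integers(0, 2, 5000)
        k = intergrader_agreement(a, b)
        assert abs(k.kappa) < 0.05
        assert k.ci_low < 0.0 < k.ci_high

    def test_single_category_is_undefined(self):
        k = intergrader_agreement([1, 1, 1], [1, 1, 1])
        assert k.status == "undefined"


def test_null_pvalues_are_uniform():
    """Under beta = 0 the univariate Wald p-values follow U(0,1)."""
    master = np.random.default_rng(14)
    pvals = []
    for _ in range(400):
        spec = CohortSpec(
            n_eyes=200, beta_per_slab=(0.0,) * 5, seed=int(master.integers(0, 2**31 - 1))
        )
        res = logistic_univariate(simulate_cohort(spec), 1)
        if res.estimable:
            pvals.append(res.p)
    stat, p = sps.kstest(pvals, "uniform")
    assert p > 0.01


@pytest.fixture(scope="module")
def results():
    return ProgressionModel(simulate_cohort(CohortSpec(n_eyes=300, seed=15))).fit()


class TestModelAndReport:
    def test_report_contains_four_tables_with_all_slabs(self, results, tmp_path):
        tables = build_report(results, tmp_path / "report")
        for name in (
            "table_counts",
            "table_baseline_quantitative",
            "table_delta_quantitative",
            "table_baseline_qualitative",
        ):
            assert len(tables[name]) == 5
            assert (tmp_path / "report" / f"{name}.csv").exists()
        assert (tmp_path / "report" / "report.md").exists()

    def test_all_zero_slab_reported_as_na(self, results):
        t2 = results.table_baseline_quantitative()
        slab5 = t2[t2.predictor == "slab 5"].iloc[0]
        assert slab5.uni_or == "NA" and slab5.multi_or == "NA"

    def test_per_slab_totals_conserve_overall_total(self, results):
        df = results.model.cohort
        t1 = results.table_counts()
        assert t1.baseline_total.sum() == df[[f"base_{k}" for k in range(1, 6)]].sum().sum()
        assert t1.followup_total.sum() == df[[f"fu_{k}" for k in range(1, 6)]].sum().sum()

    def test_summary_is_textual_and_mentions_all_sections(self, results):
        text = results.summary()
        for token in ("Per-slab lesion counts", "Baseline counts", "2-year change", "presence"):
            assert token in text

    def test_plot_writes_a_figure(self, results, tmp_path):
        results.plot_slab_counts(tmp_path / "counts.png")
        assert (tmp_path / "counts.png").stat().st_size > 0
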
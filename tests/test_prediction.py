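"""Regression fitting, nested-CV dimension selection, CV metrics, multiple testing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import qcla
from qcla.prediction import (
    bonferroni,
    cross_validate,
    default_grid,
    fit_linear_model,
    permutation_pvalue,
    pvalue_for_r,
    select_dimensions,
)


def normal_equations(X, y):
    """Closed-form OLS oracle."""
    D = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(D.T @ D, D.T @ y)


class TestFitLinearModel:
    def test_matches_normal_equations_oracle(self, rng):
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        model = fit_linear_model(X, y, n_dims=3)
        oracle = normal_equations(X[:, :3], y)
        assert np.allclose(model.coefficients, oracle, atol=1e-8)

    def test_exact_linear_signal_recovered(self, rng):
        X = rng.standard_normal((30, 4))
        w = np.array([1.0, -2.0, 0.5, 3.0])
        y = 2.0 + X @ w
        model = fit_linear_model(X, y, n_dims=4)
        assert np.allclose(model.predict(X), y, atol=1e-8)

    def test_constant_target(self, rng):
        X = rng.standard_normal((15, 3))
        model = fit_linear_model(X, np.full(15, 7.0), n_dims=3)
        assert model.intercept == pytest.approx(7.0, abs=1e-8)
        assert np.allclose(model.slopes, 0.0, atol=1e-8)

    def test_rank_deficient_falls_back_to_ridge(self, rng):
        X = rng.standard_normal((20, 4))
        X[:, 3] = X[:, 2]  # exact collinearity
        model = fit_linear_model(X, rng.standard_normal(20), n_dims=4)
        assert model.training_meta["ridge_fallback"]
        assert np.all(np.isfinite(model.coefficients))

    def test_errors(self, rng):
        X = rng.standard_normal((5, 3))
        with pytest.raises(ValueError):  # n_dims exceeds representation width
            fit_linear_model(X, np.zeros(5), n_dims=4)
        with pytest.raises(ValueError):  # n <= n_dims + 1
            fit_linear_model(rng.standard_normal((5, 4)), np.zeros(5), n_dims=4)
        with pytest.raises(ValueError):
            fit_linear_model(X, np.array([1.0, 2, np.nan, 0, 1]), n_dims=2)


class TestSelectDimensions:
    def test_single_value_grid(self, rng):
        X = rng.standard_normal((50, 8))
        assert select_dimensions(X, rng.standard_normal(50), [4]) == 4

    def test_concentrated_signal_prefers_few_dimensions(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((400, 64))
            y = 3 * X[:, 0] + 0.3 * rng.standard_normal(400)
            if select_dimensions(X, y, [2, 4, 8, 16, 32, 64], rng=rng) <= 8:
                hits += 1
        assert hits >= 9

    def test_distributed_signal_prefers_many_dimensions(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((600, 64))
            w = rng.standard_normal(50)
            y = X[:, :50] @ w + 0.5 * rng.standard_normal(600)
            if select_dimensions(X, y, [2, 4, 8, 16, 32, 64], rng=rng) > 8:
                hits += 1
        assert hits >= 9

    def test_default_grid_caps(self):
        assert default_grid(512, 1000) == [2, 4, 8, 16, 32, 64, 128, 256]
        assert default_grid(16, 1000) == [2, 4, 8, 16]
        assert default_grid(512, 20) == [2, 4, 8]


class TestCrossValidate:
    def test_strong_signal_high_r(self, rng):
        X = rng.standard_normal((500, 10))
        w = rng.standard_normal(8)
        signal = X[:, :8] @ w
        y = signal + 0.1 * signal.std() * rng.standard_normal(500)
        res = cross_validate(X, y, seed=rng, p_method="none")
        assert res.r >= 0.9
        assert res.r2 == pytest.approx(res.r**2, abs=1e-12)

    def test_predictions_are_out_of_fold(self, rng):
        """Refitting each fold's model from the stored bookkeeping reproduces
        the stored predictions exactly, proving each participant was predicted
        by a model trained without them."""
        X = rng.standard_normal((120, 6))
        y = X[:, 0] + rng.standard_normal(120)
        res = cross_validate(X, y, seed=7, grid=[2, 4], p_method="none")
        for j, g in zip(np.unique(res.fold_assignments), res.dims_per_fold):
            test = res.fold_assignments == j
            model = fit_linear_model(X[~test], y[~test], g)
            assert np.allclose(model.predict(X[test]), res.predictions[test], atol=1e-10)

    def test_rmse_recomputable_from_predictions(self, rng):
        X = rng.standard_normal((100, 5))
        y = rng.standard_normal(100)
        res = cross_validate(X, y, seed=1, grid=[2], p_method="none")
        assert res.rmse == pytest.approx(float(np.sqrt(np.mean((res.predictions - y) ** 2))))
        assert res.min_pred <= res.max_pred
        assert res.min_pred == res.predictions.min()

    def test_deterministic_under_seed(self, rng):
        X = rng.standard_normal((80, 6))
        y = rng.standard_normal(80)
        a = cross_validate(X, y, seed=42, grid=[2, 4])
        b = cross_validate(X, y, seed=42, grid=[2, 4])
        assert a.r == b.r and a.p == b.p
        assert np.array_equal(a.predictions, b.predictions)

    def test_constant_fold_target_error(self):
        X = np.random.default_rng(0).standard_normal((30, 3))
        with pytest.raises(ValueError, match="distinct"):
            cross_validate(X, np.full(30, 3.0), outer_folds=3, grid=[2], p_method="none")

    def test_too_few_participants_error(self, rng):
        with pytest.raises(ValueError):
            cross_validate(rng.standard_normal((5, 3)), rng.standard_normal(5), outer_folds=10)


class TestPValues:
    def test_r_zero_gives_one(self):
        assert pvalue_for_r(0.0, 100) == pytest.approx(1.0)

    def test_table_scale_example(self):
        # r of 0.31 in a sample of 876 is overwhelming evidence
        assert pvalue_for_r(0.31, 876) < 1e-4

    def test_limits_and_bounds(self):
        assert pvalue_for_r(1.0, 10) == 0.0
        assert pvalue_for_r(-1.0, 10) == 0.0
        with pytest.raises(ValueError):
            pvalue_for_r(0.5, 2)

    def test_matches_permutation_oracle_on_small_sample(self, rng):
        x = rng.standard_normal(20)
        y = 0.5 * x + rng.standard_normal(20)
        r = float(np.corrcoef(x, y)[0, 1])
        p_analytic = pvalue_for_r(r, 20)
        p_perm = permutation_pvalue(x, y, n_permutations=10_000, seed=5)
        se = np.sqrt(p_perm * (1 - p_perm) / 10_000)
        assert abs(p_analytic - p_perm) < max(4 * se, 0.01)


class TestBonferroni:
    def test_printed_tiering_examples(self):
        report = bonferroni([0.0003, 0.0054, 0.2], m=16)
        assert report.flags == [
            "significant_corrected",
            "significant_uncorrected",
            "ns",
        ]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.5], m=1)

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
        st.integers(1, 60),
    )
    @settings(deadline=None, max_examples=80)
    def test_flag_invariants(self, ps, m):
        report = bonferroni(ps, m=m)
        for p, flag in zip(report.raw_p, report.flags):
            if flag == "significant_corrected":
                assert p <= report.alpha / m
            if flag == "significant_uncorrected":
                assert report.alpha / m < p <= report.alpha


@pytest.fixture(scope="module")
def planted_sleep_cohorts():
    """Cohorts where only the sleep question's words carry age signal."""
    inv = qcla.default_inventory()
    vocab = [f"w{i}" for i in range(20)]
    space = qcla.SemanticSpace(vocabulary=vocab, vectors=np.eye(20), dimensionality=20)
    cohorts = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        records = []
        for i in range(200):
            age = float(rng.integers(18, 71))
            responses = {}
            for label in inv.labels:
                k = inv.words_requested[label]
                if label == "sleep":
                    # word identity tracks age deterministically + noise
                    centre = int((age - 18) / 53 * 9)
                    idx = np.clip(centre + rng.integers(-1, 2, size=k), 0, 9)
                    responses[label] = [vocab[j] for j in idx]
                else:
                    responses[label] = [vocab[10 + rng.integers(10)] for _ in range(k)]
            records.append(
                qcla.ParticipantRecord(
                    id=f"p{i}", age=age, gender="other",
                    scale_scores={"phq9": 5, "gad7": 5, "hils": 20, "swls": 20},
                    controls_passed=True, responses=responses,
                )
            )
        cohorts.append(qcla.CohortTable(records))
    return cohorts, space

class TestQuestionBattery:
    def test_planted_question_dominates_battery(self, planted_sleep_cohorts):
        cohorts, space = planted_sleep_cohorts
        wins = 0
        for seed, cohort in enumerate(cohorts):
            table, report, _ = qcla.run_question_battery(
                cohort, space, seed=seed, grid=[4, 8], n_permutations=99,
                min_participants=20,
            )
            table = table.set_index("label")
            others = table.drop(index=["sleep", "all_texts"])["r"]
            if table.loc["sleep", "r"] > others.max():
                wins += 1
        assert wins >= 4

    def test_bonferroni_m_equals_variables_tested(self, planted_sleep_cohorts):
        cohorts, space = planted_sleep_cohorts
        table, report, _ = qcla.run_question_battery(
            cohorts[0], space, seed=0, grid=[4], n_permutations=99, min_participants=20
        )
        assert report.m == len(table)
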
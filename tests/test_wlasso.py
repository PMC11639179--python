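import itertools
import warnings

import numpy as np
import pytest

from gislasso import (
    BINOMIAL,
    GAUSSIAN,
    DesignData,
    cross_validate,
    fit,
    fit_multiclass,
    kkt_residual,
    objective,
    selection_sets,
    soft_threshold,
)
from gislasso.simulate import make_expression


def design(X, y):
    n, q = X.shape
    return DesignData(
        X=X,
        y=y,
        sample_ids=[f"s{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(q)],
    )


def gaussian_problem(seed, n=60, q=20, k=3):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, q))
    beta = np.zeros(q)
    beta[:k] = rng.uniform(0.5, 2.0, k) * rng.choice([-1, 1], k)
    y = X @ beta + rng.standard_normal(n)
    return design(X, y)


def binomial_problem(seed, n=60, q=20, k=3):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, q))
    beta = np.zeros(q)
    beta[:k] = rng.uniform(0.5, 2.0, k) * rng.choice([-1, 1], k)
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    return design(X, (rng.random(n) < p).astype(int))


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "z,gamma,expected",
        [(3.0, 1.0, 2.0), (-0.5, 1.0, 0.0), (1.7, 0.0, 1.7), (-3.0, 1.0, -2.0)],
    )
    def test_examples(self, z, gamma, expected):
        assert soft_threshold(z, gamma) == pytest.approx(expected)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)


class TestObjective:
    def test_null_model_gaussian_is_half_mean_square(self):
        d = gaussian_problem(0)
        y = np.asarray(d.y, dtype=float)
        got = objective(np.zeros(d.q), 0.0, d, lam=0.3, penalties=np.ones(d.q),
                        family=GAUSSIAN)
        assert got == pytest.approx(0.5 * np.mean(y**2))

    def test_zero_lambda_is_pure_loss(self):
        d = gaussian_problem(1)
        rng = np.random.default_rng(0)
        beta = rng.standard_normal(d.q)
        with_pen = objective(beta, 0.1, d, lam=0.0, penalties=np.ones(d.q))
        resid = np.asarray(d.y, float) - 0.1 - d.X @ beta
        assert with_pen == pytest.approx(0.5 * np.mean(resid**2))

    def test_unit_penalties_match_plain_l1(self):
        d = gaussian_problem(2)
        beta = np.linspace(-1, 1, d.q)
        a = objective(beta, 0.0, d, lam=0.2, penalties=np.ones(d.q))
        resid = np.asarray(d.y, float) - d.X @ beta
        assert a == pytest.approx(0.5 * np.mean(resid**2) + 0.2 * np.abs(beta).sum())

    def test_dimension_mismatch_raises(self):
        d = gaussian_problem(3)
        with pytest.raises(ValueError, match="mismatch"):
            objective(np.zeros(d.q + 1), 0.0, d, 0.1, np.ones(d.q))


class TestFitGaussian:
    def test_large_lambda_gives_null_model(self):
        d = gaussian_problem(4)
        y = np.asarray(d.y, float)
        lam_max = np.abs(d.X.T @ (y - y.mean())).max() / d.n
        m = fit(d, lam_max * 1.01, family=GAUSSIAN, standardize=False)
        assert np.all(m.beta == 0.0)
        assert m.intercept == pytest.approx(y.mean())

    def test_two_feature_solution_beats_brute_force_grid(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 2))
        y = 1.2 * X[:, 0] - 0.7 * X[:, 1] + 0.3 * rng.standard_normal(40)
        d = design(X, y)
        lam, w = 0.1, np.array([1.0, 0.6])
        m = fit(d, lam, penalties=w, family=GAUSSIAN, standardize=False, tol=1e-9)
        obj_fit = objective(m.beta, m.intercept, d, lam, w)
        grid = np.linspace(-2, 2, 201)
        best = min(
            objective(np.array([b1, b2]), y.mean(), d, lam, w)
            for b1, b2 in itertools.product(grid, grid)
        )
        assert obj_fit <= best + 1e-4

    def test_matches_sklearn_standard_lasso(self):
        from sklearn.linear_model import Lasso

        for seed in range(5):
            d = gaussian_problem(seed)
            m = fit(d, 0.1, family=GAUSSIAN, standardize=False, tol=1e-9)
            sk = Lasso(alpha=0.1, tol=1e-12, max_iter=100_000).fit(d.X, d.y)
            assert np.abs(m.beta - sk.coef_).max() < 1e-5

    def test_zero_penalty_features_unpenalized(self):
        d = gaussian_problem(6)
        w = np.ones(d.q)
        w[0] = 0.0
        m = fit(d, 5.0, penalties=w, family=GAUSSIAN, standardize=False)
        # at huge lambda every penalized coefficient dies but g0 survives
        assert m.beta[0] != 0.0
        assert np.all(m.beta[1:] == 0.0)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            fit(gaussian_problem(7), -0.1)

    def test_constant_column_excluded_with_warning(self):
        d = gaussian_problem(8)
        X = d.X.copy()
        X[:, 5] = 2.5
        d2 = design(X, d.y)
        with pytest.warns(UserWarning, match="constant"):
            m = fit(d2, 0.05, family=GAUSSIAN, standardize=True)
        assert m.beta[5] == 0.0


class TestRescalingEquivalence:
    """Principal correctness oracle: the weighted fit equals a standard fit
    on penalty-rescaled columns with coefficients mapped back."""

    @pytest.mark.parametrize("seed", range(5))
    def test_gaussian(self, seed):
        d = gaussian_problem(seed, n=50, q=12)
        rng = np.random.default_rng(1000 + seed)
        w = rng.uniform(0.5, 1.0, d.q)
        direct = fit(d, 0.1, penalties=w, family=GAUSSIAN,
                     standardize=False, tol=1e-9)
        rescaled = design(d.X / w, d.y)
        std = fit(rescaled, 0.1, family=GAUSSIAN, standardize=False, tol=1e-9)
        assert np.abs(direct.beta - std.beta / w).max() < 1e-5

    @pytest.mark.parametrize("seed", range(5))
    def test_binomial(self, seed):
        d = binomial_problem(seed, n=50, q=12)
        rng = np.random.default_rng(2000 + seed)
        w = rng.uniform(0.5, 1.0, d.q)
        direct = fit(d, 0.05, penalties=w, family=BINOMIAL,
                     standardize=False, tol=1e-9)
        rescaled = design(d.X / w, d.y)
        std = fit(rescaled, 0.05, family=BINOMIAL, standardize=False, tol=1e-9)
        assert np.abs(direct.beta - std.beta / w).max() < 1e-5


class TestBinomial:
    def test_matches_sklearn_saga_l1(self):
        from sklearn.linear_model import LogisticRegression

        for seed in range(3):
            d = binomial_problem(seed)
            lam = 0.05
            m = fit(d, lam, family=BINOMIAL, standardize=False, tol=1e-9)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sk = LogisticRegression(
                    solver="saga", l1_ratio=1.0, penalty="elasticnet",
                    C=1.0 / (d.n * lam), tol=1e-10, max_iter=200_000,
                ).fit(d.X, d.y)
            assert np.abs(m.beta - sk.coef_.ravel()).max() < 1e-5

    def test_kkt_conditions_at_solution(self):
        for seed in range(5):
            d = binomial_problem(seed)
            rng = np.random.default_rng(seed)
            w = rng.uniform(0.5, 1.0, d.q)
            m = fit(d, 0.05, penalties=w, family=BINOMIAL,
                    standardize=False, tol=1e-8)
            assert kkt_residual(d, m) < 1e-6

    def test_non_binary_response_rejected(self):
        d = gaussian_problem(9)
        with pytest.raises(ValueError, match="0/1"):
            fit(d, 0.1, family=BINOMIAL)


@pytest.mark.parametrize("family", ["gaussian", "binomial"])
@pytest.mark.parametrize("seed", range(10))
def test_objective_path_non_increasing(family, seed):
    d = gaussian_problem(seed) if family == "gaussian" else binomial_problem(seed)
    lam = np.random.default_rng(seed).choice([0.01, 0.05, 0.2, 1.0])
    m = fit(d, float(lam), family=family, standardize=False)
    path = np.asarray(m.objective_path)
    assert (np.diff(path) <= 1e-10).all()


class TestMulticlass:
    def test_three_separated_classes_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        n_per = 30
        centers = np.array([[0.0, 0.0], [6.0, 0.0], [0.0, 6.0]])
        X = np.vstack(
            [c + rng.standard_normal((n_per, 2)) for c in centers]
        )
        X = np.hstack([X, rng.standard_normal((3 * n_per, 4))])
        y = np.repeat(["a", "b", "c"], n_per)
        d = design(X, y)
        model = fit_multiclass(d, 0.01)
        assert np.mean(model.predict(X) == y) == 1.0
        assert set(model.selected_by_class()) == {"a", "b", "c"}

    def test_two_class_models_are_negations(self):
        d = binomial_problem(3, n=80)
        y = np.where(np.asarray(d.y) == 1, "pos", "neg")
        model = fit_multiclass(design(d.X, y), 0.05, tol=1e-9)
        m_neg, m_pos = model.models
        assert np.abs(m_pos.beta + m_neg.beta).max() < 1e-5

    def test_huge_lambda_empties_every_class_model(self):
        d = binomial_problem(4)
        y = np.where(np.asarray(d.y) == 1, "pos", "neg")
        model = fit_multiclass(design(d.X, y), 50.0)
        assert all(not m.selected for m in model.models)
        assert len(model.predict(d.X)) == d.n

    def test_tiny_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        y = np.array(["a"] * 9 + ["b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_multiclass(design(X, y), 0.1)


class TestCrossValidate:
    def test_single_grid_point(self):
        d = binomial_problem(0, n=60)
        table, best = cross_validate(
            d, lam_grid=[0.1], shape_grid=[1.0], k_folds=3, seed=0
        )
        assert len(table) == 1
        assert best == (0.1, 1.0)

    def test_pure_noise_accuracy_near_chance(self):
        d = make_expression(120, 15, informative=[], family="binomial", seed=0)
        table, _ = cross_validate(
            d, lam_grid=[0.05, 0.2], k_folds=5, seed=1
        )
        # accuracy should hover near the 0.5 majority rate on null labels
        sd = table["sd_metric"].max() / np.sqrt(5)
        assert (np.abs(table["mean_metric"] - 0.5) <= max(3 * sd, 0.15)).all()

    def test_fold_sizes_balanced(self):
        from sklearn.model_selection import StratifiedKFold

        y = np.array([0, 1] * 25)
        X = np.random.default_rng(0).standard_normal((50, 3))
        sizes = [
            len(test)
            for _, test in StratifiedKFold(5, shuffle=True, random_state=0).split(X, y)
        ]
        assert max(sizes) - min(sizes) <= 1

    def test_ties_break_toward_larger_lambda(self):
        d = binomial_problem(1, n=40)
        # huge lambdas: every model is empty so all grid points tie
        table, best = cross_validate(
            d, lam_grid=[5.0, 10.0, 20.0], k_folds=2, seed=0
        )
        assert best[0] == 20.0

    def test_tiny_class_refolds_with_warning(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 4))
        y = np.array([0] * 17 + [1] * 3)
        with pytest.warns(UserWarning, match="refolding"):
            cross_validate(design(X, y), lam_grid=[0.5], k_folds=5, seed=0)


class TestSelectionSets:
    def test_union_intersection_frequency(self):
        d = gaussian_problem(0, n=40, q=6)
        models = []
        rng = np.random.default_rng(0)
        for _ in range(3):
            idx = rng.permutation(d.n)
            models.append(
                fit(design(d.X[idx], np.asarray(d.y)[idx]), 0.1, family=GAUSSIAN)
            )
        union, inter, freq = selection_sets(models)
        assert inter <= union
        assert all(0 < f <= 1 for f in freq.values())
        for g in inter:
            assert freq[g] == 1.0

    def test_single_model_union_equals_intersection(self):
        m = fit(gaussian_problem(1), 0.1, family=GAUSSIAN)
        union, inter, _ = selection_sets([m])
        assert union == inter == m.selected

    def test_hand_picked_sets(self):
        a = fit(gaussian_problem(2), 0.05, family=GAUSSIAN)
        b = fit(gaussian_problem(2), 0.05, family=GAUSSIAN)
        union, inter, _ = selection_sets([a, b])
        assert union == inter == a.selected
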
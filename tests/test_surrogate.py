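"""Mixed-variable GP: kernels, fitting, posterior prediction.

The posterior is cross-checked against (a) a dense linear-algebra oracle
built from the scalar kernel formula inside the test, and (b) sklearn's
GaussianProcessRegressor with a Matérn 3/2 kernel on continuous-only data.
"""

import numpy as np
import pytest
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

from studyopt.space import CONTINUOUS, DesignSpace, StudyDesign, VariableSpec
from studyopt.surrogate import (
    FitConfig,
    KernelParams,
    SurrogateError,
    categorical_kernel,
    exchangeable_correlation,
    fit_gp,
    gp_posterior,
    hypersphere_correlation,
    kernel_matrix,
    make_model,
    matern32,
    mixed_kernel,
)

from conftest import random_design

SQRT3 = np.sqrt(3.0)


def oracle_kernel(space, x1, x2, params):
    """Independent scalar evaluation of the mixed kernel for the oracle."""
    e1, e2 = space.encode(x1), space.encode(x2)
    d = 0.0
    k_cat = 1.0
    for i, var in enumerate(space.variables):
        if var.is_numeric:
            d += (e1[i] - e2[i]) ** 2
        else:
            corr = params.cat_corr.get(var.name)
            if corr is not None:
                k_cat *= corr[int(e1[i]), int(e2[i])]
    r = params.theta * np.sqrt(d)
    return params.sigma2 * (1 + SQRT3 * r) * np.exp(-SQRT3 * r) * k_cat


class TestKernels:
    def test_matern_at_zero_distance_is_sigma2(self, mixed_space):
        x = StudyDesign({"coverage": 30, "error_rate": 0.01, "paired": True, "informatics": "callerA"})
        params = KernelParams(sigma2=2.5, theta=0.7)
        assert matern32(mixed_space, x, x, params) == pytest.approx(2.5)

    def test_matern_unit_distance_value(self):
        # sigma2=1, theta=1, d=1 -> (1+sqrt3) * exp(-sqrt3)
        space = DesignSpace([VariableSpec("u", CONTINUOUS, 0.0, 1.0)])
        x1, x2 = StudyDesign({"u": 0.0}), StudyDesign({"u": 1.0})
        expected = (1 + SQRT3) * np.exp(-SQRT3)
        val = matern32(space, x1, x2, KernelParams(sigma2=1.0, theta=1.0))
        assert val == pytest.approx(expected, abs=1e-10)
        assert val == pytest.approx(0.4834, abs=5e-4)

    def test_matern_symmetry_random_pairs(self, mixed_space):
        rng = np.random.default_rng(0)
        params = KernelParams(sigma2=1.3, theta=2.0)
        for _ in range(20):
            a, b = random_design(mixed_space, rng), random_design(mixed_space, rng)
            assert matern32(mixed_space, a, b, params) == pytest.approx(
                matern32(mixed_space, b, a, params)
            )

    def test_nonpositive_theta_rejected(self):
        with pytest.raises(SurrogateError):
            KernelParams(theta=0.0)

    def test_categorical_same_level_is_one(self):
        corr = hypersphere_correlation(3, np.full(3, np.pi / 4))
        assert categorical_kernel("a", "a", ["a", "b", "c"], corr) == pytest.approx(1.0)
        assert np.allclose(np.diag(corr), 1.0)

    def test_two_level_correlation_rho_and_psd(self):
        rho = 0.6
        corr = hypersphere_correlation(2, np.array([np.arccos(rho)]))
        assert corr[0, 1] == pytest.approx(rho)
        assert np.all(np.linalg.eigvalsh(corr) >= -1e-12)

    def test_three_level_equal_rho_gram_psd(self):
        corr = exchangeable_correlation(3, 0.5)
        assert np.all(np.linalg.eigvalsh(corr) >= -1e-12)

    def test_hypersphere_psd_for_random_angles(self):
        rng = np.random.default_rng(1)
        for n_levels in (2, 3, 4, 5):
            n_ang = n_levels * (n_levels - 1) // 2
            corr = hypersphere_correlation(n_levels, rng.uniform(0.05, np.pi / 2, n_ang))
            assert np.all(np.linalg.eigvalsh(corr) >= -1e-10)
            assert np.all((0 < corr) & (corr <= 1 + 1e-12))

    def test_unknown_level_rejected(self):
        with pytest.raises(SurrogateError):
            categorical_kernel("z", "a", ["a", "b"], np.eye(2))

    def test_mixed_kernel_product_rule(self, mixed_space):
        rho = 0.5
        corr2 = hypersphere_correlation(2, np.array([np.arccos(rho)]))
        params = KernelParams(
            sigma2=2.0, theta=1.0,
            cat_corr={"paired": corr2, "informatics": np.eye(3)},
        )
        base = {"coverage": 50, "error_rate": 0.05, "informatics": "callerA"}
        x1 = StudyDesign({**base, "paired": False})
        x2 = StudyDesign({**base, "paired": True})
        assert mixed_kernel(mixed_space, x1, x1, params) == pytest.approx(2.0)
        assert mixed_kernel(mixed_space, x1, x2, params) == pytest.approx(2.0 * rho)

    def test_gram_matrix_psd_after_nugget(self, mixed_space):
        rng = np.random.default_rng(3)
        designs = [random_design(mixed_space, rng) for _ in range(20)]
        params = KernelParams(
            sigma2=1.0, theta=1.5,
            cat_corr={
                "paired": hypersphere_correlation(2, np.array([0.8])),
                "informatics": hypersphere_correlation(3, np.array([0.5, 0.9, 1.1])),
            },
            nugget=1e-8,
        )
        E = mixed_space.encode_matrix(designs)
        K = kernel_matrix(mixed_space, E, E, params) + params.nugget * np.eye(20)
        assert np.allclose(K, K.T)
        assert np.all(np.linalg.eigvalsh(K) >= -1e-10)

    def test_vectorized_matrix_matches_scalar_kernel(self, mixed_space):
        rng = np.random.default_rng(4)
        designs = [random_design(mixed_space, rng) for _ in range(6)]
        params = KernelParams(
            sigma2=1.7, theta=0.9,
            cat_corr={
                "paired": hypersphere_correlation(2, np.array([0.6])),
                "informatics": hypersphere_correlation(3, np.array([0.4, 0.7, 1.0])),
            },
        )
        E = mixed_space.encode_matrix(designs)
        K = kernel_matrix(mixed_space, E, E, params)
        for i in range(6):
            for j in range(6):
                assert K[i, j] == pytest.approx(
                    mixed_kernel(mixed_space, designs[i], designs[j], params), rel=1e-12
                )


class TestPosterior:
    def _training(self, mixed_space, n=5, seed=10):
        rng = np.random.default_rng(seed)
        X = [random_design(mixed_space, rng) for _ in range(n)]
        y = rng.normal(size=n)
        return X, y

    def test_interpolates_training_points_with_zero_nugget(self, mixed_space):
        X, y = self._training(mixed_space)
        params = KernelParams(sigma2=1.0, theta=1.0, nugget=0.0)
        model = make_model(mixed_space, X, y, params)
        for x, yi in zip(X, y):
            mean, var = gp_posterior(model, x)
            assert mean == pytest.approx(yi, abs=1e-6)
            assert var == pytest.approx(0.0, abs=1e-6)

    def test_reverts_to_prior_far_from_data(self):
        space = DesignSpace([VariableSpec("u", CONTINUOUS, 0.0, 1.0)])
        X = [StudyDesign({"u": 0.0}), StudyDesign({"u": 0.01})]
        params = KernelParams(sigma2=2.0, theta=50.0, nugget=1e-10)
        model = make_model(space, X, [1.0, 1.1], params)
        mean, var = gp_posterior(model, StudyDesign({"u": 1.0}))
        assert mean == pytest.approx(0.0, abs=0.05)  # prior mean
        assert var == pytest.approx(2.0, rel=0.05)  # prior variance

    def test_matches_dense_linear_algebra_oracle(self, mixed_space):
        """Posterior mean/variance equal the closed-form conditional computed
        by an independent dense solve, to 1e-8, on small training sets."""
        rng = np.random.default_rng(11)
        params = KernelParams(
            sigma2=1.4, theta=1.2,
            cat_corr={
                "paired": hypersphere_correlation(2, np.array([0.7])),
                "informatics": hypersphere_correlation(3, np.array([0.5, 0.8, 1.2])),
            },
            nugget=1e-8,
        )
        for n in (3, 6, 10):
            X = [random_design(mixed_space, rng) for _ in range(n)]
            y = rng.normal(size=n)
            model = make_model(mixed_space, X, y, params)
            K = np.array([[oracle_kernel(mixed_space, a, b, params) for b in X] for a in X])
            K += model.params.nugget * np.eye(n)
            for _ in range(3):
                x_star = random_design(mixed_space, rng)
                k_star = np.array([oracle_kernel(mixed_space, x_star, b, params) for b in X])
                Kinv = np.linalg.inv(K)
                mean_oracle = k_star @ Kinv @ y
                var_oracle = params.sigma2 - k_star @ Kinv @ k_star
                mean, var = gp_posterior(model, x_star)
                assert mean == pytest.approx(mean_oracle, abs=1e-8)
                assert var == pytest.approx(max(var_oracle, 0.0), abs=1e-8)

    def test_matches_sklearn_on_continuous_data(self, continuous_space):
        rng = np.random.default_rng(12)
        X = [
            StudyDesign({"x1": float(a), "x2": float(b)})
            for a, b in rng.random((8, 2))
        ]
        y = rng.normal(size=8)
        sigma2, theta, nugget = 1.3, 2.0, 1e-8
        model = make_model(
            continuous_space, X, y, KernelParams(sigma2=sigma2, theta=theta, nugget=nugget)
        )
        sk = GaussianProcessRegressor(
            kernel=ConstantKernel(sigma2, "fixed")
            * Matern(length_scale=1.0 / theta, length_scale_bounds="fixed", nu=1.5),
            alpha=nugget,
            optimizer=None,
        ).fit(continuous_space.encode_matrix(X), y)
        queries = [StudyDesign({"x1": float(a), "x2": float(b)}) for a, b in rng.random((5, 2))]
        mean, var = model.predict(queries)
        sk_mean, sk_std = sk.predict(continuous_space.encode_matrix(queries), return_std=True)
        np.testing.assert_allclose(mean, sk_mean, atol=1e-7)
        np.testing.assert_allclose(np.sqrt(var), sk_std, atol=1e-6)

    def test_variance_bounded_by_prior(self, mixed_space):
        X, y = self._training(mixed_space, n=8, seed=13)
        model = fit_gp(mixed_space, X, y, seed=0)
        rng = np.random.default_rng(14)
        queries = [random_design(mixed_space, rng) for _ in range(30)]
        _, var = model.predict(queries)
        assert np.all(var >= 0.0)
        prior = model.params.sigma2 * model.y_std**2
        assert np.all(var <= prior * (1 + 1e-8) + model.params.nugget)

    def test_adding_data_never_increases_variance(self, mixed_space):
        rng = np.random.default_rng(15)
        X = [random_design(mixed_space, rng) for _ in range(7)]
        y = list(rng.normal(size=7))
        params = KernelParams(sigma2=1.0, theta=1.0, nugget=0.0)
        small = make_model(mixed_space, X[:5], y[:5], params)
        large = make_model(mixed_space, X, y, params)
        for _ in range(20):
            q = random_design(mixed_space, rng)
            _, v_small = gp_posterior(small, q)
            _, v_large = gp_posterior(large, q)
            assert v_large <= v_small + 1e-8

    def test_unfitted_model_errors(self, mixed_space):
        from studyopt.surrogate import GPModel

        model = GPModel(
            space=mixed_space, X=[], y=np.array([]), params=KernelParams(),
            y_mean=0.0, y_std=1.0, X_encoded=np.empty((0, 4)), K_XX=np.empty((0, 0)),
        )
        with pytest.raises(SurrogateError, match="not fitted"):
            model.predict([])


class TestFitting:
    def test_constant_observations_give_constant_posterior(self, mixed_space):
        rng = np.random.default_rng(20)
        X = [random_design(mixed_space, rng) for _ in range(6)]
        model = fit_gp(mixed_space, X, [3.14] * 6, seed=0)
        mean, var = model.predict([random_design(mixed_space, rng) for _ in range(5)])
        np.testing.assert_allclose(mean, 3.14, atol=1e-6)
        assert np.all(var < 1e-6)

    def test_recovers_lengthscale_within_factor_two(self, continuous_space):
        rng = np.random.default_rng(21)
        true = KernelParams(sigma2=1.0, theta=3.0, nugget=1e-10)
        X = [StudyDesign({"x1": float(a), "x2": float(b)}) for a, b in rng.random((40, 2))]
        E = continuous_space.encode_matrix(X)
        K = kernel_matrix(continuous_space, E, E, true) + 1e-10 * np.eye(40)
        y = rng.multivariate_normal(np.zeros(40), K)
        model = fit_gp(continuous_space, X, y, FitConfig(n_restarts=4), seed=1)
        assert true.theta / 2 <= model.params.theta <= true.theta * 2

    def test_refit_same_seed_identical(self, mixed_space):
        rng = np.random.default_rng(22)
        X = [random_design(mixed_space, rng) for _ in range(10)]
        y = rng.normal(size=10)
        a = fit_gp(mixed_space, X, y, seed=5)
        b = fit_gp(mixed_space, X, y, seed=5)
        assert a.params.theta == b.params.theta
        assert a.params.sigma2 == b.params.sigma2

    def test_duplicate_training_set_rejected(self, mixed_space):
        x = StudyDesign({"coverage": 10, "error_rate": 0.02, "paired": True, "informatics": "callerA"})
        with pytest.raises(SurrogateError, match="duplicate"):
            fit_gp(mixed_space, [x, x, x], [1.0, 1.1, 0.9], seed=0)

    def test_non_finite_observations_rejected(self, mixed_space):
        rng = np.random.default_rng(23)
        X = [random_design(mixed_space, rng) for _ in range(3)]
        with pytest.raises(SurrogateError, match="non-finite"):
            fit_gp(mixed_space, X, [1.0, np.nan, 2.0], seed=0)


def test_archive_round_trip(tmp_path, mixed_space):
    rng = np.random.default_rng(30)
    X = [random_design(mixed_space, rng) for _ in range(8)]
    y = rng.normal(size=8)
    model = fit_gp(mixed_space, X, y, seed=2)
    path = tmp_path / "surrogate.yaml"
    model.to_archive(path)
    from studyopt.surrogate import GPModel

    back = GPModel.from_archive(mixed_space, path)
    q = [random_design(mixed_space, rng) for _ in range(5)]
    m1, v1 = model.predict(q)
    m2, v2 = back.predict(q)
    np.testing.assert_allclose(m1, m2, rtol=1e-9)
    np.testing.assert_allclose(v1, v2, rtol=1e-6, atol=1e-12)
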
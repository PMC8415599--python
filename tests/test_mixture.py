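import json

import numpy as np
import pytest
from scipy.interpolate import BSpline

from mixqc import (
    ComponentParams,
    MixtureFit,
    ModelSpec,
    SinglePopulationError,
    SyntheticParams,
    e_step,
    fit_mixture,
    initialize_responsibilities,
    label_components,
    log_likelihood,
    m_step,
    predict_component,
    simulate_qc_metrics,
)
from mixqc.mixture import SplineBasis, design_matrix, design_row

from conftest import make_cells


def gaussian(y, mean, var):
    return np.exp(-0.5 * (y - mean) ** 2 / var) / np.sqrt(2 * np.pi * var)


class TestDesignRow:
    def test_linear_and_intercept_forms(self):
        assert list(design_row(100.0, "linear")) == [1.0, 100.0]
        assert list(design_row(200.0, "linear")) == [1.0, 200.0]
        assert list(design_row(123.0, "intercept_only")) == [1.0]

    def test_complete_basis_partition_of_unity(self):
        x = np.linspace(10, 500, 200)
        basis = SplineBasis.from_training(x, df=3, degree=3)
        B = basis.complete_basis(x)
        assert B.shape == (200, 4)
        assert np.allclose(B.sum(axis=1), 1.0)

    def test_basis_matches_per_function_bspline_evaluation(self):
        # independent route: evaluate each basis function as its own BSpline
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 100, 150)
        basis = SplineBasis.from_training(x, df=5, degree=3)
        t = basis.knots
        n_basis = len(t) - basis.degree - 1
        ref = np.column_stack(
            [
                BSpline(t, np.eye(n_basis)[j], basis.degree, extrapolate=False)(x)
                for j in range(n_basis)
            ]
        )
        ref = np.nan_to_num(ref)
        ref[x == basis.hi, -1] = 1.0  # right-endpoint convention
        assert np.allclose(basis.complete_basis(x), ref, atol=1e-12)

    def test_out_of_range_prediction_clamps_with_warning(self):
        x = np.linspace(10, 100, 50)
        basis = SplineBasis.from_training(x, df=3, degree=3)
        with pytest.warns(UserWarning, match="clamped"):
            row_out = basis.basis(np.array([150.0]))
        row_edge = basis.basis(np.array([100.0]))
        assert np.allclose(row_out, row_edge)

    def test_spline_df_counts_dropped_basis_columns(self):
        x = np.linspace(0, 1, 60)
        A = design_matrix(x, "spline", SplineBasis.from_training(x, df=4, degree=3))
        assert A.shape == (60, 5)  # intercept + df


class TestInitializeResponsibilities:
    def test_quantile_split_example(self):
        cells = make_cells([10, 20, 30, 40], [1.0, 2.0, 3.0, 90.0])
        resp = initialize_responsibilities(cells, "quantile")
        assert np.allclose(resp[:, 1], [0.05, 0.05, 0.05, 0.95])

    def test_random_is_seed_reproducible(self):
        cells = make_cells(np.arange(10) + 1, np.linspace(0, 50, 10))
        a = initialize_responsibilities(cells, "random", seed=7)
        b = initialize_responsibilities(cells, "random", seed=7)
        assert np.array_equal(a, b)

    def test_random_pairs_valid_over_seeds(self):
        cells = make_cells(np.arange(20) + 1, np.linspace(0, 50, 20))
        for seed in range(10):
            resp = initialize_responsibilities(cells, "random", seed=seed)
            assert ((resp > 0) & (resp < 1)).all()
            assert np.allclose(resp.sum(axis=1), 1.0)

    def test_constant_pct_falls_back_to_random(self):
        cells = make_cells(np.arange(5) + 1, np.full(5, 3.0))
        with pytest.warns(UserWarning, match="identical"):
            resp = initialize_responsibilities(cells, "quantile", seed=1)
        assert np.allclose(resp.sum(axis=1), 1.0)


class TestEStep:
    spec = ModelSpec()

    def test_identical_components_return_prior(self):
        cells = make_cells([100, 500, 900], [3.0, 7.0, 50.0])
        comps = [ComponentParams([2.0, 0.01], 4.0)] * 2
        gamma = e_step(cells, self.spec, np.array([0.7, 0.3]), comps)
        assert np.allclose(gamma[:, 1], 0.3)

    def test_equidistant_symmetry(self):
        cells = make_cells([100], [5.0])
        comps = [ComponentParams([0.0, 0.0], 1.0), ComponentParams([10.0, 0.0], 1.0)]
        gamma = e_step(cells, self.spec, np.array([0.5, 0.5]), comps)
        assert gamma[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_matches_plain_density_bayes_formula(self):
        cells = make_cells([1000], [15.0])
        comps = [ComponentParams([2.0, 0.0], 1.0), ComponentParams([30.0, -0.01], 25.0)]
        w = np.array([0.6, 0.4])
        gamma = e_step(cells, self.spec, w, comps)
        d0 = 0.6 * gaussian(15.0, 2.0, 1.0)
        d1 = 0.4 * gaussian(15.0, 30.0 - 0.01 * 1000, 25.0)
        assert gamma[0, 1] == pytest.approx(d1 / (d0 + d1), rel=1e-12)

    def test_rows_sum_to_one_exactly(self):
        rng = np.random.default_rng(5)
        cells = make_cells(rng.integers(100, 5000, 200), rng.uniform(0, 100, 200))
        comps = [ComponentParams([1.5, 0.0005], 2.0), ComponentParams([45.0, -0.01], 60.0)]
        gamma = e_step(cells, self.spec, np.array([0.75, 0.25]), comps)
        assert np.all(gamma.sum(axis=1) == pytest.approx(1.0, abs=1e-15))

    def test_zero_total_density_falls_back_to_prior(self):
        # means so extreme both log-densities overflow to -inf
        cells = make_cells([100], [50.0])
        comps = [ComponentParams([1e200, 0.0], 1e-6), ComponentParams([-1e200, 0.0], 1e-6)]
        with pytest.warns(UserWarning, match="zero total density"):
            gamma = e_step(cells, self.spec, np.array([0.7, 0.3]), comps)
        assert gamma[0, 1] == pytest.approx(0.3)

    def test_invalid_weights_rejected(self):
        cells = make_cells([100], [5.0])
        comps = [ComponentParams([0.0, 0.0], 1.0)] * 2
        with pytest.raises(ValueError):
            e_step(cells, self.spec, np.array([0.7, 0.7]), comps)


class TestMStep:
    spec = ModelSpec()

    def test_perfect_flat_split_recovers_lines(self):
        y = np.array([2.0, 2.0, 2.0, 20.0, 20.0, 20.0])
        cells = make_cells([100, 200, 300, 100, 200, 300], y)
        resp1 = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        w, comps, degen = m_step(cells, np.column_stack([1 - resp1, resp1]), self.spec)
        assert comps[0].coefficients[0] == pytest.approx(2.0)
        assert comps[1].coefficients[0] == pytest.approx(20.0)
        assert comps[0].variance == pytest.approx(1e-6)  # floored
        assert degen  # variance floor hit

    def test_constant_responsibility_gives_mean_weight(self):
        cells = make_cells(np.arange(8) + 100, np.linspace(1, 30, 8))
        resp1 = np.full(8, 0.25)
        w, _, _ = m_step(cells, np.column_stack([1 - resp1, resp1]), self.spec)
        assert w[1] == pytest.approx(0.25)

    def test_matches_weighted_normal_equations_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.integers(100, 3000, 6).astype(float)
        y = rng.uniform(0, 60, 6)
        cells = make_cells(x, y)
        g1 = rng.uniform(0.05, 0.95, 6)
        gamma = np.column_stack([1 - g1, g1])
        _, comps, _ = m_step(cells, gamma, self.spec)
        A = np.column_stack([np.ones(6), x])
        for z in (0, 1):
            W = np.diag(gamma[:, z])
            beta = np.linalg.solve(A.T @ W @ A, A.T @ W @ y)
            assert np.allclose(comps[z].coefficients, beta, rtol=1e-9)
            resid = y - A @ beta
            var = (gamma[:, z] * resid**2).sum() / gamma[:, z].sum()
            assert comps[z].variance == pytest.approx(var)

    def test_rank_deficient_design_is_fatal(self):
        cells = make_cells(np.full(6, 500), np.linspace(1, 30, 6))  # constant x
        resp1 = np.full(6, 0.5)
        with pytest.raises(np.linalg.LinAlgError, match="rank-deficient"):
            m_step(cells, np.column_stack([1 - resp1, resp1]), self.spec)

    def test_weight_below_floor_flags_degenerate(self):
        cells = make_cells(np.arange(10) * 100 + 100, np.linspace(1, 40, 10))
        resp1 = np.full(10, 0.01)
        _, _, degen = m_step(cells, np.column_stack([1 - resp1, resp1]), self.spec)
        assert degen


class TestLogLikelihood:
    spec = ModelSpec()

    def test_single_component_reduces_to_gaussian_regression(self):
        rng = np.random.default_rng(7)
        x = rng.integers(100, 2000, 50).astype(float)
        y = 2.0 + 0.001 * x + rng.normal(0, 1, 50)
        cells = make_cells(x, y)
        comps = [ComponentParams([2.0, 0.001], 1.0), ComponentParams([50.0, 0.0], 1.0)]
        ll = log_likelihood(cells, self.spec, np.array([1.0, 0.0]), comps)
        mean = 2.0 + 0.001 * x
        direct = np.sum(-0.5 * np.log(2 * np.pi) - 0.5 * (y - mean) ** 2)
        assert ll == pytest.approx(direct, rel=1e-12)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(100, 2000, 30)
        y = rng.uniform(0, 60, 30)
        comps = [ComponentParams([1.5, 0.0005], 2.0), ComponentParams([45.0, -0.01], 60.0)]
        w = np.array([0.7, 0.3])
        a = log_likelihood(make_cells(x, y), self.spec, w, comps)
        p = rng.permutation(30)
        b = log_likelihood(make_cells(x[p], y[p]), self.spec, w, comps)
        assert a == pytest.approx(b, rel=1e-13)

    def test_matches_naive_density_summation(self):
        rng = np.random.default_rng(9)
        x = rng.integers(100, 3000, 100).astype(float)
        y = rng.uniform(0, 60, 100)
        cells = make_cells(x, y)
        comps = [ComponentParams([1.5, 0.0005], 4.0), ComponentParams([45.0, -0.01], 64.0)]
        w = np.array([0.75, 0.25])
        ll = log_likelihood(cells, self.spec, w, comps)
        naive = np.log(
            w[0] * gaussian(y, 1.5 + 0.0005 * x, 4.0)
            + w[1] * gaussian(y, 45.0 - 0.01 * x, 64.0)
        ).sum()
        assert ll == pytest.approx(naive, rel=1e-10)


class TestFitMixture:
    def test_underdetermined_sample_rejected(self):
        cells = make_cells([100, 200, 300], [1.0, 2.0, 50.0])
        with pytest.raises(ValueError, match="free parameters"):
            fit_mixture(cells)

    def test_constant_pct_rejected(self):
        cells = make_cells(np.arange(20) + 100, np.full(20, 5.0))
        with pytest.raises(ValueError, match="distinct"):
            fit_mixture(cells)

    def test_parameter_recovery_on_default_sample(self, default_fit):
        _, fit = default_fit
        b0_i = fit.components[fit.intact_index].coefficients[0]
        b0_c = fit.components[fit.compromised_index].coefficients[0]
        assert abs(b0_i - 1.5) / 1.5 < 0.10
        assert abs(b0_c - 45.0) / 45.0 < 0.10
        assert fit.converged
        assert not fit.degenerate

    def test_loglik_trace_nondecreasing(self):
        for seed in range(5):
            cells = simulate_qc_metrics(SyntheticParams(n_cells=800, seed=seed))
            fit = fit_mixture(cells, seed=seed)
            trace = np.array(fit.loglik_trace)
            assert (np.diff(trace) >= -1e-8 * np.abs(trace[:-1])).all()

    def test_fit_invariant_to_cell_order(self):
        cells = simulate_qc_metrics(SyntheticParams(n_cells=1000, seed=3))
        fit1 = fit_mixture(cells, seed=3)
        shuffled = cells.sample(frac=1.0, random_state=0).reset_index(drop=True)
        fit2 = fit_mixture(shuffled, seed=3)
        assert np.allclose(np.sort(fit1.weights), np.sort(fit2.weights), atol=1e-6)
        for z in (0, 1):
            assert np.allclose(
                fit1.components[fit1.compromised_index].coefficients,
                fit2.components[fit2.compromised_index].coefficients,
                atol=1e-5,
            )

    def test_restarts_return_best_loglik(self):
        cells = simulate_qc_metrics(SyntheticParams(n_cells=600, seed=4))
        fit1 = fit_mixture(cells, restarts=1, seed=4)
        fit3 = fit_mixture(cells, restarts=3, seed=4)
        assert fit3.loglik_trace[-1] >= fit1.loglik_trace[-1] - 1e-6
        assert fit3.n_restarts_used == 3

    def test_single_population_raises_advisory(self):
        cells = simulate_qc_metrics(
            SyntheticParams(n_cells=1500, pi_compromised=0.0, seed=5)
        )
        with pytest.raises(SinglePopulationError, match="MAD"):
            fit_mixture(cells, seed=5)

    def test_spline_variant_fits_and_labels(self):
        cells = simulate_qc_metrics(SyntheticParams(n_cells=2000, seed=6))
        spec = ModelSpec("linear", "spline", spline_df=4)
        fit = fit_mixture(cells, spec, seed=6)
        x_min = cells["detected_genes"].min()
        lo = predict_component(fit, fit.intact_index, float(x_min))
        hi = predict_component(fit, fit.compromised_index, float(x_min))
        assert hi > lo


class TestLabelComponents:
    def _fit(self, spec, comps, x_min=100.0, basis=None):
        return MixtureFit(
            spec=spec,
            weights=np.array([0.5, 0.5]),
            components=comps,
            compromised_index=-1,
            loglik_trace=[0.0],
            converged=True,
            n_iter=1,
            n_restarts_used=1,
            degenerate=False,
            basis=basis,
            x_min=x_min,
        )

    def test_greater_intercept_is_compromised(self):
        fit = self._fit(
            ModelSpec(),
            [ComponentParams([30.0, -0.01], 4.0), ComponentParams([2.0, 0.001], 1.0)],
        )
        assert label_components(fit).compromised_index == 0

    def test_intercept_only_uses_means(self):
        fit = self._fit(
            ModelSpec("intercept_only", "intercept_only"),
            [ComponentParams([3.0], 1.0), ComponentParams([60.0], 4.0)],
        )
        assert label_components(fit).compromised_index == 1

    def test_spline_labeling_matches_prediction_at_min_x(self, default_cells):
        spec = ModelSpec("linear", "spline")
        fit = fit_mixture(default_cells, spec, seed=11)
        x_min = float(fit.x_min)
        preds = [
            float(
                design_matrix(np.array([x_min]), spec.form(z), fit.basis)[0]
                @ fit.components[z].coefficients
            )
            for z in (0, 1)
        ]
        assert fit.compromised_index == int(np.argmax(preds))

    def test_exact_tie_is_fatal(self):
        fit = self._fit(
            ModelSpec(),
            [ComponentParams([5.0, 0.0], 1.0), ComponentParams([5.0, 0.1], 1.0)],
        )
        with pytest.raises(ValueError, match="identical intercepts"):
            label_components(fit)


class TestPredictComponent:
    def test_linear_arithmetic(self, default_fit):
        _, fit = default_fit
        z = fit.intact_index
        b0, b1 = fit.components[z].coefficients
        assert predict_component(fit, z, 1000.0) == pytest.approx(b0 + 1000 * b1)

    def test_intercept_only_constant(self):
        cells = simulate_qc_metrics(SyntheticParams(n_cells=1500, seed=7))
        fit = fit_mixture(cells, ModelSpec("intercept_only", "intercept_only"), seed=7)
        mu = fit.components[0].coefficients[0]
        assert predict_component(fit, 0, 5.0) == predict_component(fit, 0, 5000.0) == mu


class TestSerialization:
    def test_json_round_trip_is_bit_exact(self, default_fit):
        _, fit = default_fit
        blob = json.dumps(fit.to_dict())
        back = MixtureFit.from_dict(json.loads(blob))
        assert back.to_dict() == fit.to_dict()
        for z in (0, 1):
            assert np.array_equal(back.components[z].coefficients, fit.components[z].coefficients)
            assert back.components[z].variance == fit.components[z].variance
        assert np.array_equal(back.weights, fit.weights)
        assert back.loglik_trace == fit.loglik_trace


def univariate_gmm_em(y, resp, n_iter):
    """Independent textbook EM for a 2-component 1-D Gaussian mixture."""
    y = np.asarray(y, dtype=float)
    for _ in range(n_iter):
        w = resp.mean(axis=0)
        mu = (resp * y[:, None]).sum(axis=0) / resp.sum(axis=0)
        var = (resp * (y[:, None] - mu) ** 2).sum(axis=0) / resp.sum(axis=0)
        var = np.maximum(var, 1e-6)
        dens = w * np.exp(-0.5 * (y[:, None] - mu) ** 2 / var) / np.sqrt(2 * np.pi * var)
        resp = dens / dens.sum(axis=1, keepdims=True)
    return w, mu, var


class TestGaussianVariantEquivalence:
    def test_matches_independent_univariate_em(self):
        cells = simulate_qc_metrics(SyntheticParams(n_cells=1200, seed=8))
        spec = ModelSpec("intercept_only", "intercept_only")
        resp0 = initialize_responsibilities(cells, "quantile")

        w, comps, _ = m_step(cells, resp0, spec)
        resp = resp0
        for _ in range(200):
            resp = e_step(cells, spec, w, comps)
            w, comps, _ = m_step(cells, resp, spec)

        ow, omu, ovar = univariate_gmm_em(
            cells["pct_mito"].to_numpy(), resp0.copy(), n_iter=201
        )
        assert np.allclose(w, ow, atol=1e-6)
        assert np.allclose([c.coefficients[0] for c in comps], omu, atol=1e-6)
        assert np.allclose([c.variance for c in comps], ovar, atol=1e-6)
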
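"""Error model estimation and multistart weighted least-squares fitting."""

import numpy as np
import pytest

from protdyn import (
    ErrorModel,
    KineticParameters,
    MrnaTrajectory,
    ProteinTrajectory,
    TimeGrid,
    estimate_error_model,
    fit_all_variants,
    fit_model,
    rescale_proteins,
    solve_protein,
    wls_cost,
)

from conftest import random_mrna


class TestErrorModel:
    def test_exact_linear_replicates_recovered(self, rng):
        """Replicate cells whose sd is exactly 0.169 x mean give back the model."""
        means = rng.uniform(10, 1000, size=(30, 14))
        reps = np.empty((30, 14, 4))
        # construct 4 replicates with exact mean m and sd 0.169*m per cell
        base = np.array([-1.5, -0.5, 0.5, 1.5])
        base = (base - base.mean()) / base.std(ddof=1)
        for k in range(4):
            reps[:, :, k] = means + 0.169 * means * base[k]
        em = estimate_error_model(reps)
        assert em.slope == pytest.approx(0.169, abs=1e-12)
        assert em.intercept == pytest.approx(0.0, abs=1e-9)

    def test_sampling_recovery_at_default_noise(self):
        rng = np.random.default_rng(42)
        means = rng.uniform(10, 1000, size=500)
        reps = means[:, None] + rng.normal(0, 0.169 * means[:, None], size=(500, 4))
        em = estimate_error_model(reps[:, None, :].reshape(500, 1, 4))
        assert em.slope == pytest.approx(0.169, abs=0.02)

    def test_single_replicate_falls_back_with_warning(self, rng):
        reps = rng.uniform(1, 10, size=(5, 14, 1))
        with pytest.warns(UserWarning, match="default error model"):
            em = estimate_error_model(reps)
        assert (em.slope, em.intercept) == (0.169, 0.0)

    def test_sigma_floor(self):
        em = ErrorModel(slope=0.1, intercept=0.0, sigma_floor=1e-3)
        assert em.sigma(0.0) == 1e-3


class TestRescale:
    def test_constant_matrix(self):
        m, f = rescale_proteins(np.full((3, 4), 4.0))
        assert np.allclose(m, 1.0) and f == 4.0

    def test_two_values(self):
        m, f = rescale_proteins(np.array([[2.0, 4.0]]))
        assert np.allclose(m, [2 / 3, 4 / 3]) and f == 3.0

    def test_round_trip(self, rng):
        mat = rng.uniform(1, 100, size=(10, 14))
        mat[rng.random(mat.shape) < 0.1] = np.nan
        scaled, f = rescale_proteins(mat)
        back = scaled * f
        assert np.allclose(back[np.isfinite(back)], mat[np.isfinite(mat)])

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            rescale_proteins(np.full((2, 2), np.nan))


class TestWlsCost:
    def test_zero_when_model_equals_data(self, grid, rng, err):
        mrna = random_mrna(rng, grid)
        p = KineticParameters(y0=5.0, lambda_=0.2, alpha=0.01, variant="production")
        y = solve_protein(p, mrna, grid.times)
        protein = ProteinTrajectory("g", y, grid)
        assert wls_cost(p, mrna, protein, err) == pytest.approx(0.0, abs=1e-20)

    def test_hand_arithmetic(self):
        """Residuals (1, -1) with sigma (1, 0.5) give chi2 = 1 + 4 = 5."""
        grid = TimeGrid((0.0, 1.0))
        mrna = MrnaTrajectory("g", [1.0, 1.0], grid)
        p = KineticParameters(y0=2.0, variant="stationary")
        # data: 1 and 3 -> residuals 1 and -1; sigma from slope*data: 1, 0.5
        protein = ProteinTrajectory("g", [1.0, 3.0], grid)
        err = ErrorModel(slope=1.0, intercept=0.0)
        # sigma = data itself = (1, 3): chi2 = 1/1 + 1/9
        assert wls_cost(p, mrna, protein, err) == pytest.approx(1 + 1 / 9)

    def test_matches_naive_loop(self, grid, rng, err):
        mrna = random_mrna(rng, grid)
        p = KineticParameters(y0=3.0, lambda_=0.5, alpha=0.02, variant="production")
        data = rng.uniform(1, 10, size=len(grid))
        data[[2, 7]] = np.nan
        protein = ProteinTrajectory("g", data, grid)
        chi2 = 0.0
        for t, y in zip(grid.times, data):
            if not np.isfinite(y):
                continue
            sigma = max(0.169 * y, err.sigma_floor)
            chi2 += (solve_protein(p, mrna, [t])[0] - y) ** 2 / sigma**2
        assert wls_cost(p, mrna, protein, err) == pytest.approx(chi2, rel=1e-12)

    def test_missing_points_contribute_nothing(self, grid, rng, err):
        mrna = random_mrna(rng, grid)
        p = KineticParameters(y0=5.0, variant="stationary")
        full = ProteinTrajectory("g", np.full(len(grid), 6.0), grid)
        v = np.full(len(grid), 6.0)
        v[3] = np.nan
        masked = ProteinTrajectory("g", v, grid)
        ratio = wls_cost(p, mrna, masked, err) / wls_cost(p, mrna, full, err)
        assert ratio == pytest.approx(13 / 14)


class TestFitModel:
    def test_stationary_closed_form_equal_sigma(self, grid, rng):
        mrna = random_mrna(rng, grid)
        protein = ProteinTrajectory("g", np.full(len(grid), 7.5), grid)
        fit = fit_model("stationary", mrna, protein, ErrorModel(slope=0.0, intercept=1.0))
        assert fit.params.y0 == pytest.approx(7.5)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-20)

    def test_stationary_weighted_mean(self, grid, rng):
        mrna = random_mrna(rng, grid)
        data = rng.uniform(2, 4, size=len(grid))
        err = ErrorModel()
        fit = fit_model("stationary", mrna, protein := ProteinTrajectory("g", data, grid), err)
        w = 1 / err.sigma(data) ** 2
        assert fit.params.y0 == pytest.approx(float(np.sum(w * data) / np.sum(w)))
        assert fit.chi2 == pytest.approx(float(fit.residuals @ fit.residuals))

    def test_noise_free_production_recovery(self, production_gene, err):
        mrna, protein, truth = production_gene
        fit = fit_model("production", mrna, protein, err, seed=0)
        assert fit.converged
        assert fit.params.y0 == pytest.approx(truth["y0"], rel=1e-2)
        assert fit.params.lambda_ == pytest.approx(truth["lambda_"], rel=1e-2)
        assert fit.params.alpha == pytest.approx(truth["alpha"], rel=1e-2)

    def test_delayed_tau_recovery(self, grid, err):
        """Noise-free delayed-production data with tau = 4 h: tau back within 0.25 h."""
        rng = np.random.default_rng(3)
        mrna = random_mrna(rng, grid)
        truth = KineticParameters(y0=5.0, lambda_=0.4, alpha=0.02, tau=4.0,
                                  variant="delayed_production")
        y = solve_protein(truth, mrna, grid.times)
        protein = ProteinTrajectory("g", y, grid)
        fit = fit_model("delayed_production", mrna, protein, err, seed=0)
        assert fit.params.tau == pytest.approx(4.0, abs=0.25)

    def test_determinism(self, grid, err):
        rng = np.random.default_rng(8)
        mrna = random_mrna(rng, grid)
        y = solve_protein(KineticParameters(y0=5, lambda_=0.3, alpha=0.02,
                                            variant="production"), mrna, grid.times)
        protein = ProteinTrajectory("g", y + rng.normal(0, 0.169 * y), grid)
        f1 = fit_model("production", mrna, protein, err, seed=99)
        f2 = fit_model("production", mrna, protein, err, seed=99)
        assert f1.params == f2.params and f1.chi2 == f2.chi2

    def test_scale_covariance(self, grid, err):
        """Scaling protein data by k scales y0 and alpha by k; lambda and chi2 unchanged.

        Holds as long as the scaled optimum stays inside the parameter boxes.
        """
        rng = np.random.default_rng(21)
        mrna = random_mrna(rng, grid)
        y = solve_protein(KineticParameters(y0=5, lambda_=0.3, alpha=0.02,
                                            variant="production"), mrna, grid.times)
        y = y + rng.normal(0, 0.169 * y)
        k = 3.0
        f1 = fit_model("production", mrna, ProteinTrajectory("g", y, grid), err, seed=4)
        f2 = fit_model("production", mrna, ProteinTrajectory("g", k * y, grid), err, seed=4)
        assert f2.params.y0 == pytest.approx(k * f1.params.y0, rel=1e-4)
        assert f2.params.alpha == pytest.approx(k * f1.params.alpha, rel=1e-4)
        assert f2.params.lambda_ == pytest.approx(f1.params.lambda_, rel=1e-4)
        assert f2.chi2 == pytest.approx(f1.chi2, rel=1e-6)

    def test_insufficient_points_raises(self, grid, err, rng):
        mrna = random_mrna(rng, grid)
        v = np.full(len(grid), np.nan)
        v[:3] = 5.0
        with pytest.raises(ValueError, match="cannot constrain"):
            fit_model("production", mrna, ProteinTrajectory("g", v, grid), err)


class TestNesting:
    def test_chain_chi2_monotone(self, grid, err):
        """Richer variants fit at least as well, up to the box-minimum leak."""
        rng = np.random.default_rng(17)
        for seed in range(5):
            mrna = random_mrna(rng, grid)
            y = solve_protein(KineticParameters(y0=10, lambda_=0.3, alpha=0.02,
                                                variant="production"), mrna, grid.times)
            y = y + rng.normal(0, 0.169 * y)
            fits = fit_all_variants(mrna, ProteinTrajectory("g", y, grid), err, seed=seed)
            chis = [fits[v].chi2 for v in
                    ("stationary", "degradation", "production", "delayed_production")]
            for simpler, richer in zip(chis[:-1], chis[1:]):
                assert richer <= simpler + 4.0
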
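"""GP surrogate, acquisition functions and the active-screening loop."""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

from helo import (
    CompoundLibrary,
    GPHyperparams,
    LibrarySpec,
    ValidationError,
    acq_mei,
    acq_mpi,
    acq_optimistic,
    compare_strategies,
    fit_surrogate,
    gen_compound_library,
    run_active_optimization,
)


def gp_posterior_oracle(X, y, Xq, hp):
    """Closed-form GP posterior by direct linear solves (independent route)."""
    X = np.atleast_2d(X)
    Xq = np.atleast_2d(Xq)
    m = y.mean()
    amp2 = hp.amplitude**2

    def kern(A, B):
        sq = ((A[:, None, :] - B[None, :, :]) ** 2).sum(-1)
        return amp2 * np.exp(-sq / (2.0 * hp.length_scale**2))

    K = kern(X, X) + (hp.noise_sd**2 + hp.jitter) * np.eye(len(X))
    Ks = kern(Xq, X)
    Kinv_y = np.linalg.solve(K, y - m)
    mu = m + Ks @ Kinv_y
    var = amp2 - np.einsum("ij,ji->i", Ks, np.linalg.solve(K, Ks.T))
    return mu, np.sqrt(np.maximum(var, 0.0))


class TestSurrogate:
    def test_noiseless_interpolation_at_training_points(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, size=(6, 1))
        y = np.sin(4 * X[:, 0]) + 5.0
        hp = GPHyperparams(noise_sd=0.0)
        mu, sd = fit_surrogate(X, y, hp).predict(X)
        assert np.abs(mu - y).max() < 1e-6
        assert sd.max() < 1e-3

    def test_matches_closed_form_posterior_on_random_1d_problems(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(3, 9))
            X = rng.uniform(0, 1, size=(n, 1))
            y = rng.normal(5.0, 1.0, size=n)
            hp = GPHyperparams(
                amplitude=float(rng.uniform(0.5, 2.0)),
                length_scale=float(rng.uniform(0.1, 0.5)),
                noise_sd=float(rng.uniform(0.0, 0.3)),
            )
            Xq = rng.uniform(-0.2, 1.2, size=(7, 1))
            mu, sd = fit_surrogate(X, y, hp).predict(Xq)
            mu_o, sd_o = gp_posterior_oracle(X, y, Xq, hp)
            assert np.abs(mu - mu_o).max() < 1e-8
            assert np.abs(sd - sd_o).max() < 1e-8

    def test_far_from_data_reverts_to_prior(self):
        X = np.linspace(0, 0.1, 5).reshape(-1, 1)
        y = np.full(5, 5.0)
        hp = GPHyperparams(amplitude=1.3, length_scale=0.05, noise_sd=0.1)
        mu, sd = fit_surrogate(X, y, hp).predict(np.array([[50.0]]))
        assert mu[0] == pytest.approx(5.0, abs=1e-6)
        assert sd[0] == pytest.approx(hp.amplitude, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_surrogate(np.array([[0.0]]), np.array([1.0]))

    def test_marginal_likelihood_fit_improves_misspecified_lengthscale(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, size=(25, 1))
        y = np.sin(6 * X[:, 0])
        Xq = rng.uniform(0, 1, size=(40, 1))
        truth = np.sin(6 * Xq[:, 0])
        bad = GPHyperparams(length_scale=5.0, noise_sd=0.01)
        fitted = GPHyperparams(length_scale=5.0, noise_sd=0.01, optimize=True)
        err_bad = np.abs(fit_surrogate(X, y, bad).predict(Xq)[0] - truth).mean()
        err_fit = np.abs(fit_surrogate(X, y, fitted).predict(Xq)[0] - truth).mean()
        assert err_fit < err_bad


class TestAcquisitions:
    def test_mpi_symmetry_and_point_mass_limits(self):
        assert acq_mpi(1.0, 2.0, 1.0) == pytest.approx(0.5)
        assert acq_mpi(0.5, 0.0, 1.0) == 0.0
        assert acq_mpi(1.5, 0.0, 1.0) == 1.0

    def test_mpi_matches_quadrature_of_normal_density(self):
        mu, sigma, y = 1.0, 2.0, 0.0
        oracle, _ = integrate.quad(lambda t: norm.pdf(t, mu, sigma), y, np.inf)
        assert acq_mpi(mu, sigma, y) == pytest.approx(oracle, abs=1e-10)

    def test_mei_point_mass_limits(self):
        assert acq_mei(0.5, 0.0, 1.0) == 0.0
        assert acq_mei(1.5, 0.0, 1.0) == pytest.approx(0.5)

    def test_mei_matches_monte_carlo_expectation(self):
        mu, sigma, y = 0.7, 1.0, 0.7
        draws = np.random.default_rng(42).normal(mu, sigma, size=2_000_000)
        imp = np.maximum(draws - y, 0.0)
        se = imp.std() / math.sqrt(len(imp))
        assert abs(acq_mei(mu, sigma, y) - imp.mean()) < 3 * se

    def test_mei_matches_quadrature(self):
        mu, sigma, y = 0.3, 0.8, 0.9
        oracle, _ = integrate.quad(
            lambda t: (t - y) * norm.pdf(t, mu, sigma), y, np.inf
        )
        assert acq_mei(mu, sigma, y) == pytest.approx(oracle, abs=1e-8)

    def test_mei_nondecreasing_in_mu(self):
        mus = np.linspace(-3, 3, 61)
        vals = acq_mei(mus, np.full_like(mus, 0.7), np.zeros_like(mus))
        assert (np.diff(vals) >= -1e-12).all()

    def test_optimistic_hand_values_and_monotonicity(self):
        assert acq_optimistic(1.0, 0.5, beta=0.0) == 1.0
        assert acq_optimistic(1.0, 0.5, beta=2.0) == pytest.approx(2.0)
        sigmas = np.linspace(0, 2, 21)
        vals = acq_optimistic(np.zeros_like(sigmas), sigmas, beta=1.5)
        assert (np.diff(vals) > 0).all()

    def test_bounds_invariants_on_grid(self):
        rng = np.random.default_rng(5)
        mu = rng.normal(size=200)
        sigma = np.abs(rng.normal(size=200))
        y = rng.normal(size=200)
        p = acq_mpi(mu, sigma, y)
        assert ((0.0 <= p) & (p <= 1.0)).all()
        assert (acq_mei(mu, sigma, y) >= 0.0).all()

    def test_negative_sigma_rejected(self):
        for fn in (lambda: acq_mpi(0, -1, 0), lambda: acq_mei(0, -1, 0),
                   lambda: acq_optimistic(0, -1)):
            with pytest.raises(ValidationError):
                fn()


def peak_library(n=80, noise_sd=0.0, seed=0):
    """Noiseless 1-D library with a single smooth activity peak."""
    spec = LibrarySpec(
        n_compounds=n, n_features=1, centers=((0.62,),), widths=(0.15,),
        heights=(2.0,), noise_sd=noise_sd, seed=seed,
    )
    return gen_compound_library(spec)


class TestRunLoop:
    def test_budget_equal_bootstrap_returns_pure_bootstrap(self):
        lib = peak_library()
        res = run_active_optimization(lib, "mei", budget=10, bootstrap_n=10, seed=4)
        assert res.records == []
        assert len(res.measured) == 10
        assert set(res.bootstrap_ids) == set(res.measured)

    def test_random_strategy_bit_reproducible_under_seed(self):
        lib = peak_library()
        r1 = run_active_optimization(lib, "random", budget=25, seed=11)
        r2 = run_active_optimization(lib, "random", budget=25, seed=11)
        assert [r.selected_id for r in r1.records] == [
            r.selected_id for r in r2.records
        ]
        assert r1.measured == r2.measured

    def test_same_seed_gives_same_bootstrap_across_strategies(self):
        lib = peak_library()
        runs = {
            s: run_active_optimization(lib, s, budget=15, seed=2)
            for s in ("mpi", "mei", "optimistic", "random")
        }
        boots = {tuple(r.bootstrap_ids) for r in runs.values()}
        assert len(boots) == 1

    def test_no_compound_measured_twice_and_budget_respected(self):
        lib = peak_library()
        res = run_active_optimization(lib, "mpi", budget=30, seed=7)
        assert len(res.measured) == 30
        picked = [r.selected_id for r in res.records]
        assert len(set(picked)) == len(picked)
        assert not set(picked) & set(res.bootstrap_ids)

    def test_running_best_is_nondecreasing(self):
        lib = peak_library(noise_sd=0.05)
        res = run_active_optimization(lib, "optimistic", budget=30, seed=3)
        assert (np.diff(res.best_trajectory) >= 0).all()

    def test_mei_finds_global_best_on_smooth_peak(self):
        lib = peak_library()
        res = run_active_optimization(lib, "mei", budget=30, seed=5)
        exhaustive_best = float(lib.true_activity.max())  # argmax oracle
        assert res.best_found == pytest.approx(exhaustive_best)

    def test_probability_records_are_valid(self):
        lib = peak_library(noise_sd=0.05)
        res = run_active_optimization(lib, "mpi", budget=20, seed=6)
        for rec in res.records:
            assert 0.0 <= rec.p_improve_bootstrap <= 1.0
            assert 0.0 <= rec.p_improve_current <= 1.0
            assert 0.0 <= rec.p_max_remaining <= 1.0

    def test_budget_beyond_library_rejected(self):
        with pytest.raises(ValidationError):
            run_active_optimization(peak_library(n=20), "mei", budget=30, seed=0)


class TestCompareStrategies:
    def test_single_rep_reduces_to_single_runs(self):
        gen = lambda seed: peak_library(seed=seed)
        table = compare_strategies(gen, strategies=("mei",), reps=1, budget=15)
        single = run_active_optimization(peak_library(seed=0), "mei", budget=15, seed=0)
        assert table.loc[0, "best_mean"] == pytest.approx(single.best_found)

    def test_constant_activity_library_gives_identical_performance(self):
        def gen(seed):
            rng = np.random.default_rng(seed)
            X = rng.uniform(0, 1, size=(40, 2))
            return CompoundLibrary(
                [f"c{i}" for i in range(40)], X, np.full(40, 5.0)
            )

        table = compare_strategies(gen, reps=2, budget=15)
        assert table["best_mean"].nunique() == 1
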
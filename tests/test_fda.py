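import warnings

import numpy as np
import pytest

import gaitadapt as ga
from gaitadapt.data import TrialMatrix, ValidationError
from gaitadapt.fda import (SplineModel, SplinePosterior, build_basis,
                           curve_and_derivative_samples, default_knots,
                           gibbs_fda, rate_functions, time_varying_rates)


def _mini_model(T=60):
    knots = np.array([12.0, 24.0, 36.0, 48.0])
    return SplineModel(knots=knots)


def _posterior_from_betas(betas, T, knots):
    betas = np.asarray(betas, dtype=float)
    if betas.ndim == 2:
        betas = betas[None, :, :]
    G, S, _ = betas.shape
    return SplinePosterior(
        groups=tuple(f"G{j+1}" for j in range(G)), beta_samples=betas,
        m_samples=np.zeros((G, S, T)), alpha_samples=np.ones((G, S)),
        sigma_d2_samples=np.ones((G, S)), sigma_e2_samples=np.ones(S),
        S=S, burn_in=0, seed=0, time_index=np.arange(1.0, T + 1))


class TestBasis:
    def test_truncated_terms_vanish_left_of_knot(self):
        X = build_basis(np.array([12.0]), np.array([12.0, 24.0]))
        assert X.shape == (1, 6)
        assert X[0, 4] == 0.0 and X[0, 5] == 0.0

    def test_truncated_term_cubic_right_of_knot(self):
        X = build_basis(np.array([14.0]), np.array([12.0]))
        assert X[0, -1] == 8.0  # (14-12)^3
        assert np.allclose(X[0, :4], [1.0, 14.0, 196.0, 2744.0])

    def test_study_defaults_shape(self):
        X = build_basis(np.arange(1.0, 501), default_knots())
        assert X.shape == (500, 23)

    def test_duplicate_knots_rejected(self):
        with pytest.raises(ValidationError):
            build_basis(np.arange(10.0), np.array([3.0, 3.0]))

    def test_model_validation(self):
        with pytest.raises(ValidationError):
            SplineModel(knots=np.array([5.0, 4.0]))
        with pytest.raises(ValidationError):
            SplineModel(knots=np.array([1.0, 2.0]),
                        penalty_diag=np.ones(4))
        m = _mini_model()
        with pytest.raises(ValidationError):
            m.check_times(np.arange(1.0, 40.0))  # knot 48 outside range


class TestCurveAndDerivative:
    def test_linear_curve_has_constant_unit_step_difference(self):
        T = 30
        knots = np.array([10.0, 20.0])
        beta = np.array([2.0, 3.0, 0.0, 0.0, 0.0, 0.0])
        post = _posterior_from_betas(beta[None, :], T, knots)
        f, fp = curve_and_derivative_samples(post, SplineModel(knots=knots))
        assert np.allclose(f[0, 0], 2.0 + 3.0 * np.arange(1, T + 1))
        assert np.allclose(fp, 3.0)

    def test_constant_curve_has_zero_derivative(self):
        knots = np.array([10.0, 20.0])
        beta = np.array([7.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        post = _posterior_from_betas(beta[None, :], 30, knots)
        _, fp = curve_and_derivative_samples(post, SplineModel(knots=knots))
        assert np.allclose(fp, 0.0)

    def test_quadratic_first_difference(self):
        # f(tau) = tau^2 -> f(t+1) - f(t) = 2t + 1 exactly
        knots = np.array([10.0, 20.0])
        beta = np.array([0.0, 0.0, 1.0, 0.0, 0.0, 0.0])
        post = _posterior_from_betas(beta[None, :], 30, knots)
        _, fp = curve_and_derivative_samples(post, SplineModel(knots=knots))
        assert np.allclose(fp[0, 0], 2.0 * np.arange(1, 30) + 1.0)

    def test_mean_curve_equals_curve_of_mean_coefficients(self):
        rng = np.random.default_rng(0)
        knots = np.array([10.0, 20.0])
        betas = rng.normal(size=(2, 40, 6))
        post = _posterior_from_betas(betas, 30, knots)
        model = SplineModel(knots=knots)
        f, _ = curve_and_derivative_samples(post, model)
        X = build_basis(post.time_index, knots)
        assert np.allclose(f.mean(axis=1), betas.mean(axis=1) @ X.T,
                           atol=1e-12)


class TestGibbs:
    def test_recovers_cubic_polynomial_mean(self):
        T, n = 60, 5
        times = np.arange(1.0, T + 1)
        truth = 50 + 0.8 * times - 0.02 * times**2 + 1.5e-4 * times**3
        rng = np.random.default_rng(2)
        angles = truth[:, None] + rng.normal(0, 1.0, size=(T, n))
        trials = TrialMatrix(angles, ["G1"] * n, [f"p{i}" for i in range(n)])
        model = _mini_model()
        post = gibbs_fda(trials, model, S=400, burn_in=400, seed=1)
        f, _ = curve_and_derivative_samples(post, model)
        f_hat = f[0].mean(axis=0)
        f_sd = f[0].std(axis=0)
        inner = slice(5, 55)
        assert np.all(np.abs(f_hat - truth)[inner] < 4 * f_sd[inner])

    def test_seeded_determinism(self):
        cfg = ga.SynthConfig(seed=1, T=80, n_per_group=3, jump_step=41)
        trials, _ = ga.generate_cohort(cfg)
        model = SplineModel(knots=default_knots(80, 6))
        a = gibbs_fda(trials, model, S=25, burn_in=25, seed=7)
        b = gibbs_fda(trials, model, S=25, burn_in=25, seed=7)
        assert np.array_equal(a.beta_samples, b.beta_samples)
        assert np.array_equal(a.sigma_e2_samples, b.sigma_e2_samples)

    def test_shift_equivariance_of_mean_curve(self):
        cfg = ga.SynthConfig(seed=3, T=100, n_per_group=5, jump_step=51,
                             participant_offset_sd=0.0)
        trials, _ = ga.generate_cohort(cfg)
        shifted = trials.copy_with(trials.angles + 40.0)
        model = SplineModel(knots=default_knots(100, 6))
        p1 = gibbs_fda(trials, model, S=300, burn_in=300, seed=5)
        p2 = gibbs_fda(shifted, model, S=300, burn_in=300, seed=5)
        f1, d1 = curve_and_derivative_samples(p1, model)
        f2, d2 = curve_and_derivative_samples(p2, model)
        shift = f2.mean(axis=1) - f1.mean(axis=1)
        assert np.abs(shift - 40.0).mean() < 0.3
        assert np.abs(d2.mean(axis=1) - d1.mean(axis=1)).mean() < 0.15

    def test_weaker_smoothing_prior_fits_no_worse(self):
        cfg = ga.SynthConfig(seed=9, T=100, n_per_group=4, jump_step=51)
        trials, _ = ga.generate_cohort(cfg)
        knots = default_knots(100, 6)
        resid = {}
        for B_t in (1e-4, 10.0):
            model = SplineModel(knots=knots, B_t=B_t)
            post = gibbs_fda(trials, model, S=300, burn_in=300, seed=4)
            X = build_basis(trials.time_index, knots)
            m_hat = post.m_samples.mean(axis=1)
            f_hat = post.beta_samples.mean(axis=1) @ X.T
            resid[B_t] = np.linalg.norm(m_hat - f_hat)
        # larger B_t -> smaller alpha* -> weaker smoothing -> closer fit
        assert resid[10.0] <= resid[1e-4] * 1.05

    def test_all_variance_draws_positive(self, small_cohort):
        _, trials, _ = small_cohort
        model = SplineModel(knots=default_knots(trials.T, 8))
        post = gibbs_fda(trials, model, S=50, burn_in=50, seed=0)
        assert np.all(post.sigma_d2_samples > 0)
        assert np.all(post.sigma_e2_samples > 0)
        assert np.all(post.alpha_samples > 0)


class TestRateFunctions:
    def test_unit_denominator_learning_rate(self):
        S, T = 10, 8
        f = np.ones((1, S, T))
        fp = np.zeros((1, S, T - 1))
        ybar = np.full((1, T), 0.05)
        rates = rate_functions(f, fp, ybar)
        assert np.allclose(rates.B, 0.05)
        assert np.allclose(rates.A, 0.0)

    def test_learning_rate_zero_when_mean_matches_derivative(self):
        S, T = 5, 6
        f = np.full((1, S, T), 2.0)
        fp = np.full((1, S, T - 1), 0.3)
        ybar = np.full((1, T), 0.3)
        rates = rate_functions(f, fp, ybar)
        assert np.allclose(rates.B, 0.0)

    def test_single_draw_reconstruction_identity(self, small_cohort):
        _, trials, _ = small_cohort
        model = SplineModel(knots=default_knots(trials.T, 8))
        post = gibbs_fda(trials, model, S=1, burn_in=30, seed=6)
        rates = time_varying_rates(post, model, trials)
        ybar = trials.group_means()
        recon = rates.A + rates.B * rates.f
        assert np.allclose(recon, ybar[:, 1:], atol=1e-10)

    def test_division_guard_flags_near_zero_curves(self):
        S, T = 8, 6
        f = np.full((1, S, T), 1e-9)
        fp = np.zeros((1, S, T - 1))
        ybar = np.zeros((1, T))
        with pytest.warns(RuntimeWarning, match="division floor"):
            rates = rate_functions(f, fp, ybar)
        assert not rates.B_valid.any()
        assert np.all(np.isnan(rates.B))

    def test_band_ordering(self, small_cohort):
        _, trials, _ = small_cohort
        model = SplineModel(knots=default_knots(trials.T, 8))
        post = gibbs_fda(trials, model, S=80, burn_in=80, seed=2)
        rates = time_varying_rates(post, model, trials)
        assert np.all(rates.A_lo <= rates.A_hi)
        ok = rates.B_valid
        assert np.all(rates.B_lo[ok] <= rates.B_hi[ok])


class TestBandOverlap:
    def _rates(self, lo, hi, G=2):
        T = lo.shape[-1]
        arr = lambda x: np.broadcast_to(x, (G, T)).copy()
        mid = (lo + hi) / 2
        return ga.TimeVaryingRates(
            groups=tuple(f"G{j+1}" for j in range(G)),
            steps=np.arange(1, T + 1),
            A=arr(mid[0]) if mid.ndim > 1 else arr(mid), A_lo=lo, A_med=lo,
            A_hi=hi, B=lo.copy(), B_lo=lo, B_med=lo, B_hi=hi,
            B_valid=np.ones((G, T), dtype=bool),
            f=arr(1.0), f_lo=arr(0.5), f_hi=arr(1.5))

    def test_identical_bands_never_disjoint(self):
        lo = np.tile(np.linspace(0, 1, 10), (2, 1))
        hi = lo + 0.5
        flags, runs = ga.band_overlap(self._rates(lo, hi), "B")
        assert not flags["disjoint"].any()
        assert runs.empty

    def test_separated_intervals_flagged(self):
        lo = np.array([[0.0, 0.0, 0.0], [0.0, 2.0, 0.0]])
        hi = np.array([[1.0, 1.0, 1.0], [1.0, 3.0, 1.0]])
        flags, runs = ga.band_overlap(self._rates(lo, hi), "B")
        assert flags["disjoint"].tolist() == [False, True, False]
        assert len(runs) == 1 and runs.iloc[0].length == 1

    def test_grid_mismatch_rejected(self):
        lo = np.zeros((2, 4))
        rates = self._rates(lo, lo + 1.0)
        rates.steps = np.arange(1, 3)
        with pytest.raises(ValidationError):
            ga.band_overlap(rates, "B")
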
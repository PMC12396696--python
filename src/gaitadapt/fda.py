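"""Bayesian cubic P-spline track: smooth group means, derivatives and
time-varying retention / learning-rate functions with credible bands.

Each group mean curve is modelled hierarchically:

    y_ijt = m_jt + eps_ijt,            eps ~ N(0, sigma_e^2)
    m_jt  = f_j(tau_t) + delta_jt,     delta ~ N(0, sigma_jd^2)

with ``f_j`` a cubic truncated-power-basis spline, ``f_j(tau) = beta_0 +
beta_1 tau + beta_2 tau^2 + beta_3 tau^3 + sum_k beta_{k+3} (tau - mu_k)+^3``.
The penalty is a diagonal matrix D with zeros on the four polynomial
coefficients and ones on the knot coefficients, so the global cubic is
unpenalized and the knot terms are shrunk by a Gamma-distributed smoothing
parameter.  A five-block Gibbs sampler (beta_j, m_j, alpha*_j, sigma_jd^2,
sigma_e^2) draws from the joint posterior; curves, first-difference
derivatives and the rate functions

    A_j(tau_t) = f_j'(tau_t),
    B_j(tau_t) = (ybar_{j,t+1} - f_j'(tau_t)) / f_j(tau_t)

are transformed draw by draw, so pointwise credible bands are simple
across-draw quantiles.  Time is unit-spaced stride count, so the first
difference needs no step-width division; derivatives are in degrees/step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import TrialMatrix, ValidationError


def default_knots(T: int = 500, K: int = 19) -> np.ndarray:
    """K equally spaced interior knots: 25, 50, ..., 475 for T=500, K=19."""
    step = T / (K + 1)
    return step * np.arange(1, K + 1)


@dataclass
class SplineModel:
    """Cubic truncated-power P-spline settings and vague hyperpriors.

    ``penalty_diag`` defaults to the rank-K form (zeros on the 4 polynomial
    coefficients); any nonnegative diagonal is accepted and its nonzero count
    is used as the penalty rank in the smoothing-parameter conditional.
    """

    knots: np.ndarray = None  # type: ignore[assignment]
    penalty_diag: np.ndarray = None  # type: ignore[assignment]
    A_t: float = 0.01
    B_t: float = 0.01
    A_d: float = 0.01
    B_d: float = 0.01
    A_e: float = 0.01
    B_e: float = 0.01

    def __post_init__(self) -> None:
        if self.knots is None:
            self.knots = default_knots()
        self.knots = np.asarray(self.knots, dtype=float)
        if np.any(np.diff(self.knots) <= 0):
            raise ValidationError("knots must be strictly increasing")
        if self.penalty_diag is None:
            self.penalty_diag = np.concatenate(
                [np.zeros(4), np.ones(self.K)])
        self.penalty_diag = np.asarray(self.penalty_diag, dtype=float)
        if self.penalty_diag.shape != (self.K + 4,):
            raise ValidationError("penalty diagonal must have length K + 4")
        if np.any(self.penalty_diag < 0):
            raise ValidationError("penalty diagonal must be nonnegative")
        for h in (self.A_t, self.B_t, self.A_d, self.B_d, self.A_e, self.B_e):
            if h <= 0:
                raise ValidationError("hyperparameters must be > 0")

    @property
    def K(self) -> int:
        return self.knots.size

    @property
    def n_basis(self) -> int:
        return self.K + 4

    @property
    def penalty_rank(self) -> int:
        return int(np.count_nonzero(self.penalty_diag))

    def check_times(self, times: np.ndarray) -> None:
        if self.knots[0] <= times[0] or self.knots[-1] >= times[-1]:
            raise ValidationError(
                "knots must lie strictly inside the time range")


def build_basis(times, knots) -> np.ndarray:
    """Design matrix with rows ``[1, tau, tau^2, tau^3, (tau-mu_k)+^3 ...]``."""
    t = np.asarray(times, dtype=float)
    mu = np.asarray(knots, dtype=float)
    if np.unique(mu).size != mu.size:
        raise ValidationError("duplicate knots")
    X = np.empty((t.size, mu.size + 4))
    X[:, 0] = 1.0
    X[:, 1] = t
    X[:, 2] = t**2
    X[:, 3] = t**3
    X[:, 4:] = np.clip(t[:, None] - mu[None, :], 0.0, None) ** 3
    return X


@dataclass
class SplinePosterior:
    """Retained Gibbs draws for all groups."""

    groups: tuple
    beta_samples: np.ndarray      # (G, S, K+4)
    m_samples: np.ndarray         # (G, S, T)
    alpha_samples: np.ndarray     # (G, S)
    sigma_d2_samples: np.ndarray  # (G, S)
    sigma_e2_samples: np.ndarray  # (S,)
    S: int
    burn_in: int
    seed: int
    time_index: np.ndarray


class FdaGibbs:
    """One-sweep Gibbs kernel for the P-spline hierarchy.

    Exposed as a class so the successive-conditional simulator of the
    joint-distribution sampler check can interleave parameter sweeps with
    re-draws of the data.  Internally the basis is column-scaled for
    numerically stable Cholesky solves; draws are mapped back to the
    original coefficient scale, so the sampled posterior is unchanged.
    """

    def __init__(self, y_groups, X: np.ndarray, model: SplineModel, rng):
        self.model = model
        self.rng = rng
        self.X = X
        self.scale = np.linalg.norm(X, axis=0)
        self.Xs = X / self.scale
        self.XtXs = self.Xs.T @ self.Xs
        self.Ds = model.penalty_diag / self.scale**2
        self.set_data(y_groups)
        self.G = len(y_groups)
        self.T = X.shape[0]
        # state
        self.alpha_star = np.ones(self.G)
        self.sigma_d2 = np.ones(self.G)
        self.sigma_e2 = 1.0
        self.m = np.stack([y.mean(axis=1) for y in y_groups])
        self.beta = np.empty((self.G, model.n_basis))
        for j in range(self.G):
            A = self.XtXs + np.diag(self.Ds)
            bs = np.linalg.solve(A, self.Xs.T @ self.m[j])
            self.beta[j] = bs / self.scale

    def set_data(self, y_groups) -> None:
        self.y_groups = [np.asarray(y, dtype=float) for y in y_groups]
        self.n_j = np.array([y.shape[1] for y in self.y_groups])
        self.sum_y = np.stack([y.sum(axis=1) for y in self.y_groups])

    def step(self) -> None:
        rng = self.rng
        md = self.model
        sse_e = 0.0
        for j in range(self.G):
            alpha_j = self.alpha_star[j] * self.sigma_d2[j]
            A = self.XtXs + alpha_j * np.diag(self.Ds)
            L = np.linalg.cholesky(A)
            mean_s = np.linalg.solve(
                L.T, np.linalg.solve(L, self.Xs.T @ self.m[j]))
            z = rng.standard_normal(md.n_basis)
            beta_s = mean_s + np.sqrt(self.sigma_d2[j]) * \
                np.linalg.solve(L.T, z)
            self.beta[j] = beta_s / self.scale
            f = self.Xs @ beta_s

            prec = self.n_j[j] / self.sigma_e2 + 1.0 / self.sigma_d2[j]
            mean_m = (self.sum_y[j] / self.sigma_e2 + f / self.sigma_d2[j]) \
                / prec
            self.m[j] = mean_m + rng.standard_normal(self.T) / np.sqrt(prec)

            quad = float(self.beta[j] @ (md.penalty_diag * self.beta[j]))
            self.alpha_star[j] = rng.standard_gamma(
                md.A_t + md.penalty_rank / 2.0) / (md.B_t + 0.5 * quad)

            resid = self.m[j] - f
            self.sigma_d2[j] = (md.B_d + 0.5 * float(resid @ resid)) / \
                rng.standard_gamma(md.A_d + self.T / 2.0)

            sse_e += float(((self.y_groups[j] - self.m[j][:, None]) ** 2).sum())
        shape_e = md.A_e + self.T * self.n_j.sum() / 2.0
        self.sigma_e2 = (md.B_e + 0.5 * sse_e) / rng.standard_gamma(shape_e)


def gibbs_fda(trials: TrialMatrix, model: SplineModel | None = None,
              S: int = 1000, burn_in: int = 1000,
              seed: int = 0) -> SplinePosterior:
    """Run the five-block Gibbs sampler and retain ``S`` post-burn-in draws."""
    if model is None:
        model = SplineModel(knots=default_knots(trials.T))
    if S < 1 or burn_in < 0:
        raise ValidationError("need S >= 1 and burn_in >= 0")
    if trials.T < model.n_basis:
        raise ValidationError("need T >= K + 4 steps")
    model.check_times(trials.time_index)
    X = build_basis(trials.time_index, model.knots)
    rng = np.random.default_rng(seed)
    sampler = FdaGibbs(trials.group_data(), X, model, rng)
    G = sampler.G
    beta_s = np.empty((G, S, model.n_basis))
    m_s = np.empty((G, S, trials.T))
    alpha_s = np.empty((G, S))
    sd2_s = np.empty((G, S))
    se2_s = np.empty(S)
    for it in range(burn_in + S):
        sampler.step()
        k = it - burn_in
        if k >= 0:
            beta_s[:, k] = sampler.beta
            m_s[:, k] = sampler.m
            alpha_s[:, k] = sampler.alpha_star
            sd2_s[:, k] = sampler.sigma_d2
            se2_s[k] = sampler.sigma_e2
    return SplinePosterior(
        groups=tuple(trials.groups), beta_samples=beta_s, m_samples=m_s,
        alpha_samples=alpha_s, sigma_d2_samples=sd2_s, sigma_e2_samples=se2_s,
        S=S, burn_in=burn_in, seed=seed, time_index=trials.time_index.copy(),
    )


def curve_and_derivative_samples(posterior: SplinePosterior,
                                 model: SplineModel):
    """Per-draw curves ``f_j`` (G, S, T) and unit-step first differences
    ``f_j'`` (G, S, T-1)."""
    X = build_basis(posterior.time_index, model.knots)
    f = posterior.beta_samples @ X.T
    fprime = np.diff(f, axis=-1)
    return f, fprime


@dataclass
class TimeVaryingRates:
    """Time-varying retention / learning-rate estimates with 95% bands.

    ``A`` is in degrees/step (a derivative); ``B`` is dimensionless.  Where
    the estimated curve magnitude falls below the division floor, ``B`` is
    flagged unavailable (``B_valid`` False, NaN entries).
    """

    groups: tuple
    steps: np.ndarray      # (T-1,) time points tau_t
    A: np.ndarray          # (G, T-1) point estimates
    A_lo: np.ndarray
    A_med: np.ndarray
    A_hi: np.ndarray
    B: np.ndarray
    B_lo: np.ndarray
    B_med: np.ndarray
    B_hi: np.ndarray
    B_valid: np.ndarray    # (G, T-1) bool
    f: np.ndarray = None   # (G, T-1) mean curve at tau_t  # type: ignore
    f_lo: np.ndarray = None  # type: ignore
    f_hi: np.ndarray = None  # type: ignore

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, g in enumerate(self.groups):
            rows.append(pd.DataFrame({
                "group": g, "step": self.steps.astype(int),
                "f": self.f[j], "f_lo": self.f_lo[j], "f_hi": self.f_hi[j],
                "A": self.A[j], "A_lo": self.A_lo[j], "A_med": self.A_med[j],
                "A_hi": self.A_hi[j],
                "B": self.B[j], "B_lo": self.B_lo[j], "B_med": self.B_med[j],
                "B_hi": self.B_hi[j], "B_valid": self.B_valid[j],
            }))
        return pd.concat(rows, ignore_index=True)


def rate_functions(f_samples: np.ndarray, fprime_samples: np.ndarray,
                   ybar: np.ndarray, steps=None, groups=None,
                   floor: float = 1e-6) -> TimeVaryingRates:
    """Eq-style transform of curve draws into rate functions with bands.

    Per draw s: ``A^(s)_t = f'^(s)(tau_t)`` and
    ``B^(s)_t = (ybar_{t+1} - f'^(s)(tau_t)) / f^(s)(tau_t)``.  Point
    estimates use the across-draw mean curve and derivative; bands are the
    2.5 / 50 / 97.5 across-draw percentiles of the same transforms.
    """
    f = np.asarray(f_samples, dtype=float)
    fp = np.asarray(fprime_samples, dtype=float)
    ybar = np.atleast_2d(np.asarray(ybar, dtype=float))
    G, S, T = f.shape
    if groups is None:
        groups = tuple(f"G{j + 1}" for j in range(G))
    if steps is None:
        steps = np.arange(1, T)
    f_t = f[:, :, :-1]               # curves at tau_1..tau_{T-1}
    y_next = ybar[:, 1:][:, None, :]  # ybar_{t+1}

    A_draws = fp
    with np.errstate(divide="ignore", invalid="ignore"):
        B_draws = (y_next - fp) / f_t

    f_hat = f_t.mean(axis=1)
    fp_hat = fp.mean(axis=1)
    valid = np.abs(f_hat) >= floor
    if not valid.all():
        warnings.warn(
            "estimated curve magnitude below the division floor at "
            f"{int((~valid).sum())} step(s); learning rate unavailable there "
            "(baseline-adjusted, near-zero-mean data commonly triggers this)",
            RuntimeWarning, stacklevel=2)
    draw_valid = np.all(np.abs(f_t) >= floor, axis=1) & valid
    B_draws = np.where(np.abs(f_t) >= floor, B_draws, np.nan)

    A_lo, A_med, A_hi = np.percentile(A_draws, [2.5, 50.0, 97.5], axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        B_lo, B_med, B_hi = np.nanpercentile(B_draws, [2.5, 50.0, 97.5],
                                             axis=1)
    B_hat = np.where(valid, (ybar[:, 1:] - fp_hat) / np.where(valid, f_hat, 1.0),
                     np.nan)
    f_lo, f_hi = np.percentile(f_t, [2.5, 97.5], axis=1)
    return TimeVaryingRates(
        groups=tuple(groups), steps=np.asarray(steps),
        A=fp_hat, A_lo=A_lo, A_med=A_med, A_hi=A_hi,
        B=B_hat, B_lo=B_lo, B_med=B_med, B_hi=B_hi,
        B_valid=draw_valid,
        f=f_hat, f_lo=f_lo, f_hi=f_hi,
    )


def time_varying_rates(posterior: SplinePosterior, model: SplineModel,
                       trials: TrialMatrix,
                       floor: float = 1e-6) -> TimeVaryingRates:
    """Convenience wrapper: posterior -> rate functions for a cohort."""
    f, fp = curve_and_derivative_samples(posterior, model)
    return rate_functions(f, fp, trials.group_means(),
                          steps=posterior.time_index[:-1],
                          groups=posterior.groups, floor=floor)


def band_overlap(rates: TimeVaryingRates, parameter: str = "B"):
    """Strict-disjointness flags for every group pair at every step.

    Returns ``(flags, runs)``: a tidy frame with one row per (pair, step)
    and a summary frame of contiguous disjoint runs.
    """
    lo = getattr(rates, f"{parameter}_lo")
    hi = getattr(rates, f"{parameter}_hi")
    if lo.shape[1] != rates.steps.size:
        raise ValidationError("step grids do not match")
    G = len(rates.groups)
    rows = []
    run_rows = []
    for a in range(G):
        for b in range(a + 1, G):
            disjoint = (lo[a] > hi[b]) | (lo[b] > hi[a])
            disjoint = np.where(np.isnan(lo[a]) | np.isnan(lo[b]), False,
                                disjoint)
            pair = f"{rates.groups[a]} vs {rates.groups[b]}"
            rows.append(pd.DataFrame({
                "pair": pair, "parameter": parameter,
                "step": rates.steps.astype(int), "disjoint": disjoint,
            }))
            # contiguous runs of disjoint steps
            padded = np.concatenate([[False], disjoint, [False]])
            starts = np.flatnonzero(~padded[:-1] & padded[1:])
            ends = np.flatnonzero(padded[:-1] & ~padded[1:])
            for s0, e0 in zip(starts, ends):
                run_rows.append((pair, parameter,
                                 int(rates.steps[s0]),
                                 int(rates.steps[e0 - 1]), e0 - s0))
    flags = pd.concat(rows, ignore_index=True)
    runs = pd.DataFrame(run_rows, columns=["pair", "parameter", "start",
                                           "end", "length"])
    return flags, runs
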
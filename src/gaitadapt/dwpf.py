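"""Dynamically weighted particle filter for the knee-angle state space model.

At each stride step the group means ``m_jt`` are drawn from their Normal
full conditional (a Gibbs sweep, one draw per particle, conditional on that
particle's noise variances), the per-group noise variances evolve by the
log-AR(1) transition, importance weights are multiplied by the response
likelihood, and the particle population is controlled by splitting heavy
particles and probabilistically pruning light ones.  Splits conserve total
weight exactly; prunes conserve it in expectation.  All weight arithmetic is
in the log domain so 500-step likelihood products never underflow.

Point estimates are simple (unweighted) particle means; 95% bands are the
2.5 / 97.5 particle percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .data import TrialMatrix, ValidationError

LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class SSMPriors:
    """Priors and fixed transition constants for the state space model.

    ``A_mjt`` / ``B_mjt`` are the Normal prior mean / SD of the group means
    (vague by default); ``A_sj`` / ``B_sj`` the inverse-Gamma shape / rate for
    the initial variance; ``a_j`` and ``sigma_u2`` the log-variance AR(1)
    transition constants; ``sigma_0_2`` the variance at step 0.
    """

    A_mjt: float = 0.0
    B_mjt: float = 10.0
    A_sj: float = 2.0
    B_sj: float = 1.0
    a_j: float = 1.0
    sigma_u2: float = 0.01
    sigma_0_2: float = 1.0

    def __post_init__(self) -> None:
        if self.B_mjt <= 0:
            raise ValidationError("prior SD B_mjt must be > 0")
        if self.A_sj <= 1:
            raise ValidationError("inverse-Gamma shape A_sj must be > 1")
        if self.B_sj <= 0:
            raise ValidationError("inverse-Gamma rate B_sj must be > 0")
        if self.sigma_u2 < 0 or self.sigma_0_2 <= 0:
            raise ValidationError("variance constants must be positive")


@dataclass
class ParticlePopulation:
    """A weighted particle population over per-group state values.

    ``values`` has one row per particle; columns are whatever state is being
    carried (noise variances, and optionally the current mean draws).
    Weights are stored as logs.
    """

    values: np.ndarray
    log_weights: np.ndarray
    n_min: int = 1000
    n_max: int = 10000
    theta_high_factor: float = 5.0
    theta_low_factor: float = 0.2

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.log_weights = np.asarray(self.log_weights, dtype=float)
        if self.log_weights.shape[0] != self.values.shape[0]:
            raise ValidationError("one weight per particle required")

    @property
    def size(self) -> int:
        return self.values.shape[0]

    def total_weight(self) -> float:
        return float(np.exp(logsumexp(self.log_weights)))


def sample_group_mean(y_jt, sigma2_jt, priors: SSMPriors, rng):
    """Draw ``m_jt`` from its Normal full conditional.

    ``sigma2_jt`` may be a scalar or an array (one variance per particle);
    the draw matches its shape.  Posterior precision is ``n_j / sigma2 +
    1 / B_mjt**2`` and the posterior mean weighs the data sum against the
    prior mean accordingly.
    """
    y = np.asarray(y_jt, dtype=float)
    if y.size == 0:
        raise ValidationError("empty group")
    s2 = np.asarray(sigma2_jt, dtype=float)
    if np.any(s2 <= 0):
        raise ValidationError("noise variance must be > 0")
    n = y.size
    V = 1.0 / (n / s2 + 1.0 / priors.B_mjt**2)
    M = (y.sum() / s2 + priors.A_mjt / priors.B_mjt**2) * V
    return M + np.sqrt(V) * rng.standard_normal(np.shape(s2))


def sample_initial_variance(y_j1, m_j1, priors: SSMPriors, rng):
    """Draw ``sigma2_j1`` from its inverse-Gamma full conditional.

    Shape ``n_j/2 + A_sj`` and rate ``0.5 * sum (y - m)^2 + B_sj``; with the
    default priors (shape 2, rate 1) these are the ``+2`` / ``+1`` constants.
    ``m_j1`` may be an array of per-particle mean draws.
    """
    y = np.asarray(y_j1, dtype=float)
    if y.size == 0:
        raise ValidationError("empty group")
    m = np.asarray(m_j1, dtype=float)
    n = y.size
    shape = n / 2.0 + priors.A_sj
    rate = 0.5 * ((y**2).sum() - 2.0 * m * y.sum() + n * m**2) + priors.B_sj
    return rate / rng.standard_gamma(shape, size=np.shape(m) or None)


def propagate_particle(lambda_prev, priors: SSMPriors, rng):
    """Advance per-group variances by the log-AR(1) transition."""
    lam = np.asarray(lambda_prev, dtype=float)
    if np.any(lam <= 0):
        raise ValidationError("variances must be > 0")
    log_s2 = priors.a_j * np.log(lam)
    if priors.sigma_u2 > 0:
        log_s2 = log_s2 + rng.normal(0.0, np.sqrt(priors.sigma_u2), size=lam.shape)
    return np.exp(log_s2)


def update_weight(log_weight, y_t, m_t, lambda_t):
    """Multiply a weight by the response likelihood of step ``t`` (log domain).

    ``y_t`` is a sequence of per-group observation vectors; ``m_t`` and
    ``lambda_t`` hold per-group means and variances, either flat ``(G,)`` or
    per-particle ``(N, G)``.  Returns the updated log weight(s).
    """
    m = np.atleast_2d(np.asarray(m_t, dtype=float))
    lam = np.atleast_2d(np.asarray(lambda_t, dtype=float))
    out = np.asarray(log_weight, dtype=float).copy()
    acc = np.zeros(m.shape[0])
    for j, y in enumerate(y_t):
        y = np.asarray(y, dtype=float)
        n = y.size
        ss = (y**2).sum() - 2.0 * m[:, j] * y.sum() + n * m[:, j] ** 2
        acc += -0.5 * (n * (LOG_2PI + np.log(lam[:, j])) + ss / lam[:, j])
    if np.ndim(log_weight) == 0 and m.shape[0] == 1:
        return float(out + acc[0])
    return out + acc


def dynamic_weight_control(pop: ParticlePopulation, rng) -> ParticlePopulation:
    """Split heavy particles, prune light ones, keep size within bounds.

    A particle with weight above ``theta_high = f_hi * W / N`` (W the total
    weight, N the population size) is split into ``ceil(w / theta_high)``
    equal-weight copies — exact weight conservation.  A particle below
    ``theta_low = f_lo * W / N`` survives with probability ``w / theta_low``
    and takes weight ``theta_low`` — conservation in expectation.  The bounds
    ``[n_min, n_max]`` are enforced by limiting splits and, if pruning is too
    aggressive, by force-keeping the heaviest pruned particles at their
    original weight (again exact conservation).
    """
    lw = pop.log_weights
    shift = float(lw.max())
    w = np.exp(lw - shift)
    N = w.size
    W = w.sum()
    if not np.isfinite(W) or W <= 0:
        raise RuntimeError(
            f"particle population collapsed: size={N}, total weight={W!r}"
        )
    th_hi = pop.theta_high_factor * W / N
    th_lo = pop.theta_low_factor * W / N

    copies = np.maximum(np.ceil(w / th_hi).astype(int), 1)
    budget = pop.n_max - N
    if copies.sum() - N > budget:
        allowed = np.zeros(N, dtype=int)
        for idx in np.argsort(-w):
            take = min(copies[idx] - 1, budget)
            allowed[idx] = take
            budget -= take
            if budget <= 0:
                break
        copies = 1 + allowed
    vals = np.repeat(pop.values, copies, axis=0)
    w2 = np.repeat(w / copies, copies)

    small = w2 < th_lo
    survive = rng.random(w2.size) < np.where(small, w2 / th_lo, 1.0)
    keep = ~small | survive
    w3 = np.where(small & keep, th_lo, w2)
    deficit = min(pop.n_min, w2.size) - int(keep.sum())
    if deficit > 0:
        dropped = np.flatnonzero(~keep)
        top = dropped[np.argsort(-w2[dropped])][:deficit]
        keep[top] = True
        w3[top] = w2[top]
    if not keep.any():
        raise RuntimeError(
            "particle population collapsed to zero particles "
            f"(pre-control size {N}, total weight {W:.3e}, "
            f"thresholds ({th_lo:.3e}, {th_hi:.3e}))"
        )
    with np.errstate(divide="ignore"):
        new_lw = np.log(w3[keep]) + shift
    return replace(pop, values=vals[keep], log_weights=new_lw)


@dataclass
class FilterEstimate:
    """Per-step filtered means and variances with 95% particle bands."""

    groups: tuple
    m_hat: np.ndarray
    m_lo: np.ndarray
    m_hi: np.ndarray
    sigma2_hat: np.ndarray
    sigma2_lo: np.ndarray
    sigma2_hi: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        T = self.m_hat.shape[1]
        for j, g in enumerate(self.groups):
            rows.append(pd.DataFrame({
                "group": g,
                "step": np.arange(1, T + 1),
                "m_hat": self.m_hat[j],
                "m_lo": self.m_lo[j],
                "m_hi": self.m_hi[j],
                "sigma2_hat": self.sigma2_hat[j],
                "sigma2_lo": self.sigma2_lo[j],
                "sigma2_hi": self.sigma2_hi[j],
            }))
        return pd.concat(rows, ignore_index=True)


def run_filter(trials: TrialMatrix, priors: SSMPriors | None = None,
               n_particles: int = 5000, seed: int = 0,
               n_min: int | None = None, n_max: int | None = None,
               fixed_variance: float | None = None) -> FilterEstimate:
    """Run the dynamically weighted particle filter over a cohort.

    ``fixed_variance`` freezes every particle's noise variance at the given
    value (no initial-variance draw, no propagation); useful for validating
    the mean track against the closed-form conjugate posterior.
    """
    if priors is None:
        priors = SSMPriors()
    if trials.T < 2:
        raise ValidationError("need at least two steps")
    if n_particles < 100:
        raise ValidationError("n_particles must be >= 100")
    rng = np.random.default_rng(seed)
    groups = tuple(trials.groups)
    y_groups = trials.group_data()
    G = len(groups)
    T = trials.T
    n_j = np.array([y.shape[1] for y in y_groups])
    sum_y = np.stack([y.sum(axis=1) for y in y_groups])    # (G, T)
    sum_y2 = np.stack([(y**2).sum(axis=1) for y in y_groups])

    n_min = min(1000, n_particles) if n_min is None else n_min
    n_max = 10000 if n_max is None else n_max

    N = n_particles
    lam = np.full((N, G), priors.sigma_0_2 if fixed_variance is None
                  else fixed_variance)
    lw = np.zeros(N)

    m_hat = np.empty((G, T)); m_lo = np.empty((G, T)); m_hi = np.empty((G, T))
    s2_hat = np.empty((G, T)); s2_lo = np.empty((G, T)); s2_hi = np.empty((G, T))
    size_trace = np.empty(T, dtype=int)
    log_evidence = np.empty(T)

    prior_prec = 1.0 / priors.B_mjt**2
    prior_term = priors.A_mjt * prior_prec

    for t in range(T):
        if fixed_variance is None and t > 0:
            lam = propagate_particle(lam, priors, rng)
        # Gibbs draw of m_jt per particle given that particle's variances
        V = 1.0 / (n_j[None, :] / lam + prior_prec)
        M = (sum_y[:, t][None, :] / lam + prior_term) * V
        m = M + np.sqrt(V) * rng.standard_normal(lam.shape)
        if fixed_variance is None and t == 0:
            shape = n_j / 2.0 + priors.A_sj
            rate = 0.5 * (sum_y2[:, 0][None, :] - 2.0 * m * sum_y[:, 0][None, :]
                          + n_j[None, :] * m**2) + priors.B_sj
            lam = rate / rng.standard_gamma(np.broadcast_to(shape, rate.shape))
        # weight update with the step-t response likelihood
        ss = sum_y2[:, t][None, :] - 2.0 * m * sum_y[:, t][None, :] \
            + n_j[None, :] * m**2
        lw = lw - 0.5 * ((n_j[None, :] * (LOG_2PI + np.log(lam)) + ss / lam)
                         .sum(axis=1))
        tot = logsumexp(lw)
        log_evidence[t] = tot - np.log(lw.size)
        lw = lw - tot
        pop = ParticlePopulation(
            values=np.concatenate([lam, m], axis=1), log_weights=lw,
            n_min=n_min, n_max=n_max)
        pop = dynamic_weight_control(pop, rng)
        lam = pop.values[:, :G]
        m_ctrl = pop.values[:, G:]
        lw = pop.log_weights
        size_trace[t] = pop.size

        m_hat[:, t] = m_ctrl.mean(axis=0)
        m_lo[:, t], m_hi[:, t] = np.percentile(m_ctrl, [2.5, 97.5], axis=0)
        s2_hat[:, t] = lam.mean(axis=0)
        s2_lo[:, t], s2_hi[:, t] = np.percentile(lam, [2.5, 97.5], axis=0)

    return FilterEstimate(
        groups=groups, m_hat=m_hat, m_lo=m_lo, m_hi=m_hi,
        sigma2_hat=s2_hat, sigma2_lo=s2_lo, sigma2_hi=s2_hi,
        diagnostics={"population_size": size_trace,
                     "log_evidence_increment": log_evidence},
    )


def smooth_mean_curve(series, window: int):
    """Centered moving average with edge truncation; ``window=1`` is identity."""
    x = np.asarray(series, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValidationError("window must be an odd integer >= 1")
    if window > x.size:
        raise ValidationError("window longer than the series")
    if window == 1:
        return x.copy()
    h = window // 2
    c = np.concatenate([[0.0], np.cumsum(x)])
    out = np.empty_like(x)
    for i in range(x.size):
        lo = max(0, i - h)
        hi = min(x.size, i + h + 1)
        out[i] = (c[hi] - c[lo]) / (hi - lo)
    return out
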
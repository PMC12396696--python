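"""Constant retention factor / learning rate estimation with equality tests.

The state model treats the next angle as a blend of the current angle
(retention, A) and a shared group-level driver (learning, B):

    response_{t+1} = A_j * response_t + B_j * driver_jt + error,

with no intercept, Gaussian errors and a separate residual variance per
group.  The driver can be the particle-filter means, the observed sample
means, or a known series (e.g. a generator's ground-truth driver).  Fits are
exact Gaussian maximum likelihood: closed-form GLS for the coefficients
given the group variances, iterated with ML variance updates to convergence.
Group-equality hypotheses (A shared, B shared) are tested by chi-squared
differences of the -2 log-likelihoods of nested fits — the SEM analogue of a
one-way ANOVA across feedback groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import TrialMatrix, ValidationError

CONSTRAINTS = ("none", "A", "B", "both")


class CollinearityError(ValidationError):
    """Lagged response and driver are linearly dependent for some group."""


@dataclass
class DriverSeries:
    """Per-group driver used in the B term, plus the observed means."""

    groups: tuple
    driver: np.ndarray  # (G, T)
    ybar: np.ndarray    # (G, T)
    name: str = "driver"

    def __post_init__(self) -> None:
        self.driver = np.atleast_2d(np.asarray(self.driver, dtype=float))
        self.ybar = np.atleast_2d(np.asarray(self.ybar, dtype=float))
        if self.driver.shape != self.ybar.shape:
            raise ValidationError("driver and ybar must share shape (G, T)")
        if not np.all(np.isfinite(self.driver)) or not np.all(np.isfinite(self.ybar)):
            raise ValidationError("driver series contain missing values")

    @classmethod
    def from_sample_means(cls, trials: TrialMatrix) -> "DriverSeries":
        ybar = trials.group_means()
        return cls(groups=tuple(trials.groups), driver=ybar.copy(), ybar=ybar,
                   name="sample_mean")

    @classmethod
    def from_filter(cls, trials: TrialMatrix, estimate) -> "DriverSeries":
        if tuple(estimate.groups) != tuple(trials.groups):
            raise ValidationError("filter estimate groups do not match trials")
        return cls(groups=tuple(trials.groups), driver=estimate.m_hat,
                   ybar=trials.group_means(), name="pf_mean")

    @classmethod
    def from_series(cls, trials: TrialMatrix, driver: np.ndarray,
                    name: str = "known") -> "DriverSeries":
        return cls(groups=tuple(trials.groups), driver=driver,
                   ybar=trials.group_means(), name=name)


@dataclass
class RateEstimate:
    """Fitted per-group retention factors and learning rates."""

    groups: tuple
    A_hat: np.ndarray
    B_hat: np.ndarray
    se_A: np.ndarray
    se_B: np.ndarray
    loglik: float
    n_obs: int
    level: str
    constrain_equal: str
    driver_name: str
    chi2_diff: float | None = None
    df: int | None = None
    p_value: float | None = None

    @property
    def minus2_loglik(self) -> float:
        return -2.0 * self.loglik

    @property
    def n_free_coef(self) -> int:
        G = len(self.groups)
        return {"none": 2 * G, "A": G + 1, "B": G + 1, "both": 2}[
            self.constrain_equal]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": list(self.groups) * 2,
            "parameter": ["A"] * len(self.groups) + ["B"] * len(self.groups),
            "estimate": np.concatenate([self.A_hat, self.B_hat]),
            "std_error": np.concatenate([self.se_A, self.se_B]),
        })


def _group_blocks(trials_or_means, driver: DriverSeries, level: str):
    """Per-group (response, 2-column design) pairs at the requested level."""
    if level not in ("individual", "group-mean"):
        raise ValidationError(f"unknown level {level!r}")
    blocks = []
    if level == "group-mean":
        for j, g in enumerate(driver.groups):
            r = driver.ybar[j, 1:]
            Z = np.column_stack([driver.ybar[j, :-1], driver.driver[j, :-1]])
            blocks.append((g, r, Z))
    else:
        if not isinstance(trials_or_means, TrialMatrix):
            raise ValidationError("individual-level fit needs a TrialMatrix")
        trials = trials_or_means
        if tuple(trials.groups) != tuple(driver.groups):
            raise ValidationError("driver groups do not match trials")
        for j, (g, Y) in enumerate(zip(trials.groups, trials.group_data())):
            Tn = Y.shape[0]
            r = Y[1:, :].T.ravel()
            lag = Y[:-1, :].T.ravel()
            drv = np.tile(driver.driver[j, :Tn - 1], Y.shape[1])
            blocks.append((g, r, np.column_stack([lag, drv])))
    return blocks


def _check_rank(blocks) -> None:
    for g, _, Z in blocks:
        s = np.linalg.svd(Z, compute_uv=False)
        if s[-1] <= 1e-10 * s[0]:
            raise CollinearityError(
                f"driver and lagged response are collinear in group {g!r}; "
                "the two coefficients are not separately identifiable"
            )


def fit_state_model(trials_or_means, driver: DriverSeries,
                    level: str = "individual",
                    constrain_equal: str = "none",
                    tol: float = 1e-10, max_iter: int = 500) -> RateEstimate:
    """Gaussian ML fit of the two-coefficient state model.

    ``constrain_equal`` forces the named coefficient(s) to be shared across
    groups (the nested "null" models of the equality tests).  Residual
    variances are always group-specific.
    """
    if constrain_equal not in CONSTRAINTS:
        raise ValidationError(f"constrain_equal must be one of {CONSTRAINTS}")
    blocks = _group_blocks(trials_or_means, driver, level)
    if any(r.size < 2 for _, r, _ in blocks):
        raise ValidationError("need at least T >= 3 steps per group")
    _check_rank(blocks)
    G = len(blocks)
    grams = [Z.T @ Z for _, _, Z in blocks]
    cross = [Z.T @ r for _, r, Z in blocks]
    rss0 = [float(r @ r) for _, r, _ in blocks]
    n_obs = np.array([r.size for _, r, _ in blocks])

    # map free parameters theta -> per-group (A_j, B_j)
    if constrain_equal == "none":
        idx = [(2 * j, 2 * j + 1) for j in range(G)]
        p = 2 * G
    elif constrain_equal == "A":
        idx = [(0, 1 + j) for j in range(G)]
        p = 1 + G
    elif constrain_equal == "B":
        idx = [(j, G) for j in range(G)]
        p = 1 + G
    else:
        idx = [(0, 1) for _ in range(G)]
        p = 2

    psi = np.ones(G)
    theta = np.zeros(p)
    for _ in range(max_iter):
        M = np.zeros((p, p))
        h = np.zeros(p)
        for j in range(G):
            ia, ib = idx[j]
            sel = np.array([ia, ib])
            M[np.ix_(sel, sel)] += grams[j] / psi[j]
            h[sel] += cross[j] / psi[j]
        theta = np.linalg.solve(M, h)
        psi_new = np.empty(G)
        for j in range(G):
            gam = theta[list(idx[j])]
            rss = rss0[j] - 2.0 * gam @ cross[j] + gam @ grams[j] @ gam
            psi_new[j] = max(rss / n_obs[j], 1e-300)
        if np.max(np.abs(np.log(psi_new) - np.log(psi))) < tol:
            psi = psi_new
            break
        psi = psi_new

    # final information and log-likelihood at the ML solution
    M = np.zeros((p, p))
    for j in range(G):
        sel = np.array(idx[j])
        M[np.ix_(sel, sel)] += grams[j] / psi[j]
    cov = np.linalg.inv(M)
    loglik = float(-0.5 * np.sum(n_obs * (np.log(2.0 * np.pi * psi) + 1.0)))

    A_hat = np.array([theta[ia] for ia, _ in idx])
    B_hat = np.array([theta[ib] for _, ib in idx])
    se = np.sqrt(np.diag(cov))
    se_A = np.array([se[ia] for ia, _ in idx])
    se_B = np.array([se[ib] for _, ib in idx])
    return RateEstimate(
        groups=tuple(g for g, _, _ in blocks), A_hat=A_hat, B_hat=B_hat,
        se_A=se_A, se_B=se_B, loglik=loglik, n_obs=int(n_obs.sum()),
        level=level, constrain_equal=constrain_equal, driver_name=driver.name,
    )


def lr_difference_test(fit_full: RateEstimate, fit_null: RateEstimate):
    """Chi-squared difference between nested fits: ``(chi2, df, p)``."""
    if fit_full.n_obs != fit_null.n_obs or fit_full.level != fit_null.level \
            or fit_full.driver_name != fit_null.driver_name:
        raise ValidationError("fits must use the same data, level and driver")
    order = {"none": 0, "A": 1, "B": 1, "both": 2}
    cf, cn = fit_full.constrain_equal, fit_null.constrain_equal
    nested = (cf == cn) or (order[cn] > order[cf] and
                            (cf == "none" or cn == "both"))
    if not nested:
        raise ValidationError(
            f"null constraints {cn!r} are not a superset of full {cf!r}")
    df = fit_full.n_free_coef - fit_null.n_free_coef
    chi2 = fit_null.minus2_loglik - fit_full.minus2_loglik
    if chi2 < -1e-6 * max(1.0, abs(fit_full.minus2_loglik)):
        raise ValidationError(
            f"null fit beats full fit (diff {chi2:.3g}); check convergence")
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, p


def fit_with_equality_tests(trials_or_means, driver: DriverSeries,
                            level: str = "individual") -> dict:
    """Full fit plus separate A- and B-equality tests (Table-style output).

    Returns a dict with the three :class:`RateEstimate` objects and a tidy
    summary frame (group, parameter, estimate, std_error, chi2_diff, df, p).
    """
    full = fit_state_model(trials_or_means, driver, level, "none")
    null_A = fit_state_model(trials_or_means, driver, level, "A")
    null_B = fit_state_model(trials_or_means, driver, level, "B")
    chi2_A, df_A, p_A = lr_difference_test(full, null_A)
    chi2_B, df_B, p_B = lr_difference_test(full, null_B)
    tab = full.to_frame()
    tab["chi2_diff"] = np.where(tab["parameter"] == "A", chi2_A, chi2_B)
    tab["df"] = np.where(tab["parameter"] == "A", df_A, df_B)
    tab["p_value"] = np.where(tab["parameter"] == "A", p_A, p_B)
    return {"full": full, "null_A": null_A, "null_B": null_B,
            "chi2_A": chi2_A, "chi2_B": chi2_B, "p_A": p_A, "p_B": p_B,
            "df_A": df_A, "df_B": df_B, "table": tab}


def fit_individual_rates(trials: TrialMatrix,
                         driver: DriverSeries) -> pd.DataFrame:
    """Per-participant OLS of the state model (for box-plot summaries).

    Participants whose design is rank-deficient (e.g. a constant series
    collinear with the driver) are flagged with ``rank_ok = False`` and NaN
    estimates; the rest are still returned.
    """
    if tuple(trials.groups) != tuple(driver.groups):
        raise ValidationError("driver groups do not match trials")
    rows = []
    for j, g in enumerate(trials.groups):
        cols = trials.group_columns(g)
        d = driver.driver[j, :-1]
        for c in cols:
            y = trials.angles[:, c]
            Z = np.column_stack([y[:-1], d])
            r = y[1:]
            s = np.linalg.svd(Z, compute_uv=False)
            if s[-1] <= 1e-10 * s[0]:
                rows.append((trials.participant_ids[c], g, np.nan, np.nan, False))
                continue
            coef, *_ = np.linalg.lstsq(Z, r, rcond=None)
            rows.append((trials.participant_ids[c], g, coef[0], coef[1], True))
    return pd.DataFrame(rows, columns=["participant", "group", "A", "B",
                                       "rank_ok"])


def fit_smoothed_group_rates(trials: TrialMatrix, driver: DriverSeries,
                             window: int = 9) -> RateEstimate:
    """Group-level fit on smoothed mean series (recovery-oriented estimator).

    Observation noise on the lagged regressor attenuates the retention
    factor (errors in variables).  The state recursion is preserved exactly
    under any shared linear smoothing of response, lag and driver, while the
    noise variance drops by roughly the window length, so fitting the
    smoothed group means against the smoothed driver removes essentially all
    of the attenuation.  Used for ground-truth recovery studies; the
    table-style fits keep the raw series.
    """
    from .dwpf import smooth_mean_curve

    ys = np.stack([smooth_mean_curve(y, window) for y in driver.ybar])
    ds = np.stack([smooth_mean_curve(d, window) for d in driver.driver])
    sm = DriverSeries(groups=driver.groups, driver=ds, ybar=ys,
                      name=f"{driver.name}_smoothed{window}")
    return fit_state_model(trials, sm, level="group-mean")
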
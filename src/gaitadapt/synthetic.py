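"""Synthetic locomotor-adaptation cohorts with known ground truth.

Emulates the study design the estimators assume: G groups of participants
walking a baseline phase (steps 1..jump_step-1) followed by a +30 degree
knee-flexion target jump, with the latent group mean driven by a linear
state recursion

    m_{j,t+1} = A_j * m_jt + B_j * d_jt,

where the driver ``d_jt`` is the phase target rescaled by ``(1 - A_j)/B_j``
so the recursion's fixed point equals the target, and observations

    y_ijt = m_jt + offset_i + eps_ijt,     eps_ijt ~ N(0, sigma2_jt),

with the noise variance following a log-AR(1) transition
``log sigma2_jt = a_j log sigma2_{j,t-1} + u_jt``, ``u_jt ~ N(0, sigma_u2)``.

The default retention factors and learning rates are study-like values for
Control / Punishment / Reward feedback groups, so the default cohort mirrors
the design (3 x 11 participants x 500 steps) the estimators target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import TrialMatrix, ValidationError

#: group names used when three groups are generated
STUDY_GROUPS = ("Control", "Punishment", "Reward")

#: study-like per-group retention factors and learning rates
DEFAULT_TRUE_A = (0.9404, 0.9394, 0.8889)
DEFAULT_TRUE_B = (0.0477, 0.0567, 0.1231)


@dataclass
class SynthConfig:
    """Generative settings for one synthetic cohort."""

    n_groups: int = 3
    n_per_group: int = 11
    T: int = 500
    baseline_mean: float = 60.0
    adaptation_increment: float = 30.0
    jump_step: int = 251
    true_A: tuple = DEFAULT_TRUE_A
    true_B: tuple = DEFAULT_TRUE_B
    a_j: float = 1.0
    sigma_u2: float = 0.01
    sigma_0_2: float = 1.0
    participant_offset_sd: float = 3.0
    baseline_adjusted: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_A = tuple(np.atleast_1d(self.true_A).astype(float))
        self.true_B = tuple(np.atleast_1d(self.true_B).astype(float))
        if len(self.true_A) == 1:
            self.true_A = self.true_A * self.n_groups
        if len(self.true_B) == 1:
            self.true_B = self.true_B * self.n_groups
        self.validate()

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        if self.T < 3:
            raise ValidationError("T must be >= 3")
        if not (1 < self.jump_step < self.T):
            raise ValidationError("jump_step must lie strictly inside (1, T)")
        if self.sigma_u2 < 0:
            raise ValidationError("sigma_u2 must be >= 0")
        if self.sigma_0_2 <= 0:
            raise ValidationError("sigma_0_2 must be > 0")
        if len(self.true_A) != self.n_groups or len(self.true_B) != self.n_groups:
            raise ValidationError("true_A / true_B must have one entry per group")
        for A in self.true_A:
            if not (0.0 < A < 1.5):
                raise ValidationError("retention factors must lie in (0, 1.5)")
        for B in self.true_B:
            if B < 0:
                raise ValidationError("learning rates must be >= 0")

    @property
    def group_names(self) -> tuple:
        if self.n_groups == 3:
            return STUDY_GROUPS
        return tuple(f"G{j + 1}" for j in range(self.n_groups))


@dataclass
class CohortTruth:
    """Ground-truth quantities returned alongside a generated cohort."""

    groups: tuple
    m: np.ndarray            # (G, T) latent model group means
    m_realized: np.ndarray   # (G, T) model mean + realized average offset
    sigma2: np.ndarray       # (G, T) noise variances at steps 1..T
    driver: np.ndarray       # (G, T) rescaled target series d_jt
    true_A: np.ndarray       # (G,)
    true_B: np.ndarray       # (G,)
    offsets: np.ndarray      # (G, n_per_group) constant participant offsets


def generate_variance_path(a_j: float, sigma_u2: float, sigma_0_2: float,
                           T: int, rng) -> np.ndarray:
    """Simulate the log-AR(1) noise-variance series, length ``T + 1``.

    Entry 0 is the initial variance ``sigma2_{j,0}``; entries ``1..T`` follow
    ``log sigma2_t = a_j log sigma2_{t-1} + u_t`` with ``u_t ~ N(0, sigma_u2)``.
    """
    if sigma_0_2 <= 0:
        raise ValidationError("initial variance must be > 0")
    if sigma_u2 < 0:
        raise ValidationError("sigma_u2 must be >= 0")
    rng = np.random.default_rng(rng)
    log_s2 = np.empty(T + 1)
    log_s2[0] = np.log(sigma_0_2)
    u = rng.normal(0.0, np.sqrt(sigma_u2), size=T) if sigma_u2 > 0 else np.zeros(T)
    for t in range(1, T + 1):
        log_s2[t] = a_j * log_s2[t - 1] + u[t - 1]
    return np.exp(log_s2)


def latent_mean_path(config: SynthConfig, group: int) -> tuple:
    """Deterministic latent mean trajectory and its driver for one group.

    Returns ``(m, d)`` with ``m`` of length T (steps 1..T) and ``d`` the
    driver series such that ``m[t+1] = A m[t] + B d[t]``.  The driver is the
    phase target scaled by ``(1 - A)/B``; with ``B = 0`` (or ``A = 1``) it
    degenerates to zero and the recursion is pure retention.
    """
    A = config.true_A[group]
    B = config.true_B[group]
    # target of the step being produced: the jump appears at jump_step
    target = np.full(config.T + 1, config.baseline_mean)
    target[config.jump_step - 1:] += config.adaptation_increment
    scale = (1.0 - A) / B if B > 0 else 0.0
    d = scale * target[1:]  # d[t-1] drives the transition t -> t+1
    m = np.empty(config.T)
    m[0] = config.baseline_mean
    for t in range(config.T - 1):
        m[t + 1] = A * m[t] + B * d[t]
    return m, d


def generate_cohort(config: SynthConfig,
                    sigma2_override: np.ndarray | None = None) -> tuple:
    """Generate one cohort; returns ``(TrialMatrix, CohortTruth)``.

    ``sigma2_override`` replaces the simulated noise-variance paths with a
    fixed ``(G, T)`` (or broadcastable) array, e.g. to impose a variance jump
    at the phase change.
    """
    rng = np.random.default_rng(config.seed)
    G, n, T = config.n_groups, config.n_per_group, config.T
    names = config.group_names

    m = np.empty((G, T))
    driver = np.empty((G, T))
    sigma2 = np.empty((G, T))
    for j in range(G):
        m[j], driver[j] = latent_mean_path(config, j)
        path = generate_variance_path(config.a_j, config.sigma_u2,
                                      config.sigma_0_2, T, rng)
        sigma2[j] = path[1:]
    if sigma2_override is not None:
        sigma2 = np.broadcast_to(np.asarray(sigma2_override, float), (G, T)).copy()
        if np.any(sigma2 <= 0):
            raise ValidationError("overridden variances must be > 0")

    offsets = (rng.normal(0.0, config.participant_offset_sd, size=(G, n))
               if config.participant_offset_sd > 0 else np.zeros((G, n)))

    angles = np.empty((T, G * n))
    labels = np.empty(G * n, dtype=object)
    pids = np.empty(G * n, dtype=object)
    for j in range(G):
        eps = rng.normal(0.0, 1.0, size=(T, n)) * np.sqrt(sigma2[j])[:, None]
        block = m[j][:, None] + offsets[j][None, :] + eps
        sl = slice(j * n, (j + 1) * n)
        angles[:, sl] = block
        labels[sl] = names[j]
        pids[sl] = [f"{names[j]}_{i + 1:02d}" for i in range(n)]

    trials = TrialMatrix(angles=angles, group_labels=labels,
                         participant_ids=pids)
    truth = CohortTruth(
        groups=names,
        m=m,
        m_realized=m + offsets.mean(axis=1)[:, None],
        sigma2=sigma2,
        driver=driver,
        true_A=np.asarray(config.true_A),
        true_B=np.asarray(config.true_B),
        offsets=offsets,
    )
    if config.baseline_adjusted:
        from .io import baseline_adjust as _baseline_adjust

        window = (1, config.jump_step - 1)
        trials = _baseline_adjust(trials, baseline_steps=window)
        base = m[:, : config.jump_step - 1].mean(axis=1)[:, None]
        truth = replace(truth, m=m - base,
                        m_realized=truth.m_realized - truth.m_realized[
                            :, : config.jump_step - 1].mean(axis=1)[:, None])
    return trials, truth


def simulate_state_model_cohort(true_A, true_B, driver, n_per_group: int,
                                T: int, noise_sd: float = 1.0,
                                y0: float = 60.0, seed: int = 0,
                                group_names=None) -> tuple:
    """Simulate directly from the individual-level state regression.

    Each participant's series follows ``y_{t+1} = A_j y_t + B_j d_jt + e``
    with iid Normal errors, i.e. exactly the model the constant-rate fits
    assume.  This is the calibration oracle for the chi-squared difference
    tests: under it the fitted model is true, so likelihood-ratio statistics
    follow their nominal null distribution (unlike cohorts from
    :func:`generate_cohort`, where observation noise on the lagged angle
    makes the regression an approximation).

    Returns ``(TrialMatrix, driver_array)`` with driver of shape ``(G, T)``.
    """
    rng = np.random.default_rng(seed)
    true_A = np.atleast_1d(np.asarray(true_A, dtype=float))
    true_B = np.atleast_1d(np.asarray(true_B, dtype=float))
    G = true_A.size
    d = np.broadcast_to(np.asarray(driver, dtype=float), (G, T)).copy()
    if group_names is None:
        group_names = STUDY_GROUPS if G == 3 else tuple(
            f"G{j + 1}" for j in range(G))
    angles = np.empty((T, G * n_per_group))
    labels = np.empty(G * n_per_group, dtype=object)
    pids = np.empty(G * n_per_group, dtype=object)
    for j in range(G):
        y = np.empty((T, n_per_group))
        y[0] = y0 + noise_sd * rng.standard_normal(n_per_group)
        e = noise_sd * rng.standard_normal((T - 1, n_per_group))
        for t in range(T - 1):
            y[t + 1] = true_A[j] * y[t] + true_B[j] * d[j, t] + e[t]
        sl = slice(j * n_per_group, (j + 1) * n_per_group)
        angles[:, sl] = y
        labels[sl] = group_names[j]
        pids[sl] = [f"{group_names[j]}_{i + 1:02d}" for i in range(n_per_group)]
    return TrialMatrix(angles=angles, group_labels=labels,
                       participant_ids=pids), d
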
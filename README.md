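# gaitadapt

Estimation of locomotor-adaptation dynamics — how fast people learn a new
walking pattern and how strongly they retain it — from stride-by-stride knee
flexion angles, under three feedback conditions (Control, Reward,
Punishment).

Two complementary tracks are implemented over the same state space model.
For participant *i* in group *j* at stride step *t*:

```
response model:  y_ijt   = m_jt + eps_ijt,          eps_ijt ~ N(0, sigma2_jt)
state model:     y_ij,t+1 = A_j(tau_t) y_ijt + B_j(tau_t) m_jt
```

with a log-AR(1) transition for the noise variance,
`log sigma2_jt = a_j log sigma2_j,t-1 + u_jt`, `u_jt ~ N(0, sigma_u2)`.
`A` is the **retention factor** (carry-over of the current movement) and `B`
the **learning rate** (pull toward the shared group signal).

1. **Sequential track** (`gaitadapt.dwpf`, `gaitadapt.sem`): a dynamically
   weighted particle filter — Gibbs draws of the group means from their
   Normal full conditionals inside a particle population over the variance
   states, with split/prune weight control — estimates `m_jt` and
   `sigma2_jt` per step.  Constant per-group `A_j`, `B_j` are then fitted by
   exact Gaussian maximum likelihood of the state regression (driver =
   particle-filter means or sample means), and group equality is tested by
   chi-squared differences of nested fits (the SEM analogue of one-way
   ANOVA).
2. **Functional track** (`gaitadapt.fda`): Bayesian cubic P-splines
   (truncated-power basis, 19 knots, diagonal penalty that leaves the global
   cubic unpenalized) fitted by a five-block Gibbs sampler give smooth group
   mean curves `f_j`; per-draw first differences yield time-varying
   `A_j(tau_t) = f_j'(tau_t)` and
   `B_j(tau_t) = (ybar_j,t+1 - f_j'(tau_t)) / f_j(tau_t)` with pointwise 95%
   credible bands, so group differences can be read off band overlap.

A synthetic cohort generator (`gaitadapt.synthetic`) reproduces the study
design — 3 groups x 11 participants x 500 steps, 250-step baseline, +30
degree target jump — with known ground truth, so every stage is testable
without the original recordings.

## Worked example

```
python analysis/01_simulate_cohort.py
python analysis/02_filter_state_space.py
python analysis/03_sem_rates.py
```

prints (abridged):

```
Control: filtered mean 62.3 -> 92.1 deg; variance 12.01 -> 11.52
...
--- driver = pf means ---
     group parameter  estimate  std_error  chi2_diff  df  p_value
   Control         A    0.9785     0.0031   519.4418   2   0.0000
   Control         B    0.0224     0.0031   517.3164   2   0.0000
...
```

The filtered means track the 60 -> 90 degree adaptation; the constant-rate
table shows retention near 1 with a small learning rate for the Control
group and a much larger one for Reward, and the chi-squared differences
reject equality of the groups.  `analysis/04_fda_psplines.py` adds the
functional picture — `A(tau)` near zero (degrees/step) with a peak at the
phase jump, and learning-rate bands that separate mostly after the jump —
and `analysis/05_compare_tracks.py` writes the full side-by-side comparison
to `results/compare/`.

The same operations are available as a CLI:

```
gait-adapt simulate --seed 1 --out angles.csv
gait-adapt filter   --input angles.csv --particles 5000 --seed 2 --out est.csv
gait-adapt sem      --input angles.csv --driver pf --out rates.csv
gait-adapt fda      --input angles.csv --samples 1000 --burnin 1000 --seed 4 --out rates_fda.csv
gait-adapt compare  --out results/compare --seed 1
```

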
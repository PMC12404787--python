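# fovadapt

Analysis pipeline for **whole-body visuomotor adaptation in fish driving a
fish-operated vehicle (FOV)**. A goldfish steering a wheeled platform from a
start point to a target (2.5 m away) by swimming is a motor-control task:
the fish's heading commands the vehicle's motion direction, and a fixed
rotation (e.g. +45° to the right) inserted into that mapping perturbs the
task the way rotated visual feedback perturbs human reaching. The package is
for behavioural and computational researchers who need the full chain from
raw vehicle trajectories to population-level statements about learning,
aftereffects, and savings — plus a simulator that generates every input the
chain consumes, with ground truth, so the whole pipeline is testable without
animal data.

## What it computes

**Trial metrics** (`fovadapt.metrics`). Per trial: success (final point in
the target disc), signed angular error (the angle from the start→target to
the start→end direction, clockwise-positive, so an unadapted fish under a
+45° rotation shows +45°), and path length. Failed trials get an adjusted
distance `d = len + EAL` with `EAL = eff × ET`, where `ET` is the
end-to-target distance and `eff = Σlen/ΣSE` the session's efficiency.
Sessions are summarised by success counts and medians; a baseline criterion
(3 consecutive sessions with median success ≥ 4, |median error| < 15°,
median distance < 4.5 m) decides advancement.

**Learning curves** (`fovadapt.curves`, `fovadapt.inference`). Performance
per stage follows an exponential relaxation

```
μ̂(ses) = A_μ·exp(−ses/τ_μ) + μ_∞        σ̂(ses) = A_σ·exp(−ses/τ_μ) + σ_∞
```

with measure-specific likelihoods — Poisson for success counts, Student-t
(shared ν) for angular error, Gamma(mode = μ̂, sd = σ̂) for distance — in a
hierarchical Bayesian model across fish (fish-level curves under
population-level priors centered empirically on the data). Derived
parameters: initial value `A_μ+μ_∞`, asymptotic performance `μ_∞`, initial
learning rate `−A_μ/τ_μ`. Posterior draws come from independently seeded
ensemble MCMC chains with convergence diagnostics (split-R̂, ESS).

**Posterior comparisons** (`fovadapt.posterior`). 94% highest-density
intervals, stage contrasts as difference posteriors with ROPE overlap
(regions of practical equivalence: ±1 success/session, ±5°, ±2 m), and the
across-fish regression of savings-stage on rotation-stage learning rates.

**Synthetic cohorts** (`fovadapt.simulate`). Two tiers: direct draws from
the likelihood families with known population curves (for calibration and
parameter recovery), and a trajectory-level agent whose heading bias adapts
exponentially across sessions under the rotational perturbation (for
end-to-end pipeline tests). Both are exactly reproducible from a seed.

## Worked example

Simulate a small cohort (rotation → washout → re-rotation), compute
metrics, fit the angular-error model for both perturbation stages, and
compare them:

```
fovadapt simulate --config config.yaml --seed 7 --out sim/
fovadapt metrics sim/samples.csv --out metrics/
fovadapt fit metrics/trial_metrics.csv --measure angular --stage rotation \
    --seed 5 --chains 2 --tune 4000 --draws 2000 --out fit_rot/
fovadapt fit metrics/trial_metrics.csv --measure angular --stage savings \
    --seed 5 --chains 2 --tune 4000 --draws 2000 --out fit_sav/
fovadapt compare fit_rot/fit.nc fit_sav/fit.nc --out cmp/
```

with `config.yaml`:

```yaml
n_fish: 4
stages:
  - {stage: rotation, n_sessions: 12, rotation_deg: 45.0}
  - {stage: washout, n_sessions: 6, rotation_deg: 0.0}
  - {stage: savings, n_sessions: 12, rotation_deg: 45.0}
heading_kappa: 25.0
initial_aim_bias_deg: 0.0
```

`fovadapt report fit_rot/` prints the rotation-stage summary:

```
# angular_student_t / stage rotation
  draws=4144 rhat_max=1.0072 ess_min=3292 flags=none
  initial_value: median 44.9 (94% HDI 40.8 to 48.9)
  asymptotic_performance: median -0.0961 (94% HDI -2.52 to 1.99)
  initial_learning_rate: median -11.2 (94% HDI -13.5 to -9.13)
```

— the cohort starts at the full +45° error imposed by the rotation, adapts
at ≈ −11°/session initially (the simulator's time constant is 4 sessions:
−45/4 = −11.25), and converges to ≈ 0°. The compare step prints:

```
          measure              parameter  stage_a stage_b  median_diff    hdi_low  hdi_high  rope_overlap
angular_student_t          initial_value rotation savings    -9.912017 -15.372184 -5.043024      0.035473
angular_student_t asymptotic_performance rotation savings     0.124640  -2.921013  2.800801      0.995174
angular_student_t  initial_learning_rate rotation savings     2.447360  -0.482282  5.224622      0.958253
```

Read: on re-exposure the cohort *starts* ≈ 10° better than in the first
rotation (the difference HDI sits outside the ±5° ROPE, overlap 0.035 —
residual adaptation survived the short washout), reaches a practically
equivalent asymptote (overlap 0.995), and its initial learning rate is
≈ 2.4°/session *less steep* (overlap 0.958, practically equivalent):
better initial performance leaves less to learn — improved initial value
without faster relearning. Here that pattern follows from the simulator's
bias carry-over; on real data the same report answers whether the animals
show it.

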
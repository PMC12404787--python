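# Methods

## The behavioural task and its measures

A fish steers a wheeled vehicle (an FOV — fish-operated vehicle) from a
fixed start point to a target 2.5 m away by swimming: the fish's heading in
its onboard tank commands the vehicle's motion direction. Inserting a fixed
rotation (e.g. +45°, rightward) between heading and motion creates a
visuomotor perturbation; the stages *baseline → rotation → washout →
savings → final* (with 15 perturbed and 10 unperturbed sessions after a
baseline of up to 25) probe adaptation, aftereffects, and savings. A session
is one experimental day of six trials; a trial ends on reaching the target,
leaving the arena, or after 3 minutes.

Three measures summarise a trial or session:

* **success/session** — count of trials (0–6) whose final point lies in the
  target area. A recorded outcome flag takes precedence; geometrically the
  target is a closed disc of radius 0.25 m (the physical board is not
  dimensioned, so the radius is configurable).
* **angular error** — the signed angle from the start→target direction to
  the start→end direction, computed with a full-quadrant arctangent of the
  two vectors rather than a frame-bound `arctan(Δy/Δx)`, which is
  quadrant-ambiguous. Positive is clockwise (the direction of a rightward
  perturbation), so an unadapted animal under +45° shows +45° error. Range
  (−180°, 180°]; zero-displacement trials have undefined error and are
  excluded from medians but count as failures.
* **adjusted distance** — the polyline path length `len`; failed trials add
  an estimated additional length `EAL = eff × ET`, where `ET` is the
  end-to-target distance and `eff = Σlen / ΣSE` is the session's efficiency
  (`SE` = start-to-end displacement). A session whose trials all have zero
  displacement has undefined efficiency; this raises by default, with an
  explicit opt-in fallback of `eff = 1`.

Medians over even numbers of trials use the mean of the two middle values.
Baseline advancement requires a window of three consecutive sessions whose
median success count is ≥ 4, whose pooled trial angular errors have
|median| < 15°, and whose pooled adjusted distances have median < 4.5 m,
closing by session 25. The returned index is the last session of the first
qualifying window.

Trajectory cleaning: frames with no detection are dropped, refilled by
linear interpolation at their original timestamps when the surrounding gap
is shorter than 1 s (configurable), then smoothed with a 3-sample moving
median (nearest-edge padding). The exact smoothing used upstream of the
deposited data is not specified; these defaults are deliberately mild and
exactly invertible on gap-free straight segments.

## The learning-curve model

Median performance within a stage relaxes exponentially in the session
index `ses` (0 at the stage's first session, each stage fitted separately):

    μ̂(ses) = A_μ · exp(−ses/τ_μ) + μ_∞
    σ̂(ses) = A_σ · exp(−ses/τ_μ) + σ_∞

The dispersion curve shares the mean curve's time constant (an option
decouples it). Three derived scalars characterise learning: the initial
value `A_μ + μ_∞`, the asymptotic performance `μ_∞`, and the initial
learning rate `−A_μ/τ_μ` (the curve's slope at session 0), so improvement
is a positive rate for success and a negative rate for angular error and
distance.

Measure-specific likelihoods, fitted at the granularity of individual
observations:

* success counts: Poisson with rate μ̂ (one count per session). The Poisson
  support is unbounded although a session cannot exceed 6 successes; a
  Binomial(6, μ̂/6) alternative exists behind a flag, off by default.
* angular error: Student-t with location μ̂, scale σ̂, and degrees of
  freedom ν shared across all fish of a measure. "σ̂" is the scale
  parameter, not the standard deviation √(ν/(ν−2))·scale.
* adjusted distance: Gamma parameterised by mode μ̂ and standard deviation
  σ̂, converted in closed form to shape/rate via
  `rate = (mode + √(mode² + 4·sd²)) / (2·sd²)`, `shape = 1 + mode·rate`
  (shape > 1 guaranteed, so the mode is interior).

## Hierarchy, priors, and sampling

Each fish has its own (A_μ, τ_μ, μ_∞), drawn from population-level
distributions; A_σ, σ_∞ and ν are shared within a fit. The sampler works on
an unconstrained scale: τ is always log-transformed, the asymptote is
log-transformed for the count and distance measures (whose mean curve must
stay positive) and raw for the angular measure, and the amplitude is
raw-scale (Normal hierarchy) for *every* measure — its sign is identified
by the data, since fixing it from a noisy point estimate mis-specifies a
non-negligible fraction of fits when the curve flattens early. Positivity
of the mean curve itself is enforced through the likelihood: any parameter
point with μ̂ ≤ 0 at an observed session has −∞ density. Population priors
are Normal on the working scale (lognormal on the natural scale for
log-transformed parameters, which respects positivity the way a Gamma
prior would); ν has the traditional Exponential prior (mean 30).

Prior centers follow an empirical-Bayes recipe computed from coarse
summaries: the asymptote center is the median of the last third of
sessions, the amplitude center the first-third median minus that — scaled
up by the exponential's own decay factor at the middle of the first
window, since that median reflects the curve a couple of sessions in and
would otherwise systematically understate the session-0 deficit — the time
constant center one third of the stage length, dispersion centers from
robust spreads of the first/last thirds. Widths are broad multiples of the
data's robust spread (e.g. 1.0–1.5 on the log scale, ≥ 2 spreads on raw
scales) so the priors fix the scale of the problem without informing the
conclusions. With fewer than three sessions the fixed defaults are used and
a warning emitted.

Three parameterizations are implemented. The default, *marginal*,
integrates the population means out analytically — the fish parameters'
joint prior given the population sds is multivariate normal with covariance
`s²I + w²11ᵀ`, evaluated via Sherman–Morrison — and recovers population-mean
draws afterwards from their exact normal conditional given each retained
draw (a Rao-Blackwellised recovery). *Centered* and *non-centered* forms
are available. The marginal form removes the global ridge coupling the
population means to every fish's parameters, which is the direction an
ensemble sampler traverses most slowly; with it the default budget reaches
split-R̂ ≤ 1.01 on population-level quantities, which the non-centered form
did not at any practical budget.

Sampling uses affine-invariant ensembles (emcee) with a 90/10 mixture of
differential-evolution and DE-snooker moves and a generous ensemble of
4×dimension walkers — ensemble richness buys more mixing here than chain
length. A "chain" is an independently initialised and seeded ensemble
(default 4 chains × 1000 retained draws each after 1000 tuning steps,
thinned ×2), so split-R̂ compares genuinely independent runs. Initial
points are moderately overdispersed around the prior centers. There are no
divergences in this sampler; the acceptance gates are split-R̂ ≤ 1.01 on
population-level parameters and a floor on the mean acceptance fraction,
and fits exceeding them carry explicit flags. Identical seeds reproduce
draws bit-exactly.

Prior-predictive sampling draws hyperparameters, fish parameters and data
from the model forward; posterior-predictive checks replicate data at the
observed design points and report the fraction of per-(fish, session)
observed medians inside the central 94% interval of replicated medians —
near 0.94 for well-specified data, collapsing under non-monotone trends
that an exponential relaxation cannot track.

## Posterior summaries and stage comparisons

Summaries are medians with 94% highest-density intervals. The HDI is the
leftmost shortest window of the sorted draws containing ⌈0.94·n⌉ of them;
constant draws give a zero-width interval, and a heuristic warns when the
shortest window is far shorter than the central interval (a multimodality
signature that makes any contiguous interval misleading).

Stage contrasts (aftereffect, savings) report difference draws `b − a` of a
population-level derived parameter, their HDI, and the fraction of the
difference posterior inside a region of practical equivalence: ±1
success/session, ±5°, or ±2 m by measure. The two fits are independent
posteriors, so each fit's draws are shuffled with a seed keyed to the
draws themselves before pairing — reproducible, order-free, and exactly
antisymmetric under swapping the fits (a fit compared with itself yields
identically zero differences and overlap 1).

The across-fish relation between initial learning rates in the two
perturbation stages is a Bayesian simple linear regression of second-stage
on first-stage per-fish posterior medians, sampled exactly from the
normal–inverse-gamma posterior under the reference prior. An optional
errors-in-variables variant treats each fish's true rates as latent with
known per-fish posterior SDs on both axes and samples with an ensemble;
walker initialisation keeps the latent positions within the measurement sd,
without which the ensemble starts at negligible density and degenerates.

## The synthetic-data generator

*Likelihood tier.* Fish-level curve parameters are drawn around population
values on the same scales the hierarchy uses — normal for every amplitude
and for the angular asymptote, lognormal (population value = median) for
time constants and the count/distance asymptotes — then observations are
drawn from the exact likelihood families, so recovery studies probe a
well-specified estimation problem. Draws violating the support of the
count/distance curves are rejected, i.e. the population distribution is
truncated to the likelihood's support. Success counts are clipped at the
physical maximum of 6 and the number of clips is logged, so calibration
studies can quantify the (small) model/generator mismatch this ceiling
introduces. Default population values mirror the rotation-stage study
conditions: success rising from ≈1.9 to ≈3.5 per session, angular error
falling from ≈+11° to ≈−1.5°, distance falling from ≈6 m to ≈3.8 m, time
constants of 2.5–3 sessions, with between-fish spreads of 0.1–0.25 on the
log scales and 0.4–4 measure units on the raw scales.

*Trajectory tier.* An agent commits at trial start to the start→target
bearing (its plan), offset by an adaptation bias and optional von Mises
heading noise (default concentration κ = 20); the vehicle moves at constant
speed (0.15 m/s, 0.5 s timestep — a straight drive takes ≈17 s, matching
typical successful trials) along the commanded heading rotated by the
stage's perturbation. The bias relaxes across sessions from its carried-in
value toward the negative of the current rotation with the fish's time
constant, so the measured angular error of a noiseless agent equals
`rotation·exp(−ses/τ)` exactly and the full pipeline recovers τ to
numerical precision. Washout stages start from the adapted bias, producing
the aftereffect; the first baseline starts from a naive aiming offset so
baseline performance itself improves. Committing to the start bearing
(rather than re-aiming every step) is what makes an unadapted trial a
straight rotated ray with a measured error equal to the rotation; per-step
re-aiming (available as an option) would curve the path into a pursuit
spiral whose endpoint error understates the perturbation. The wall-zone
gating of the physical vehicle (motion only when the fish is near a wall
facing outward) is abstracted away: the analysis consumes vehicle
trajectories only, and an optional stationary-dwell fraction reintroduces
idle time if wanted.

What the generator does **not** emulate: hydrodynamics and biomechanics,
within-trial learning, session-to-session forgetting, reward effects,
fish-specific noise levels, or tracking artifacts beyond simple dropout.
Passing recovery tests therefore demonstrates that the estimation machinery
is calibrated for data generated by the model family it assumes (plus the
success ceiling), not that real FOV data satisfy those assumptions.

## Numerical choices

* Angles wrap to (−180°, 180]; −180 maps to +180.
* HDI tie-break: leftmost shortest window. Minimum 2 draws; fewer than 100
  draws warns.
* Working-scale exponentials are clipped (e.g. log-values to ±8…±20) so a
  wild walker proposal yields −∞ density rather than overflow.
* Poisson/Gamma fits return −∞ for any parameter point whose mean curve is
  non-positive at an observed session — the support constraint replaces a
  hard amplitude prior bound.
* Out-of-support data in the standalone likelihood function give −∞ with a
  warning; the model constructors reject them outright.
* Seeds: every stochastic operation takes an explicit integer seed;
  sub-seeds derive via `default_rng([seed, k])` or fixed multipliers, all
  below 2³¹.

## Problem sizes

Cohort-level checks use 8 fish × 15 sessions × 6 trials (the rotation-stage
shape). Calibration uses 20 replications per measure at a reduced sampler
budget (2 chains × 500 draws, 800 tuning steps), with nominal-94% HDIs
expected to cover ≥ 85% of replications (the binomial tolerance at 20
reps). Diagnostic-gate checks use the full default budget. The end-to-end
acceptance script reruns metric geometry (1000 trials), the curve and Gamma
identities on parameter grids, HDI/ROPE machinery on 10⁶/2×10⁵ normal
draws, trajectory τ-recovery, a 10-replication calibration, and a
rotation-versus-savings contrast on angular error generated under the
study's stage conditions.

## Known limitations

* The ensemble sampler's split-R̂ can exceed 1.01 on occasional seeds for
  the distance measure at default budgets; such fits carry flags rather
  than being silently accepted.
* ROPE half-widths and the 0.25 m target radius are conventions, not
  estimates.
* The success ceiling (clipped Poisson) slightly biases late-stage
  asymptotes downward when μ_∞ approaches 6; the generator logs clip counts
  so this is measurable.
* Baseline improvement in the trajectory simulator comes from a decaying
  aiming offset, not from noise reduction; only its session-median error
  trajectory, not its variance structure, mimics a learning animal.
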
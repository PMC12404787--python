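"""Posterior summaries and stage comparisons.

Fits are summarised by the median and the 94% highest-density interval
(HDI): the shortest contiguous interval holding 94% of the draws, within
which every point is more credible than any point outside.  Stage contrasts
(aftereffect, savings) are reported as difference draws together with the
fraction of the difference posterior falling inside a region of practical
equivalence (ROPE): differences of 1 success/session, 5 degrees of angular
error, or 2 m of distance are considered practically zero.

The across-fish relation between initial learning rates in the first and
second exposure to the perturbation is estimated as a Bayesian simple
linear regression on per-fish posterior medians (exact
normal-inverse-gamma posterior under the reference prior), with an optional
measurement-error variant that propagates per-fish posterior uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import emcee
import numpy as np

from fovadapt.curves import MeasureFamily

__all__ = [
    "RopeSpec",
    "StageComparison",
    "hdi",
    "rope_overlap",
    "compare_stages",
    "learning_rate_slope",
    "DERIVED_PARAMETERS",
]

DERIVED_PARAMETERS = ("initial_value", "asymptotic_performance", "initial_learning_rate")

#: Printed ROPE half-widths per measure (difference scale).
DEFAULT_ROPE_HALF_WIDTH = {
    MeasureFamily.SUCCESS_POISSON: 1.0,  # one success/session
    MeasureFamily.ANGULAR_STUDENT_T: 5.0,  # degrees
    MeasureFamily.DISTANCE_GAMMA: 2.0,  # metres
}


@dataclass(frozen=True)
class RopeSpec:
    """A symmetric region of practical equivalence for one measure."""

    measure: MeasureFamily
    half_width: float

    @classmethod
    def for_measure(cls, measure: MeasureFamily | str) -> "RopeSpec":
        measure = MeasureFamily(measure)
        return cls(measure, DEFAULT_ROPE_HALF_WIDTH[measure])

    @property
    def interval(self) -> tuple[float, float]:
        return (-self.half_width, self.half_width)


@dataclass
class StageComparison:
    """A paired posterior contrast of one derived parameter between stages."""

    parameter: str
    stage_a: str
    stage_b: str
    difference_draws: np.ndarray = field(repr=False)
    median: float = 0.0
    hdi_low: float = 0.0
    hdi_high: float = 0.0
    rope_overlap: float = float("nan")
    rope: RopeSpec | None = None


def hdi(draws, prob: float = 0.94) -> tuple[float, float]:
    """Highest-density interval: the shortest window holding ``prob`` mass.

    Implemented as the leftmost shortest window over the sorted draws
    containing ``ceil(prob * n)`` of them.  Warns (heuristically) when that
    window is much shorter than the central interval, a sign of
    multimodality where a single contiguous interval misrepresents the
    distribution, and when fewer than 100 draws make the estimate coarse.
    """
    x = np.sort(np.asarray(draws, float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("hdi needs at least 2 draws")
    if n < 100:
        warnings.warn("hdi on fewer than 100 draws is unreliable", stacklevel=2)
    if not 0.0 < prob <= 1.0:
        raise ValueError("prob must be in (0, 1]")
    m = int(np.ceil(prob * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: leftmost tie-break
    lo, hi = float(x[i]), float(x[i + m - 1])
    alpha = (1.0 - prob) / 2.0
    central = float(np.quantile(x, 1 - alpha) - np.quantile(x, alpha))
    if central > 0 and (hi - lo) < 0.4 * central:
        warnings.warn(
            "HDI much shorter than the central interval; distribution may be "
            "multimodal and a contiguous HDI misleading",
            stacklevel=2,
        )
    return lo, hi


def rope_overlap(difference_draws, rope: RopeSpec | tuple[float, float] | float) -> float:
    """Fraction of difference draws inside the ROPE (closed interval)."""
    x = np.asarray(difference_draws, float).ravel()
    if isinstance(rope, RopeSpec):
        lo, hi = rope.interval
    elif np.isscalar(rope):
        lo, hi = -float(rope), float(rope)
    else:
        lo, hi = map(float, rope)
    return float(np.mean((x >= lo) & (x <= hi)))


def _keyed_shuffle(draws: np.ndarray, seed: int) -> np.ndarray:
    """Shuffle draws with a seed derived from the draws' own bytes."""
    import zlib

    key = zlib.crc32(np.ascontiguousarray(draws[: min(64, draws.size)]).tobytes())
    rng = np.random.default_rng([seed, key])
    return draws[rng.permutation(draws.size)]


def compare_stages(
    fit_a,
    fit_b,
    parameter: str,
    *,
    rope: RopeSpec | None = None,
    seed: int = 0,
    prob: float = 0.94,
) -> StageComparison:
    """Posterior contrast ``b - a`` of a population derived parameter.

    The two fits are independent posteriors, so their draws carry no joint
    order; a seeded permutation of each before pairing removes any spurious
    correlation from sampler trajectories while keeping the contrast
    reproducible.  Swapping the fits negates the difference draws exactly
    (the permutation depends only on the seed and draw counts).
    """
    if parameter not in DERIVED_PARAMETERS:
        raise ValueError(f"parameter must be one of {DERIVED_PARAMETERS}")
    if fit_a.family is not fit_b.family:
        raise ValueError("stage comparison requires fits of the same measure")
    if rope is None:
        rope = RopeSpec.for_measure(fit_a.family)
    da = fit_a.population_draws(parameter)
    db = fit_b.population_draws(parameter)
    n = min(da.size, db.size)
    # Each fit's shuffle is keyed by the fit's own draws (not its argument
    # position), so swapping the fits negates the differences exactly.
    diff = _keyed_shuffle(db, seed)[:n] - _keyed_shuffle(da, seed)[:n]
    lo, hi = hdi(diff, prob)
    return StageComparison(
        parameter=parameter,
        stage_a=getattr(fit_a, "stage", "a"),
        stage_b=getattr(fit_b, "stage", "b"),
        difference_draws=diff,
        median=float(np.median(diff)),
        hdi_low=lo,
        hdi_high=hi,
        rope_overlap=rope_overlap(diff, rope),
        rope=rope,
    )


def _conjugate_regression_draws(
    x: np.ndarray, y: np.ndarray, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Exact posterior slope draws for y = a + b x under the reference prior."""
    n = x.size
    X = np.column_stack([np.ones(n), x])
    XtX = X.T @ X
    beta_hat = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta_hat
    rss = float(resid @ resid)
    dof = n - 2
    if dof < 1:
        raise ValueError("regression needs at least 3 points")
    if rss <= 0:  # exactly collinear points: slope is known with certainty
        return np.full(n_draws, beta_hat[1])
    sigma2 = rss / rng.chisquare(dof, size=n_draws)
    cov = np.linalg.inv(XtX)
    slope_sd = np.sqrt(sigma2 * cov[1, 1])
    return beta_hat[1] + slope_sd * rng.standard_normal(n_draws)


def learning_rate_slope(
    rates_stage1,
    rates_stage2,
    *,
    seed: int = 0,
    n_draws: int = 8000,
    prob: float = 0.94,
    measurement_error: bool = False,
    sd_stage1=None,
    sd_stage2=None,
) -> dict:
    """Across-fish regression of second-exposure on first-exposure learning rate.

    ``rates_stage1``/``rates_stage2`` are per-fish summaries (posterior
    medians) of the initial learning rate in the first rotation and the
    re-rotation stage.  The default model is an exact Bayesian simple linear
    regression on those points.  With ``measurement_error=True`` (requires
    per-fish posterior SDs) each fish's true rates are latent, observed with
    known noise on both axes, and the posterior is sampled with an ensemble
    sampler.

    Returns a dict with ``slope_draws``, ``median`` and the 94% HDI.
    """
    x = np.asarray(rates_stage1, float)
    y = np.asarray(rates_stage2, float)
    if x.size != y.size:
        raise ValueError("both stages must provide the same fish")
    if x.size < 3:
        raise ValueError("learning-rate slope needs at least 3 fish in both stages")
    rng = np.random.default_rng(seed)
    if not measurement_error:
        slope = _conjugate_regression_draws(x, y, n_draws, rng)
    else:
        if sd_stage1 is None or sd_stage2 is None:
            raise ValueError("measurement_error=True requires per-fish posterior SDs")
        sx = np.clip(np.asarray(sd_stage1, float), 1e-9, None)
        sy = np.clip(np.asarray(sd_stage2, float), 1e-9, None)
        F = x.size
        scale = max(float(np.std(y)), 1e-3)

        def logp(theta):
            theta = np.atleast_2d(theta)
            a, b, lsig = theta[:, 0], theta[:, 1], theta[:, 2]
            xt = theta[:, 3:]
            sig = np.exp(np.clip(lsig, -10, 5))
            lp = -0.5 * (a / (10 * scale)) ** 2 - 0.5 * (b / 10.0) ** 2
            lp += -0.5 * ((lsig - np.log(scale)) / 1.5) ** 2
            lp += -0.5 * (((x - xt) / sx) ** 2).sum(axis=1)
            mu_y = a[:, None] + b[:, None] * xt
            lp += (
                -0.5 * (((y - mu_y) / np.hypot(sy, sig[:, None])) ** 2).sum(axis=1)
                - F * np.log(sig)
            )
            return lp

        ndim = 3 + F
        nwalkers = max(4 * ndim + 2, 24)
        sampler = emcee.EnsembleSampler(nwalkers, ndim, logp, vectorize=True)
        sampler.random_state = np.random.RandomState(seed % (2**32)).get_state()
        # latent-x jitter must respect the measurement sd, or walkers start
        # at negligible density and the ensemble degenerates
        p0 = np.empty((nwalkers, ndim))
        p0[:, 0] = np.mean(y) + 0.2 * scale * rng.standard_normal(nwalkers)
        p0[:, 1] = 0.5 * rng.standard_normal(nwalkers)
        p0[:, 2] = np.log(scale) + 0.3 * rng.standard_normal(nwalkers)
        p0[:, 3:] = x + np.minimum(sx, 0.3 * scale) * rng.standard_normal((nwalkers, F))
        burn = 800
        steps = burn + int(np.ceil(n_draws / nwalkers)) * 3
        sampler.run_mcmc(p0, steps, progress=False, skip_initial_state_check=True)
        slope = sampler.get_chain(discard=burn, thin=3)[:, :, 1].ravel()[:n_draws]
    lo, hi = hdi(slope, prob)
    return dict(
        slope_draws=slope,
        median=float(np.median(slope)),
        hdi_low=lo,
        hdi_high=hi,
    )
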
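"""Exponential learning curves and measure-specific likelihood families.

Performance on session ``ses`` (0-based within a stage) is modelled as an
exponential relaxation

    mu_hat(ses) = A_mu * exp(-ses / tau_mu) + mu_inf

and the spread of trials around that curve relaxes with the same time
constant,

    sigma_hat(ses) = A_sigma * exp(-ses / tau_mu) + sigma_inf.

Three likelihood families match the three performance measures: Poisson for
success counts per session, Student's t (location mu_hat, scale sigma_hat,
shared degrees of freedom nu) for signed angular error, and a Gamma
distribution parameterised by its mode (= mu_hat) and standard deviation
(= sigma_hat) for the adjusted distance.

Each curve reduces to three behavioural scalars: the initial value
``A_mu + mu_inf``, the asymptotic performance ``mu_inf``, and the initial
learning rate ``-A_mu / tau_mu`` (the curve's slope at session 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

__all__ = [
    "MeasureFamily",
    "LearningCurveParams",
    "curve_mean",
    "curve_sd",
    "gamma_mode_sd_to_shape_rate",
    "log_likelihood",
    "derived_parameters",
]


class MeasureFamily(str, Enum):
    """The three measure/likelihood pairings."""

    SUCCESS_POISSON = "success_poisson"
    ANGULAR_STUDENT_T = "angular_student_t"
    DISTANCE_GAMMA = "distance_gamma"

    @property
    def positive_mean(self) -> bool:
        """Whether the mean curve must stay positive (count/positive support)."""
        return self in (MeasureFamily.SUCCESS_POISSON, MeasureFamily.DISTANCE_GAMMA)

    @property
    def has_dispersion(self) -> bool:
        return self is not MeasureFamily.SUCCESS_POISSON

    @property
    def measure_column(self) -> str:
        return {
            MeasureFamily.SUCCESS_POISSON: "success_count",
            MeasureFamily.ANGULAR_STUDENT_T: "angular_error_deg",
            MeasureFamily.DISTANCE_GAMMA: "d_m",
        }[self]


@dataclass
class LearningCurveParams:
    """Exponential-curve parameters for one fish x stage x measure.

    ``A_mu`` carries the sign of the deficit: positive when performance
    starts high and relaxes down (angular error, distance), negative when it
    rises toward the asymptote (success counts).
    """

    A_mu: float
    tau_mu: float
    mu_inf: float
    A_sigma: float = 0.0
    sigma_inf: float = 1.0
    nu: float = 30.0

    def __post_init__(self) -> None:
        if self.tau_mu <= 0:
            raise ValueError("tau_mu must be positive")
        if self.sigma_inf <= 0:
            raise ValueError("sigma_inf must be positive")
        if self.A_sigma < 0:
            raise ValueError("A_sigma must be non-negative")
        if self.nu <= 0:
            raise ValueError("nu must be positive")


def curve_mean(params: LearningCurveParams, ses) -> np.ndarray | float:
    """Mean performance ``A_mu * exp(-ses/tau_mu) + mu_inf`` at session(s) ``ses``."""
    ses = np.asarray(ses, float)
    out = params.A_mu * np.exp(-ses / params.tau_mu) + params.mu_inf
    return float(out) if out.ndim == 0 else out


def curve_sd(params: LearningCurveParams, ses, *, tau_sigma: float | None = None):
    """Dispersion curve ``A_sigma * exp(-ses/tau) + sigma_inf``.

    Shares the mean curve's time constant unless ``tau_sigma`` decouples it.
    Rejects parameter combinations giving a non-positive spread.
    """
    tau = params.tau_mu if tau_sigma is None else tau_sigma
    if tau <= 0:
        raise ValueError("time constant must be positive")
    ses = np.asarray(ses, float)
    out = params.A_sigma * np.exp(-ses / tau) + params.sigma_inf
    if np.any(out <= 0):
        raise ValueError("dispersion curve must stay positive")
    return float(out) if out.ndim == 0 else out


def gamma_mode_sd_to_shape_rate(mode, sd):
    """Convert a (mode, sd) Gamma parameterisation to (shape, rate).

    Solves ``mode = (shape - 1)/rate`` and ``sd^2 = shape/rate^2`` in closed
    form: ``rate = (mode + sqrt(mode^2 + 4 sd^2)) / (2 sd^2)`` and
    ``shape = 1 + mode * rate``, so shape > 1 and the mode is interior.
    """
    mode = np.asarray(mode, float)
    sd = np.asarray(sd, float)
    if np.any(mode <= 0) or np.any(sd <= 0):
        raise ValueError("mode and sd must be positive")
    rate = (mode + np.sqrt(mode**2 + 4.0 * sd**2)) / (2.0 * sd**2)
    shape = 1.0 + mode * rate
    if mode.ndim == 0 and sd.ndim == 0:
        return float(shape), float(rate)
    return shape, rate


def log_likelihood(
    family: MeasureFamily,
    datum,
    params: LearningCurveParams,
    ses,
    *,
    success_family: str = "poisson",
) -> np.ndarray | float:
    """Log-density of ``datum`` observed at session ``ses`` under ``family``.

    Out-of-support data (negative or non-integer counts, non-positive
    distances) get ``-inf`` with a warning rather than an exception, so a
    single corrupt trial cannot abort a whole fit.

    ``success_family="binomial"`` swaps the Poisson for a Binomial(6, p)
    with ``p = mu_hat/6``, acknowledging the physical ceiling of six
    successes per session (off by default; the Poisson matches the model as
    specified).
    """
    family = MeasureFamily(family)
    datum = np.asarray(datum, float)
    ses = np.asarray(ses, float)
    mu = np.asarray(curve_mean(params, ses), float)

    if family is MeasureFamily.SUCCESS_POISSON:
        ok = (datum >= 0) & (datum == np.floor(datum))
        if not np.all(ok):
            warnings.warn("success counts must be non-negative integers", stacklevel=2)
        if np.any(mu <= 0):
            raise ValueError("Poisson mean curve must stay positive over the fitted range")
        if success_family == "binomial":
            p = np.clip(mu / 6.0, 1e-12, 1 - 1e-12)
            if np.any(datum > 6):
                warnings.warn("success counts above 6 are outside the binomial support", stacklevel=2)
            out = np.where(ok & (datum <= 6), stats.binom.logpmf(np.where(ok, datum, 0), 6, p), -np.inf)
        else:
            out = np.where(ok, stats.poisson.logpmf(np.where(ok, datum, 0), mu), -np.inf)
    elif family is MeasureFamily.ANGULAR_STUDENT_T:
        sd = np.asarray(curve_sd(params, ses), float)
        out = stats.t.logpdf(datum, df=params.nu, loc=mu, scale=sd)
    else:
        sd = np.asarray(curve_sd(params, ses), float)
        if np.any(mu <= 0):
            raise ValueError("Gamma mode curve must stay positive over the fitted range")
        ok = datum > 0
        if not np.all(ok):
            warnings.warn("distances must be strictly positive", stacklevel=2)
        shape, rate = gamma_mode_sd_to_shape_rate(mu, sd)
        out = np.where(ok, stats.gamma.logpdf(np.where(ok, datum, 1.0), a=shape, scale=1.0 / rate), -np.inf)
    return float(out) if out.ndim == 0 else out


def derived_parameters(params: LearningCurveParams) -> tuple[float, float, float]:
    """(initial value, asymptotic performance, initial learning rate).

    ``initial value = A_mu + mu_inf`` is the curve at session 0;
    ``asymptotic performance = mu_inf`` its limit; and
    ``initial learning rate = -A_mu / tau_mu`` equals d(mu_hat)/d(ses) at 0,
    so improvement is a positive rate for success counts and a negative rate
    for angular error and distance.
    """
    return (
        params.A_mu + params.mu_inf,
        params.mu_inf,
        -params.A_mu / params.tau_mu,
    )
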
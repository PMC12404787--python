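"""Hierarchical Bayesian fitting of learning curves across fish.

One fit covers one measure in one stage.  Every fish gets its own
exponential-curve parameters (amplitude, time constant, asymptote), drawn
from population-level distributions; dispersion-curve parameters and the
Student-t degrees of freedom are shared across fish.  The sampler works in
an unconstrained space:

* time constants ``tau`` — always log-scale;
* the asymptote — log-scale for the count and distance measures (whose
  mean curve must stay positive), raw scale for the angular measure; the
  amplitude is raw-scale (Normal) for every measure, with the mean curve's
  positivity enforced through the likelihood's support;
* population priors are Normal on the working scale (lognormal on the
  natural scale for positive parameters), centered empirically on coarse
  data summaries with deliberately broad widths;
* ``nu`` has an Exponential prior (mean 30, configurable), the traditional
  choice for degrees of freedom.

Three parameterizations of the hierarchy are available: ``marginal`` (the
default — population means integrated out analytically, then recovered per
draw from their exact normal conditional), ``centered`` and
``non-centered``.  The marginal form removes the global ridge between the
population means and every fish's parameters, which is the direction an
ensemble sampler traverses most slowly.

The joint log-density is written here explicitly; posterior draws come from
independently seeded affine-invariant ensemble samplers (emcee) with
differential-evolution moves, and diagnostics (split R-hat across the
independent chains, effective sample size, acceptance fraction) are
computed with ArviZ.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import ceil

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.special import gammaln

from fovadapt.curves import LearningCurveParams, MeasureFamily, curve_mean, curve_sd
from fovadapt.curves import gamma_mode_sd_to_shape_rate

__all__ = [
    "HierarchySpec",
    "SamplerConfig",
    "HierarchicalModel",
    "PosteriorFit",
    "empirical_bayes_prior_centers",
    "build_model",
    "sample_posterior",
    "sample_ensemble_chains",
    "prior_predictive",
    "posterior_predictive",
    "sample_observations",
]

log = logging.getLogger(__name__)

_CURVE_PARAMS = ("A_mu", "tau_mu", "mu_inf")


@dataclass
class HierarchySpec:
    """Population-prior settings for one measure's hierarchical fit.

    ``centers``/``widths`` are on the working (transformed) scale.  The
    amplitude is unconstrained (Normal hierarchy) for every measure — its
    sign is identified by the data, and the likelihood's support constraint
    (the mean curve must stay positive for counts and distances) replaces
    any hard bound on the amplitude itself.
    """

    family: MeasureFamily
    centers: dict[str, float]
    widths: dict[str, float]
    pop_sd_scale: dict[str, float] = field(
        default_factory=lambda: {"A_mu": 0.3, "tau_mu": 0.3, "mu_inf": 0.2}
    )
    pop_sd_log_width: float = 0.5
    log_A_sigma_center: float = 0.0
    log_sigma_inf_center: float = 0.0
    dispersion_width: float = 1.0
    nu_prior_mean: float = 30.0
    tau_sigma_decoupled: bool = False  # reserve: dispersion with its own tau

    @property
    def raw_mean_scale(self) -> bool:
        return self.family is MeasureFamily.ANGULAR_STUDENT_T


@dataclass
class SamplerConfig:
    """MCMC settings: 4 chains x 1000 retained draws after 1000 tuning steps.

    Each chain is an independently initialised and seeded walker ensemble;
    split R-hat therefore compares genuinely independent runs.  Every chain
    retains at least ``draws`` thinned draws (flattened over its walkers),
    so the total is at least ``chains * draws``.  ``thin`` trades wall time
    for lower autocorrelation.
    """

    chains: int = 4
    tune: int = 1000
    draws: int = 1000
    seed: int = 0
    thin: int = 2
    walkers: int | None = None
    target_rhat: float = 1.01
    min_acceptance: float = 0.03


DEFAULT_SPECS: dict[MeasureFamily, dict] = {
    MeasureFamily.SUCCESS_POISSON: dict(
        centers={"A_mu": -1.5, "tau_mu": np.log(4.0), "mu_inf": np.log(3.0)},
        widths={"A_mu": 2.5, "tau_mu": 1.0, "mu_inf": 1.0},
        pop_sd_scale={"A_mu": 0.5, "tau_mu": 0.3, "mu_inf": 0.2},
        log_A_sigma_center=0.0,
        log_sigma_inf_center=0.0,
    ),
    MeasureFamily.ANGULAR_STUDENT_T: dict(
        centers={"A_mu": 30.0, "tau_mu": np.log(4.0), "mu_inf": 0.0},
        widths={"A_mu": 30.0, "tau_mu": 1.0, "mu_inf": 15.0},
        pop_sd_scale={"A_mu": 4.0, "tau_mu": 0.3, "mu_inf": 2.0},
        log_A_sigma_center=np.log(10.0),
        log_sigma_inf_center=np.log(8.0),
    ),
    MeasureFamily.DISTANCE_GAMMA: dict(
        centers={"A_mu": 2.5, "tau_mu": np.log(4.0), "mu_inf": np.log(3.5)},
        widths={"A_mu": 3.0, "tau_mu": 1.0, "mu_inf": 1.0},
        pop_sd_scale={"A_mu": 0.8, "tau_mu": 0.3, "mu_inf": 0.2},
        log_A_sigma_center=np.log(1.5),
        log_sigma_inf_center=np.log(1.0),
    ),
}


def _robust_sd(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return 1.0
    mad = np.median(np.abs(x - np.median(x)))
    return float(1.4826 * mad) if mad > 0 else float(max(np.std(x), 1e-3))


def empirical_bayes_prior_centers(
    obs: pd.DataFrame, family: MeasureFamily, *, value_col: str = "value"
) -> HierarchySpec:
    """Center population priors on coarse summaries of the data.

    The asymptote prior is centered on the median of the last third of
    sessions, the amplitude on the first-third median minus that, and the
    time constant on one third of the stage length; widths are broad
    multiples of the data's robust spread so the priors inform scale, not
    conclusions.  With fewer than three sessions the fixed defaults are used
    with a warning.
    """
    family = MeasureFamily(family)
    defaults = DEFAULT_SPECS[family]
    n_ses = int(obs["session"].max()) + 1 if len(obs) else 0
    if n_ses < 3:
        warnings.warn("fewer than 3 sessions: falling back to default prior centers", stacklevel=2)
        return HierarchySpec(family=family, **defaults)

    per_ses = obs.groupby("session")[value_col].median()
    third = max(1, n_ses // 3)
    m1 = float(per_ses.iloc[:third].median())
    m3 = float(per_ses.iloc[-third:].median())
    tau_c_natural = max(n_ses / 3.0, 1.0)
    # m1 reflects the curve ~mid-way through the first window, after some
    # decay; undo that with the exponential's own factor so the amplitude
    # center estimates the session-0 deficit rather than a diluted one
    mid_first = (third - 1) / 2.0
    a_c = (m1 - m3) * float(np.exp(mid_first / tau_c_natural))
    scale = _robust_sd(obs[value_col].to_numpy())
    tau_c, tau_w = float(np.log(tau_c_natural)), 1.0

    first_vals = obs.loc[obs["session"] < third, value_col].to_numpy()
    last_vals = obs.loc[obs["session"] >= n_ses - third, value_col].to_numpy()
    sd1, sd3 = _robust_sd(first_vals), _robust_sd(last_vals)
    lsig_c = float(np.log(max(sd3, 1e-2)))
    lasig_c = float(np.log(max(sd1 - sd3, 0.25 * sd3, 1e-2)))

    if family.positive_mean:
        floor = max(0.05 * max(abs(m3), scale), 1e-3)
        centers = {
            "A_mu": a_c,
            "tau_mu": tau_c,
            "mu_inf": float(np.log(max(m3, floor))),
        }
        widths = {
            "A_mu": max(2.0 * abs(a_c), 2.0 * scale, 0.5),
            "tau_mu": tau_w,
            "mu_inf": 1.0,
        }
        pop_sd = {
            "A_mu": max(0.3 * abs(a_c), 0.3 * scale, 0.1),
            "tau_mu": 0.3,
            "mu_inf": 0.2,
        }
    else:
        centers = {"A_mu": a_c, "tau_mu": tau_c, "mu_inf": m3}
        widths = {
            "A_mu": max(2.0 * abs(a_c), 2.0 * scale, 10.0),
            "tau_mu": tau_w,
            "mu_inf": max(2.0 * scale, 10.0),
        }
        pop_sd = {
            "A_mu": max(0.5 * scale, 2.0),
            "tau_mu": 0.3,
            "mu_inf": max(0.3 * scale, 1.0),
        }
    return HierarchySpec(
        family=family,
        centers=centers,
        widths=widths,
        pop_sd_scale=pop_sd,
        log_A_sigma_center=lasig_c,
        log_sigma_inf_center=lsig_c,
        nu_prior_mean=30.0,
    )


class HierarchicalModel:
    """Joint log-density over population hyperparameters and fish curves.

    Parameter vector layout (working scale):
    ``[m_A, m_tau, m_mu, log s_A, log s_tau, log s_mu,
    z_A(fish...), z_tau(fish...), z_mu(fish...),
    (log A_sigma, log sigma_inf), (log nu)]``.
    """

    def __init__(
        self,
        family: MeasureFamily,
        hierarchy: HierarchySpec,
        fish_ids: list[str],
        ses: np.ndarray,
        y: np.ndarray,
        fish_idx: np.ndarray,
        *,
        parameterization: str = "marginal",
    ) -> None:
        self.family = MeasureFamily(family)
        if hierarchy.family is not self.family:
            raise ValueError("hierarchy spec was built for a different measure family")
        self.hierarchy = hierarchy
        self.fish_ids = list(fish_ids)
        self.n_fish = len(self.fish_ids)
        if self.n_fish < 1 or len(y) == 0:
            raise ValueError("need at least one fish and one observation")
        self.ses = np.asarray(ses, float)
        self.y = np.asarray(y, float)
        self.fish_idx = np.asarray(fish_idx, int)
        if self.family is MeasureFamily.SUCCESS_POISSON:
            if np.any(self.y < 0) or np.any(self.y != np.floor(self.y)):
                raise ValueError("success counts must be non-negative integers")
            self._logfact = gammaln(self.y + 1.0).sum()
        if self.family is MeasureFamily.DISTANCE_GAMMA and np.any(self.y <= 0):
            raise ValueError("distances must be strictly positive")

        if parameterization not in ("marginal", "centered", "non-centered"):
            raise ValueError(
                "parameterization must be 'marginal', 'centered' or 'non-centered'"
            )
        self.parameterization = parameterization
        F = self.n_fish
        self._c = np.array([hierarchy.centers[p] for p in _CURVE_PARAMS])
        self._w = np.array([hierarchy.widths[p] for p in _CURVE_PARAMS])
        self._ls0 = np.log([hierarchy.pop_sd_scale[p] for p in _CURVE_PARAMS])
        self.has_dispersion = self.family.has_dispersion
        self.has_nu = self.family is MeasureFamily.ANGULAR_STUDENT_T
        n_extra = (2 if self.has_dispersion else 0) + (1 if self.has_nu else 0)
        if parameterization == "marginal":
            # population means integrated out in closed form; the sampler
            # sees only [log pop-sd (3), fish params (3F), dispersion, nu]
            self._im = None
            self._ils = slice(0, 3)
            self._iz = slice(3, 3 + 3 * F)
            self._idisp = 3 + 3 * F
            self.ndim = 3 + 3 * F + n_extra
        else:
            self._im = slice(0, 3)
            self._ils = slice(3, 6)
            self._iz = slice(6, 6 + 3 * F)
            self._idisp = 6 + 3 * F
            self.ndim = 6 + 3 * F + n_extra

    # -- parameter transforms -------------------------------------------------

    def _natural(self, Theta: np.ndarray):
        """Working-scale (W, D) -> natural fish-level and shared parameters."""
        h = self.hierarchy
        W = Theta.shape[0]
        F = self.n_fish
        s = np.exp(np.clip(Theta[:, self._ils], -10, 5))
        z = Theta[:, self._iz].reshape(W, 3, F)
        if self.parameterization == "non-centered":
            m = Theta[:, self._im]
            x = m[:, :, None] + s[:, :, None] * z  # (W, 3, F)
        else:
            m = Theta[:, self._im] if self._im is not None else None
            x = z  # fish-level working-scale parameters sampled directly
        tau = np.exp(np.clip(x[:, 1], -8, 8))
        A = x[:, 0]  # raw scale for every measure; sign identified by data
        if h.raw_mean_scale:
            mu_inf = x[:, 2]
        else:
            mu_inf = np.exp(np.clip(x[:, 2], -20, 10))
        out = dict(A=A, tau=tau, mu_inf=mu_inf, m=m, s=s, x=x)
        if self.has_dispersion:
            out["A_sigma"] = np.exp(np.clip(Theta[:, self._idisp], -15, 8))
            out["sigma_inf"] = np.exp(np.clip(Theta[:, self._idisp + 1], -15, 8))
        if self.has_nu:
            out["nu"] = np.exp(np.clip(Theta[:, self._idisp + 2], np.log(1.05), 7))
        return out

    # -- densities ------------------------------------------------------------

    def _log_prior(self, Theta: np.ndarray) -> np.ndarray:
        h = self.hierarchy
        W = Theta.shape[0]
        F = self.n_fish
        lp = -0.5 * (((Theta[:, self._ils] - self._ls0) / h.pop_sd_log_width) ** 2).sum(axis=1)
        s = np.exp(np.clip(Theta[:, self._ils], -10, 5))
        if self.parameterization == "marginal":
            # Fish parameters under the hierarchy with the population mean
            # integrated out: x_p ~ MVN(c_p 1, s_p^2 I + w_p^2 J), evaluated
            # via Sherman-Morrison (J is the all-ones matrix).
            x = Theta[:, self._iz].reshape(W, 3, F)
            d = x - self._c[None, :, None]
            s2 = s**2
            w2 = self._w**2
            Q = (d**2).sum(axis=2)
            T = d.sum(axis=2)
            quad = (Q - (w2 / (s2 + F * w2)) * T**2) / s2
            logdet = (F - 1) * np.log(s2) + np.log(s2 + F * w2)
            lp -= 0.5 * (quad + logdet).sum(axis=1)
        else:
            lp -= 0.5 * (((Theta[:, self._im] - self._c) / self._w) ** 2).sum(axis=1)
            if self.parameterization == "centered":
                m = Theta[:, self._im][:, :, None]
                x = Theta[:, self._iz].reshape(W, 3, F)
                lp -= (0.5 * ((x - m) / s[:, :, None]) ** 2 + np.log(s[:, :, None])).sum(
                    axis=(1, 2)
                )
            else:
                lp -= 0.5 * (Theta[:, self._iz] ** 2).sum(axis=1)
        if self.has_dispersion:
            cd = np.array([h.log_A_sigma_center, h.log_sigma_inf_center])
            lp -= 0.5 * (
                ((Theta[:, self._idisp : self._idisp + 2] - cd) / h.dispersion_width) ** 2
            ).sum(axis=1)
        if self.has_nu:
            lnu = Theta[:, self._idisp + 2]
            nu = np.exp(np.clip(lnu, np.log(1.05), 7))
            lp += -nu / h.nu_prior_mean + lnu  # Exponential prior + log-Jacobian
        return lp

    def _log_likelihood(self, nat: dict) -> np.ndarray:
        ses, y, fi = self.ses, self.y, self.fish_idx
        tau_o = nat["tau"][:, fi]
        decay = np.exp(-ses / tau_o)
        mu = nat["A"][:, fi] * decay + nat["mu_inf"][:, fi]
        if self.family is MeasureFamily.SUCCESS_POISSON:
            bad = np.any(mu <= 0, axis=1)
            mu_safe = np.where(mu > 0, mu, 1.0)
            ll = (y * np.log(mu_safe) - mu_safe).sum(axis=1) - self._logfact
            ll[bad] = -np.inf
            return ll
        sd = nat["A_sigma"][:, None] * decay + nat["sigma_inf"][:, None]
        bad = np.any(sd <= 0, axis=1)
        sd = np.where(sd > 0, sd, 1.0)
        if self.family is MeasureFamily.ANGULAR_STUDENT_T:
            nu = nat["nu"]
            zsc = (y - mu) / sd
            n = y.size
            const = gammaln((nu + 1) / 2) - gammaln(nu / 2) - 0.5 * np.log(nu * np.pi)
            ll = (
                n * const
                - np.log(sd).sum(axis=1)
                - ((nu[:, None] + 1) / 2 * np.log1p(zsc**2 / nu[:, None])).sum(axis=1)
            )
            ll[bad] = -np.inf
            return ll
        # Gamma(mode, sd)
        bad |= np.any(mu <= 0, axis=1)
        mu_safe = np.where(mu > 0, mu, 1.0)
        rate = (mu_safe + np.sqrt(mu_safe**2 + 4.0 * sd**2)) / (2.0 * sd**2)
        shape = 1.0 + mu_safe * rate
        ll = (
            shape * np.log(rate)
            - gammaln(shape)
            + (shape - 1.0) * np.log(y)
            - rate * y
        ).sum(axis=1)
        ll[bad] = -np.inf
        return ll

    def log_prob_batch(self, Theta: np.ndarray) -> np.ndarray:
        """Joint log-density for a (walkers, ndim) batch."""
        Theta = np.atleast_2d(np.asarray(Theta, float))
        lp = self._log_prior(Theta)
        nat = self._natural(Theta)
        lp = lp + self._log_likelihood(nat)
        lp[~np.isfinite(lp)] = -np.inf
        return lp

    def log_prob(self, theta: np.ndarray) -> float:
        return float(self.log_prob_batch(theta[None, :])[0])

    # -- sampling helpers -----------------------------------------------------

    def initial_points(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Moderately overdispersed start points around the prior centers."""
        h = self.hierarchy
        p = np.empty((n, self.ndim))
        if self._im is not None:
            p[:, self._im] = self._c + 0.3 * self._w * rng.standard_normal((n, 3))
        p[:, self._ils] = self._ls0 + 0.2 * rng.standard_normal((n, 3))
        if self.parameterization == "non-centered":
            p[:, self._iz] = 0.4 * rng.standard_normal((n, 3 * self.n_fish))
        else:
            s0 = np.exp(self._ls0)
            x0 = self._c[None, :, None] + 0.8 * s0[None, :, None] * rng.standard_normal(
                (n, 3, self.n_fish)
            )
            p[:, self._iz] = x0.reshape(n, 3 * self.n_fish)
        if self.has_dispersion:
            p[:, self._idisp] = h.log_A_sigma_center + 0.3 * rng.standard_normal(n)
            p[:, self._idisp + 1] = h.log_sigma_inf_center + 0.3 * rng.standard_normal(n)
        if self.has_nu:
            p[:, self._idisp + 2] = np.log(15.0) + 0.3 * rng.standard_normal(n)
        return p

    def named_draws(
        self, chain: np.ndarray, rng: np.random.Generator | None = None
    ) -> dict[str, np.ndarray]:
        """Natural-scale variables from a (chains, draws, ndim) chain array.

        Under the marginal parameterization the population means are not in
        the chain; they are reconstructed per draw by sampling their exact
        normal conditional given the fish parameters and population sds
        (Rao-Blackwellised recovery), which needs ``rng``.
        """
        C, D, _ = chain.shape
        nat = self._natural(chain.reshape(C * D, self.ndim))
        h = self.hierarchy

        def rs(a):
            return a.reshape(C, D, *a.shape[1:])

        m, s = nat["m"], nat["s"]
        if m is None:
            rng = rng or np.random.default_rng(0)
            F = self.n_fish
            s2 = s**2
            w2 = self._w**2
            prec = F / s2 + 1.0 / w2
            cond_mean = (nat["x"].sum(axis=2) / s2 + self._c / w2) / prec
            m = cond_mean + rng.standard_normal(s2.shape) / np.sqrt(prec)
        pop_A = m[:, 0]
        pop_mu = m[:, 2] if h.raw_mean_scale else np.exp(m[:, 2])
        pop_tau = np.exp(m[:, 1])
        out = {
            "A_mu": rs(nat["A"]),
            "tau_mu": rs(nat["tau"]),
            "mu_inf": rs(nat["mu_inf"]),
            "initial_value": rs(nat["A"] + nat["mu_inf"]),
            "asymptotic_performance": rs(nat["mu_inf"]),
            "initial_learning_rate": rs(-nat["A"] / nat["tau"]),
            "pop_A_mu": rs(pop_A),
            "pop_tau_mu": rs(pop_tau),
            "pop_mu_inf": rs(pop_mu),
            "pop_initial_value": rs(pop_A + pop_mu),
            "pop_asymptotic_performance": rs(pop_mu),
            "pop_initial_learning_rate": rs(-pop_A / pop_tau),
            "pop_scale_A_mu": rs(s[:, 0]),
            "pop_scale_tau_mu": rs(s[:, 1]),
            "pop_scale_mu_inf": rs(s[:, 2]),
        }
        if self.has_dispersion:
            out["A_sigma"] = rs(nat["A_sigma"])
            out["sigma_inf"] = rs(nat["sigma_inf"])
        if self.has_nu:
            out["nu"] = rs(nat["nu"])
        return out

    def fish_params_from_point(self, theta: np.ndarray) -> list[LearningCurveParams]:
        nat = self._natural(theta[None, :])
        return [
            LearningCurveParams(
                A_mu=float(nat["A"][0, f]),
                tau_mu=float(nat["tau"][0, f]),
                mu_inf=float(nat["mu_inf"][0, f]),
                A_sigma=float(nat["A_sigma"][0]) if self.has_dispersion else 0.0,
                sigma_inf=float(nat["sigma_inf"][0]) if self.has_dispersion else 1.0,
                nu=float(nat["nu"][0]) if self.has_nu else 30.0,
            )
            for f in range(self.n_fish)
        ]


@dataclass
class PosteriorFit:
    """Posterior draws, diagnostics, and derived parameters for one fit."""

    idata: az.InferenceData
    family: MeasureFamily
    fish_ids: list[str]
    stage: str
    config: SamplerConfig
    diagnostics: dict
    flags: list[str]

    @property
    def converged(self) -> bool:
        return not self.flags

    def draws(self, var: str) -> np.ndarray:
        """Posterior draws of ``var``, flattened over chains; fish axis kept."""
        da = self.idata.posterior[var]
        return da.stack(sample=("chain", "draw")).transpose("sample", ...).to_numpy()

    def population_draws(self, parameter: str) -> np.ndarray:
        """Flattened draws of a population-level derived parameter."""
        return self.draws(f"pop_{parameter}")

    def fish_draws(self, parameter: str, fish_id: str) -> np.ndarray:
        i = self.fish_ids.index(fish_id)
        return self.draws(parameter)[:, i]

    def summary(self) -> pd.DataFrame:
        """Per-variable posterior summary (median, 94% HDI, R-hat, ESS)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df = az.summary(self.idata, hdi_prob=0.94, stat_focus="median")
        return df


def build_model(
    obs: pd.DataFrame,
    family: MeasureFamily,
    hierarchy: HierarchySpec | None = None,
    *,
    value_col: str = "value",
    parameterization: str = "marginal",
) -> HierarchicalModel:
    """Assemble the hierarchical model from tidy observations.

    ``obs`` needs columns ``fish_id``, ``session`` and the measure value —
    one row per session for success counts, one per trial for angular error
    and distance (fitting happens at the individual-trial level).
    """
    family = MeasureFamily(family)
    if len(obs) == 0:
        raise ValueError("no observations")
    if hierarchy is None:
        hierarchy = empirical_bayes_prior_centers(obs, family, value_col=value_col)
    fish_ids = sorted(obs["fish_id"].unique())
    fmap = {f: i for i, f in enumerate(fish_ids)}
    return HierarchicalModel(
        family,
        hierarchy,
        fish_ids,
        ses=obs["session"].to_numpy(float),
        y=obs[value_col].to_numpy(float),
        fish_idx=obs["fish_id"].map(fmap).to_numpy(int),
        parameterization=parameterization,
    )


def _walker_count(ndim: int, config: SamplerConfig) -> int:
    # a generous ensemble (4x dimension) keeps the differential-evolution
    # proposal pool rich, which matters more here than chain length
    w = config.walkers or max(4 * ndim + 2, 16)
    return w + w % 2


def sample_ensemble_chains(
    log_prob_batch,
    initial_points,
    ndim: int,
    config: SamplerConfig,
) -> tuple[np.ndarray, list[float]]:
    """Run ``config.chains`` independent walker ensembles over a log-density.

    ``initial_points(rng, n)`` supplies start positions.  Each ensemble gets
    its own deterministic sub-seed, burns ``config.tune`` steps, and is then
    run (thinned by ``config.thin``) until at least ``config.draws`` draws
    are retained per chain; one ensemble's retained steps are flattened
    step-major.  Returns the ``(chains, draws_per_chain, ndim)`` array and
    per-chain mean acceptance fractions.
    """
    nwalkers = _walker_count(ndim, config)
    steps_retain = ceil(config.draws / nwalkers)
    total = config.tune + steps_retain * config.thin
    chains, accepts = [], []
    for c in range(config.chains):
        rng = np.random.default_rng([config.seed, c])
        p0 = initial_points(rng, nwalkers)
        sampler = emcee.EnsembleSampler(
            nwalkers,
            ndim,
            log_prob_batch,
            vectorize=True,
            moves=[(emcee.moves.DEMove(), 0.9), (emcee.moves.DESnookerMove(), 0.1)],
        )
        sampler.random_state = np.random.RandomState(
            (config.seed * 1000003 + c) % (2**32)
        ).get_state()
        sampler.run_mcmc(p0, total, progress=False, skip_initial_state_check=True)
        raw = sampler.get_chain(discard=config.tune, thin=config.thin)  # (S, W, D)
        # Flatten one ensemble step-major (the usual emcee convention).
        chains.append(raw.reshape(raw.shape[0] * nwalkers, ndim))
        accepts.append(float(np.mean(sampler.acceptance_fraction)))
    return np.stack(chains), accepts


def sample_posterior(
    model: HierarchicalModel, config: SamplerConfig | None = None, *, stage: str = ""
) -> PosteriorFit:
    """Draw posterior samples and attach convergence diagnostics.

    Runs ``config.chains`` independent walker ensembles, each initialised
    near the prior centers with its own sub-seed, tuned for ``config.tune``
    steps, then run until ``draws`` thinned draws per chain are retained.
    Split R-hat and effective sample size are computed across the
    independent chains; exceeding the R-hat gate or falling under the
    acceptance-fraction floor raises a flag on the returned fit (the
    ensemble sampler has no divergences; these gates play that role).
    Identical seeds give identical draws.
    """
    config = config or SamplerConfig()
    log.info(
        "sampling %s: ndim=%d chains=%d", model.family.value, model.ndim, config.chains
    )
    chain, accepts = sample_ensemble_chains(
        model.log_prob_batch, model.initial_points, model.ndim, config
    )
    named = model.named_draws(chain, rng=np.random.default_rng([config.seed, 997]))
    dims = {
        k: ["fish"]
        for k, v in named.items()
        if v.ndim == 3
    }
    idata = az.from_dict(
        posterior=named, coords={"fish": model.fish_ids}, dims=dims
    )
    accept = float(np.mean(accepts))
    pop_vars = [k for k in named if k.startswith("pop_")] + (
        ["nu"] if model.has_nu else []
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rhat_max = float(max(rhat[v].max() for v in pop_vars))
    ess_min = float(min(ess[v].min() for v in pop_vars))
    flags = []
    if rhat_max > config.target_rhat:
        flags.append(f"rhat {rhat_max:.3f} > {config.target_rhat}")
    if accept < config.min_acceptance:
        flags.append(f"acceptance fraction {accept:.3f} below {config.min_acceptance}")
    diagnostics = dict(
        rhat_max=rhat_max,
        ess_min=ess_min,
        acceptance_fraction=accept,
        divergences=0,
        n_draws=int(chain.shape[0] * chain.shape[1]),
    )
    if flags:
        log.warning("fit flagged: %s", "; ".join(flags))
    return PosteriorFit(
        idata=idata,
        family=model.family,
        fish_ids=model.fish_ids,
        stage=stage,
        config=config,
        diagnostics=diagnostics,
        flags=flags,
    )


def sample_observations(
    family: MeasureFamily,
    fish_params: list[LearningCurveParams],
    ses: np.ndarray,
    fish_idx: np.ndarray,
    rng: np.random.Generator,
    *,
    clip_success: bool = True,
) -> np.ndarray:
    """Draw one replicated dataset at the observation design points."""
    family = MeasureFamily(family)
    ses = np.asarray(ses, float)
    fish_idx = np.asarray(fish_idx, int)
    mu = np.empty_like(ses)
    sd = np.empty_like(ses)
    for i, p in enumerate(fish_params):
        mask = fish_idx == i
        if not mask.any():
            continue
        mu[mask] = curve_mean(p, ses[mask])
        if family.has_dispersion:
            sd[mask] = curve_sd(p, ses[mask])
    if family is MeasureFamily.SUCCESS_POISSON:
        mu = np.clip(mu, 1e-6, None)
        y = rng.poisson(mu).astype(float)
        return np.minimum(y, 6.0) if clip_success else y
    if family is MeasureFamily.ANGULAR_STUDENT_T:
        nu = fish_params[0].nu
        return mu + sd * rng.standard_t(nu, size=mu.shape)
    mu = np.clip(mu, 1e-6, None)
    shape, rate = gamma_mode_sd_to_shape_rate(mu, sd)
    return rng.gamma(shape, 1.0 / rate)


def prior_predictive(model: HierarchicalModel, n_draws: int = 200, seed: int = 0) -> dict:
    """Datasets simulated from the prior, with a plausibility summary.

    Each draw samples population hyperparameters from their priors,
    fish-level parameters from the population, and observations from the
    likelihood at the model's design points.  The summary reports the range
    of simulated data and of the implied session-0 curve values, the
    quantities one inspects when tuning priors to cover all reasonable
    datasets and exclude pathological ones.
    """
    rng = np.random.default_rng(seed)
    h = model.hierarchy
    datasets, mu0s = [], []
    for _ in range(n_draws):
        theta = np.empty(model.ndim)
        m = model._c + model._w * rng.standard_normal(3)
        ls = model._ls0 + h.pop_sd_log_width * rng.standard_normal(3)
        if model._im is not None:
            theta[model._im] = m
        theta[model._ils] = ls
        z = rng.standard_normal((3, model.n_fish))
        if model.parameterization == "non-centered":
            theta[model._iz] = z.ravel()
        else:
            theta[model._iz] = (m[:, None] + np.exp(ls)[:, None] * z).ravel()
        if model.has_dispersion:
            theta[model._idisp] = h.log_A_sigma_center + h.dispersion_width * rng.standard_normal()
            theta[model._idisp + 1] = (
                h.log_sigma_inf_center + h.dispersion_width * rng.standard_normal()
            )
        if model.has_nu:
            theta[model._idisp + 2] = np.log(rng.exponential(h.nu_prior_mean) + 1.05)
        params = model.fish_params_from_point(theta)
        if model.family.positive_mean and any(
            curve_mean(p, s) <= 0 for p in params for s in (0.0, float(model.ses.max()))
        ):
            continue  # prior draw outside the likelihood's support
        mu0s.append(np.mean([curve_mean(p, 0.0) for p in params]))
        datasets.append(
            sample_observations(model.family, params, model.ses, model.fish_idx, rng)
        )
    stacked = np.asarray(datasets)
    return dict(
        datasets=stacked,
        mu0_mean=float(np.mean(mu0s)),
        data_min=float(stacked.min()),
        data_max=float(stacked.max()),
        n_kept=len(datasets),
    )


def posterior_predictive(
    fit: PosteriorFit, model: HierarchicalModel, *, n_rep: int = 200, seed: int = 0
) -> dict:
    """Replicated datasets from the posterior and session-median coverage.

    For each (fish, session) cell, checks whether the observed median of the
    measure falls inside the central 94% interval of the replicated
    medians.  Well-specified data should give coverage near 0.94; clearly
    lower coverage flags misspecification.
    """
    rng = np.random.default_rng(seed)
    post = fit.idata.posterior
    C, D = post.sizes["chain"], post.sizes["draw"]
    idx = rng.integers(0, C * D, size=n_rep)
    A = fit.draws("A_mu")
    tau = fit.draws("tau_mu")
    mu_inf = fit.draws("mu_inf")
    A_sig = fit.draws("A_sigma") if model.has_dispersion else None
    sig_inf = fit.draws("sigma_inf") if model.has_dispersion else None
    nu = fit.draws("nu") if model.has_nu else None
    reps = np.empty((n_rep, len(model.y)))
    for r, i in enumerate(idx):
        params = [
            LearningCurveParams(
                A_mu=float(A[i, f]),
                tau_mu=float(tau[i, f]),
                mu_inf=float(max(mu_inf[i, f], 1e-6))
                if model.family.positive_mean
                else float(mu_inf[i, f]),
                A_sigma=float(A_sig[i]) if model.has_dispersion else 0.0,
                sigma_inf=float(sig_inf[i]) if model.has_dispersion else 1.0,
                nu=float(nu[i]) if model.has_nu else 30.0,
            )
            for f in range(model.n_fish)
        ]
        reps[r] = sample_observations(model.family, params, model.ses, model.fish_idx, rng)

    cells = {}
    for j, (f, s) in enumerate(zip(model.fish_idx, model.ses)):
        cells.setdefault((int(f), float(s)), []).append(j)
    records, covered = [], 0
    for (f, s), js in cells.items():
        obs_med = float(np.median(model.y[js]))
        rep_med = np.median(reps[:, js], axis=1)
        lo, hi = np.quantile(rep_med, [0.03, 0.97])
        inside = bool(lo <= obs_med <= hi)
        covered += inside
        records.append(dict(fish=f, session=s, observed=obs_med, lo=lo, hi=hi, inside=inside))
    coverage = covered / len(cells)
    return dict(replicates=reps, coverage=float(coverage), table=pd.DataFrame(records))
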
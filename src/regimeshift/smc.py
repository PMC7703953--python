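"""Sequential Monte Carlo posterior inference for one Gaussian regime.

The observation model within a regime is Normal(mu, sigma).  The particle
machinery is prior-agnostic: any parameter prior exposing sampling, a
density over (mu, log sigma) and a prior predictive can drive it.  The
analysis prior is the uniform box on (mu, sigma) — or on (mu, sigma^2) —
for which no conjugate shortcut exists; the normal-gamma prior is also
provided so the particle filter can be cross-checked against its exact
conjugate counterpart.

Weight degeneracy is controlled by systematic resampling followed by a
random-walk Metropolis move step on (mu, log sigma) targeting the
within-regime posterior, computed from the regime's sufficient statistics
so a move sweep costs O(particles) regardless of regime length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, ndtr

from . import conjugate as _cj

__all__ = [
    "SMCSettings",
    "UniformPriorBounds",
    "UniformBoxPrior",
    "NormalGammaParameterPrior",
    "ParticleSet",
    "DegenerateUpdateWarning",
    "normal_density",
    "predictive_density",
    "smc_update",
    "fit_posterior",
    "predictive_interval",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class DegenerateUpdateWarning(UserWarning):
    """All particles were inconsistent with an observation."""


def _normal_logpdf(y: float, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    z = (y - mu) / sigma
    return -_LOG_SQRT_2PI - np.log(sigma) - 0.5 * z * z


def normal_density(y: float, mu: float, sigma: float) -> float:
    """Gaussian observation density N(y; mu, sigma)."""
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return float(np.exp(_normal_logpdf(float(y), np.float64(mu), np.float64(sigma))))


@dataclass(frozen=True)
class UniformPriorBounds:
    """Uniform box prior bounds for the regime parameters.

    ``mu_low < mu_high`` bound the mean; ``0 < s_low < s_high`` bound the
    standard deviation (always expressed on the sigma scale, even when the
    prior is taken uniform in the variance).
    """

    mu_low: float
    mu_high: float
    s_low: float
    s_high: float

    def __post_init__(self) -> None:
        if not self.mu_low < self.mu_high:
            raise ValueError("mu_low must be < mu_high")
        if not 0 < self.s_low < self.s_high:
            raise ValueError("need 0 < s_low < s_high")

    @classmethod
    def from_data(cls, values: np.ndarray) -> "UniformPriorBounds":
        """Default bounds wide enough to contain all plausible parameters.

        mu spans the data range extended by one full range on each side;
        sigma spans (range/1000, 3*range].  Degenerate (constant) data fall
        back to a unit range.
        """
        values = np.asarray(values, dtype=float)
        lo, hi = float(np.min(values)), float(np.max(values))
        rng = hi - lo
        if rng <= 0:
            rng = max(abs(hi), 1.0)
        return cls(lo - rng, hi + rng, rng / 1000.0, 3.0 * rng)

    def contains(self, values: np.ndarray) -> bool:
        return bool(np.all(values >= self.mu_low) and np.all(values <= self.mu_high))


class UniformBoxPrior:
    """Uniform parameter prior on the box, on the sigma or variance scale.

    The prior predictive — the emission for a fresh-regime hypothesis —
    integrates mu analytically (a difference of Gaussian CDFs) and the
    remaining one-dimensional sigma integral by Gauss-Legendre quadrature,
    so the shift hypothesis is scored without Monte Carlo noise.
    """

    def __init__(
        self,
        bounds: UniformPriorBounds,
        sigma_prior: str = "sd",
        n_quad_nodes: int = 256,
    ) -> None:
        if sigma_prior not in ("sd", "var"):
            raise ValueError("sigma_prior must be 'sd' or 'var'")
        self.bounds = bounds
        self.sigma_prior = sigma_prior
        x, w = np.polynomial.legendre.leggauss(n_quad_nodes)
        sl, sh = bounds.s_low, bounds.s_high
        self._qsigma = 0.5 * (sh - sl) * x + 0.5 * (sh + sl)
        quad_w = 0.5 * (sh - sl) * w
        if sigma_prior == "var":
            dens = 2.0 * self._qsigma / (sh**2 - sl**2)
        else:
            dens = np.full_like(self._qsigma, 1.0 / (sh - sl))
        self._qweights = quad_w * dens / (bounds.mu_high - bounds.mu_low)

    def sample(
        self, n: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        b = self.bounds
        mus = rng.uniform(b.mu_low, b.mu_high, n)
        if self.sigma_prior == "var":
            sigmas = np.sqrt(rng.uniform(b.s_low**2, b.s_high**2, n))
        else:
            sigmas = rng.uniform(b.s_low, b.s_high, n)
        return mus, sigmas

    def log_density(self, mus: np.ndarray, log_sigmas: np.ndarray) -> np.ndarray:
        """Unnormalized log prior density over the (mu, log sigma) plane."""
        b = self.bounds
        sigmas = np.exp(log_sigmas)
        # Jacobian sigma, plus one extra sigma when uniform in the variance
        logp = log_sigmas if self.sigma_prior == "sd" else 2.0 * log_sigmas
        logp = logp.copy()
        out = (
            (mus < b.mu_low)
            | (mus > b.mu_high)
            | (sigmas < b.s_low)
            | (sigmas > b.s_high)
        )
        logp[out] = -np.inf
        return logp

    def log_prior_predictive(self, y: float) -> float:
        b = self.bounds
        upper = ndtr((b.mu_high - y) / self._qsigma)
        lower = ndtr((b.mu_low - y) / self._qsigma)
        val = float(np.sum(self._qweights * (upper - lower)))
        return float(np.log(val)) if val > 0 else -np.inf


class NormalGammaParameterPrior:
    """Normal-gamma prior driving the particle machinery.

    Exists so the particle filter can be run with exactly the prior of the
    closed-form conjugate filter and validated against it; the prior
    predictive is the closed-form Student-t.
    """

    def __init__(self, ng: "_cj.NormalGammaPrior") -> None:
        self.ng = ng

    def sample(
        self, n: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        ng = self.ng
        precisions = rng.gamma(ng.alpha0, 1.0 / ng.beta0, n)
        variances = 1.0 / precisions
        mus = rng.normal(ng.m0, np.sqrt(variances / ng.kappa0))
        return mus, np.sqrt(variances)

    def log_density(self, mus: np.ndarray, log_sigmas: np.ndarray) -> np.ndarray:
        ng = self.ng
        sigmas2 = np.exp(2.0 * log_sigmas)
        # inverse-gamma over sigma^2, then Jacobians to (mu, log sigma)
        log_iv = (
            ng.alpha0 * np.log(ng.beta0)
            - _gammaln(ng.alpha0)
            - (ng.alpha0 + 1.0) * np.log(sigmas2)
            - ng.beta0 / sigmas2
        )
        log_mu = (
            -_LOG_SQRT_2PI
            - 0.5 * np.log(sigmas2 / ng.kappa0)
            - 0.5 * ng.kappa0 * (mus - ng.m0) ** 2 / sigmas2
        )
        return log_iv + log_mu + np.log(2.0) + 2.0 * log_sigmas

    def log_prior_predictive(self, y: float) -> float:
        return _cj.log_predictive(y, self.ng)


def _gammaln(x):
    from scipy.special import gammaln

    return gammaln(x)


def _as_parameter_prior(prior, sigma_prior: str = "sd"):
    if isinstance(prior, UniformPriorBounds):
        return UniformBoxPrior(prior, sigma_prior)
    if isinstance(prior, _cj.NormalGammaPrior):
        return NormalGammaParameterPrior(prior)
    return prior


@dataclass(frozen=True)
class SMCSettings:
    """Tuning knobs for the particle machinery.

    n_particles
        Cloud size; 100,000 for analysis runs, a few thousand is plenty
        for unit tests.
    ess_fraction
        Resample-move triggers when ESS < ess_fraction * n_particles.
    n_move
        Random-walk Metropolis sweeps per rejuvenation.
    move_scale
        Proposal standard deviation as a multiple of the current particle
        spread, per coordinate.
    sigma_prior
        "sd" places the uniform prior on sigma, "var" on sigma^2 (only
        relevant for the uniform box prior).
    """

    n_particles: int = 100_000
    ess_fraction: float = 0.5
    n_move: int = 5
    move_scale: float = 0.5
    sigma_prior: str = "sd"

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if self.sigma_prior not in ("sd", "var"):
            raise ValueError("sigma_prior must be 'sd' or 'var'")


@dataclass
class ParticleSet:
    """Weighted sample of (mu, sigma) for one run-length hypothesis.

    ``log_weights`` are kept normalized (logsumexp == 0).  ``n_obs``,
    ``sum_y`` and ``sum_y2`` are the sufficient statistics of the
    observations the cloud is conditioned on; they drive the move step.
    """

    mus: np.ndarray
    sigmas: np.ndarray
    log_weights: np.ndarray
    prior: object
    n_obs: int = 0
    sum_y: float = 0.0
    sum_y2: float = 0.0

    @property
    def n_particles(self) -> int:
        return len(self.mus)

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_weights)

    @classmethod
    def from_prior(
        cls,
        prior,
        n_particles: int,
        rng: np.random.Generator,
        sigma_prior: str = "sd",
    ) -> "ParticleSet":
        prior = _as_parameter_prior(prior, sigma_prior)
        mus, sigmas = prior.sample(n_particles, rng)
        logw = np.full(n_particles, -np.log(n_particles))
        return cls(mus, sigmas, logw, prior)

    def ess(self) -> float:
        """Effective sample size 1 / sum(w_i^2)."""
        return float(np.exp(-logsumexp(2.0 * self.log_weights)))

    def posterior_mean_mu(self) -> float:
        return float(np.sum(self.weights * self.mus))

    def posterior_mean_sigma(self) -> float:
        return float(np.sum(self.weights * self.sigmas))


def predictive_density(ps: ParticleSet, y: float) -> float:
    """Posterior predictive density of a new observation.

    The weighted particle average of the Gaussian observation density;
    converges to the exact predictive as the cloud grows.
    """
    log_w = ps.log_weights
    if not np.any(np.isfinite(log_w)):
        raise ValueError("degenerate particle set: all weights are zero")
    return float(np.exp(logsumexp(log_w + _normal_logpdf(float(y), ps.mus, ps.sigmas))))


def _log_target(ps: ParticleSet, mus: np.ndarray, log_sigmas: np.ndarray) -> np.ndarray:
    """Log within-regime posterior over (mu, log sigma), up to a constant."""
    sigmas2 = np.exp(2.0 * log_sigmas)
    quad = ps.sum_y2 - 2.0 * mus * ps.sum_y + ps.n_obs * mus * mus
    loglik = -ps.n_obs * (_LOG_SQRT_2PI + log_sigmas) - 0.5 * quad / sigmas2
    return loglik + ps.prior.log_density(mus, log_sigmas)


def _systematic_resample(
    log_weights: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n = len(log_weights)
    w = np.exp(log_weights - logsumexp(log_weights))
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(w), positions).clip(max=n - 1)


def _move(ps: ParticleSet, settings: SMCSettings, rng: np.random.Generator) -> int:
    """Random-walk Metropolis rejuvenation after resampling; returns accepts."""
    mus, logsig = ps.mus, np.log(ps.sigmas)
    scale_mu = max(float(np.std(mus)), 1e-12) * settings.move_scale
    scale_ls = max(float(np.std(logsig)), 1e-12) * settings.move_scale
    logp = _log_target(ps, mus, logsig)
    n_accept = 0
    for _ in range(settings.n_move):
        prop_mu = mus + scale_mu * rng.standard_normal(len(mus))
        prop_ls = logsig + scale_ls * rng.standard_normal(len(mus))
        logp_prop = _log_target(ps, prop_mu, prop_ls)
        with np.errstate(invalid="ignore"):
            accept = np.log(rng.random(len(mus))) < (logp_prop - logp)
        mus[accept] = prop_mu[accept]
        logsig[accept] = prop_ls[accept]
        logp[accept] = logp_prop[accept]
        n_accept += int(np.sum(accept))
    ps.mus, ps.sigmas = mus, np.exp(logsig)
    return n_accept


def smc_update(
    ps: ParticleSet,
    y: float,
    settings: SMCSettings,
    rng: np.random.Generator,
    loglik: np.ndarray | None = None,
) -> tuple[float, bool]:
    """Assimilate one observation in place.

    Reweights by the per-particle likelihood of ``y``, renormalizes, and —
    when the effective sample size drops below the threshold — resamples
    systematically and rejuvenates with Metropolis moves.  ``loglik`` may
    carry precomputed per-particle log likelihoods of ``y`` (the
    run-length filter computes them once for the emission and reuses them
    here).

    Returns
    -------
    log_predictive : float
        Log of the predictive density of ``y`` under the cloud *before*
        assimilation (the run-length filter's emission term).
    resampled : bool
        Whether a resample-move step was triggered.
    """
    y = float(y)
    if loglik is None:
        loglik = _normal_logpdf(y, ps.mus, ps.sigmas)
    joint = ps.log_weights + loglik
    log_pred = float(logsumexp(joint))
    if not np.isfinite(log_pred):
        warnings.warn(
            "all particles inconsistent with the observation; "
            "reinitializing from the prior",
            DegenerateUpdateWarning,
            stacklevel=2,
        )
        mus, sigmas = ps.prior.sample(ps.n_particles, rng)
        ps.mus, ps.sigmas = mus, sigmas
        ps.log_weights = np.full(ps.n_particles, -np.log(ps.n_particles))
        ps.n_obs, ps.sum_y, ps.sum_y2 = 0, 0.0, 0.0
        joint = ps.log_weights + _normal_logpdf(y, ps.mus, ps.sigmas)
        log_pred = float(logsumexp(joint))
        if not np.isfinite(log_pred):
            # observation impossible under the prior itself: keep the fresh
            # equal-weight cloud and skip assimilating this point
            return log_pred, False
    ps.log_weights = joint - logsumexp(joint)
    ps.n_obs += 1
    ps.sum_y += y
    ps.sum_y2 += y * y
    resampled = False
    if ps.ess() < settings.ess_fraction * ps.n_particles:
        idx = _systematic_resample(ps.log_weights, rng)
        ps.mus = ps.mus[idx].copy()
        ps.sigmas = ps.sigmas[idx].copy()
        ps.log_weights = np.full(ps.n_particles, -np.log(ps.n_particles))
        _move(ps, settings, rng)
        resampled = True
    return log_pred, resampled


def fit_posterior(
    values: np.ndarray,
    prior,
    settings: SMCSettings,
    rng: np.random.Generator,
) -> ParticleSet:
    """Particle posterior of (mu, sigma) for one block of observations.

    ``prior`` may be :class:`UniformPriorBounds` (wrapped as a uniform box
    prior on the scale set by ``settings.sigma_prior``), a
    :class:`~regimeshift.conjugate.NormalGammaPrior`, or any parameter
    prior object.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot fit a posterior to zero observations")
    ps = ParticleSet.from_prior(
        prior, settings.n_particles, rng, settings.sigma_prior
    )
    for y in values:
        smc_update(ps, y, settings, rng)
    return ps


def predictive_interval(ps: ParticleSet, level: float = 0.68) -> tuple[float, float]:
    """Central probability interval of the posterior predictive distribution.

    The predictive is the weighted Gaussian mixture over particles; its
    quantiles are found by bisection on the mixture CDF, so the interval is
    deterministic given the particle cloud.
    """
    from scipy.optimize import brentq

    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    w = ps.weights
    keep = w > 0
    w, mus, sigmas = w[keep], ps.mus[keep], ps.sigmas[keep]

    def cdf(x: float) -> float:
        return float(np.sum(w * ndtr((x - mus) / sigmas)))

    lo_q, hi_q = 0.5 - level / 2.0, 0.5 + level / 2.0
    span = float(np.max(sigmas)) * 40.0 + 1.0
    a = float(np.min(mus)) - span
    b = float(np.max(mus)) + span
    lo = brentq(lambda x: cdf(x) - lo_q, a, b)
    hi = brentq(lambda x: cdf(x) - hi_q, a, b)
    return float(lo), float(hi)
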
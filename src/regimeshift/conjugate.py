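"""Normal-gamma conjugate observation model.

With a normal-gamma prior on (mu, precision) the within-regime posterior
and the posterior predictive (a Student-t) are closed-form, so the
run-length filter becomes fully deterministic.  The package uses this
variant as an exact oracle for the particle implementation and for
enumeration cross-checks; it is also available directly through the
filtering API.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "NormalGammaPrior",
    "posterior_params",
    "log_predictive",
    "log_marginal_likelihood",
]


@dataclass(frozen=True)
class NormalGammaPrior:
    """Hyperparameters (m0, kappa0, alpha0, beta0).

    mu | sigma^2 ~ Normal(m0, sigma^2 / kappa0) and
    1/sigma^2 ~ Gamma(alpha0, rate=beta0).
    """

    m0: float = 0.0
    kappa0: float = 1.0
    alpha0: float = 1.0
    beta0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.kappa0 > 0 and self.alpha0 > 0 and self.beta0 > 0):
            raise ValueError("kappa0, alpha0, beta0 must all be positive")

    @classmethod
    def diffuse_matched_to(cls, bounds, sigma_star: float | None = None) -> "NormalGammaPrior":
        """Density-match a diffuse normal-gamma prior to a uniform box.

        The block marginal likelihoods of the two priors agree (by Laplace
        approximation) wherever their prior densities agree, so the
        normal-gamma density is pinned to the box's flat level at a
        representative scale ``sigma_star`` (default: the geometric mean of
        the sigma bounds): the implied sigma density peaks at sigma_star
        with height 1/(s_high - s_low), and the conditional mu density at
        its center equals 1/(mu_high - mu_low).  The match is necessarily
        local — a heavy-tailed conjugate prior cannot reproduce a compact
        box globally — which is why the particle filter is cross-checked
        against the conjugate filter at *identical* priors, not across
        priors.
        """
        from scipy.optimize import brentq

        sl, sh = bounds.s_low, bounds.s_high
        if sigma_star is None:
            sigma_star = float(np.sqrt(sl * sh))
        dmu = bounds.mu_high - bounds.mu_low
        kappa0 = 2.0 * np.pi * sigma_star**2 / dmu**2

        def sigma_density_peak(a: float) -> float:
            b = (2.0 * a + 1.0) * sigma_star**2 / 2.0
            return 2.0 * np.exp(
                a * np.log(b)
                - gammaln(a)
                - (2.0 * a + 1.0) * np.log(sigma_star)
                - b / sigma_star**2
            )

        alpha0 = brentq(
            lambda a: sigma_density_peak(a) - 1.0 / (sh - sl), 1e-4, 500.0
        )
        beta0 = (2.0 * alpha0 + 1.0) * sigma_star**2 / 2.0
        m0 = 0.5 * (bounds.mu_low + bounds.mu_high)
        return cls(m0, float(kappa0), float(alpha0), float(beta0))


def posterior_params(
    prior: NormalGammaPrior, n: int, sum_y: float, sum_y2: float
) -> tuple[float, float, float, float]:
    """Posterior (m, kappa, alpha, beta) from block sufficient statistics."""
    if n == 0:
        return prior.m0, prior.kappa0, prior.alpha0, prior.beta0
    ybar = sum_y / n
    ss = max(sum_y2 - n * ybar * ybar, 0.0)
    kappa = prior.kappa0 + n
    m = (prior.kappa0 * prior.m0 + sum_y) / kappa
    alpha = prior.alpha0 + 0.5 * n
    beta = prior.beta0 + 0.5 * ss + (
        prior.kappa0 * n * (ybar - prior.m0) ** 2 / (2.0 * kappa)
    )
    return m, kappa, alpha, beta


def _student_t_logpdf(y: float, df: float, loc: float, scale: float) -> float:
    z = (y - loc) / scale
    return float(
        gammaln((df + 1.0) / 2.0)
        - gammaln(df / 2.0)
        - 0.5 * np.log(df * np.pi)
        - np.log(scale)
        - (df + 1.0) / 2.0 * np.log1p(z * z / df)
    )


def log_predictive(
    y: float, prior: NormalGammaPrior, n: int = 0, sum_y: float = 0.0, sum_y2: float = 0.0
) -> float:
    """Log posterior predictive density of y after n observations.

    Student-t with 2*alpha_n degrees of freedom, location m_n and scale
    sqrt(beta_n (kappa_n + 1) / (alpha_n kappa_n)).
    """
    m, kappa, alpha, beta = posterior_params(prior, n, sum_y, sum_y2)
    scale = np.sqrt(beta * (kappa + 1.0) / (alpha * kappa))
    return _student_t_logpdf(float(y), 2.0 * alpha, m, scale)


def log_marginal_likelihood(values: np.ndarray, prior: NormalGammaPrior) -> float:
    """Exact log marginal likelihood of one regime's observations."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        return 0.0
    _, kappa_n, alpha_n, beta_n = posterior_params(
        prior, n, float(values.sum()), float((values**2).sum())
    )
    return float(
        gammaln(alpha_n)
        - gammaln(prior.alpha0)
        + prior.alpha0 * np.log(prior.beta0)
        - alpha_n * np.log(beta_n)
        + 0.5 * (np.log(prior.kappa0) - np.log(kappa_n))
        - 0.5 * n * np.log(2.0 * np.pi)
    )
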
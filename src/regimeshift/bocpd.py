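"""Bayesian online change-point detection: the run-length filter.

The run length r_t is the number of steps since the most recent regime
shift (r_t = 0 opens a fresh regime at time t).  With a constant-hazard
prior — shift probability 1/lambda per step — the filtered posterior
p(r_t | y_1:t) follows the recursion

    p(r_t | y_1:t)  ∝  sum_{r_{t-1}}  p(r_t | r_{t-1})
                        * p(y_t | last r_t observations)
                        * p(r_{t-1} | y_1:t-1),

where a hypothesis of run length r is scored by the predictive density of
y_t conditional on exactly the r preceding observations of its regime; the
shift hypothesis (r_t = 0) is scored by the prior predictive, which
dominates when no existing run explains the new observation.

Two underlying predictive models are provided: the particle (SMC)
implementation for uniform priors on (mu, sigma), and the normal-gamma
conjugate model whose Student-t predictives make the whole filter
deterministic — an exact oracle for the particle variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from . import conjugate as cj
from .conjugate import NormalGammaPrior
from .series import TimeSeries
from .smc import (
    ParticleSet,
    SMCSettings,
    UniformPriorBounds,
    _as_parameter_prior,
    _normal_logpdf,
    smc_update,
)

__all__ = [
    "HazardPrior",
    "hazard_transition",
    "RunLengthPosterior",
    "FilterStep",
    "filter_series",
    "conjugate_filter",
]


@dataclass(frozen=True)
class HazardPrior:
    """Constant change-point hazard: expected regime duration ``lam`` steps.

    The per-step prior shift probability is 1/lam; a run otherwise grows by
    one.  ``lam`` must exceed 1 so both probabilities lie in (0, 1).
    """

    lam: float

    def __post_init__(self) -> None:
        if not self.lam > 1:
            raise ValueError(f"hazard rate lambda must be > 1, got {self.lam}")

    @property
    def shift_prob(self) -> float:
        return 1.0 / self.lam

    @property
    def growth_prob(self) -> float:
        return 1.0 - 1.0 / self.lam


def hazard_transition(r_prev: int, hazard: HazardPrior) -> dict[str, float]:
    """Run-length transition probabilities from r_prev.

    Returns {"shift": p(r=0), "grow": p(r=r_prev+1), "other": 0.0}; the
    constant hazard makes this independent of ``r_prev``.
    """
    if r_prev < 0:
        raise ValueError("run length must be >= 0")
    return {"shift": hazard.shift_prob, "grow": hazard.growth_prob, "other": 0.0}


@dataclass
class FilterStep:
    """Per-step diagnostics recorded while filtering."""

    time: int
    log_evidence: float  # log p(y_t | y_1:t-1)
    n_hypotheses: int
    min_ess: float | None = None
    n_resampled: int = 0


@dataclass
class RunLengthPosterior:
    """Run-length distributions, filtered or smoothed, with ragged support.

    ``support[t]`` lists the retained run lengths at step t and
    ``probs[t]`` the matching probabilities (each row sums to one).
    ``log_emissions[t]`` holds the log predictive density of y_t for every
    *candidate* run length considered at step t (before pruning); the
    backward smoothing pass consumes these.
    """

    times: np.ndarray
    support: list[np.ndarray]
    probs: list[np.ndarray]
    log_emissions: list[tuple[np.ndarray, np.ndarray]]
    log_evidence: np.ndarray
    kind: str = "filtered"

    def __len__(self) -> int:
        return len(self.times)

    def prob(self, t_index: int, r: int) -> float:
        """p(r_t = r | data) at step ``t_index``; zero off the support."""
        idx = np.searchsorted(self.support[t_index], r)
        if idx < len(self.support[t_index]) and self.support[t_index][idx] == r:
            return float(self.probs[t_index][idx])
        return 0.0

    def map_run_length(self, t_index: int) -> int:
        return int(self.support[t_index][np.argmax(self.probs[t_index])])

    def to_frame(self):
        """Long-format (t, r, probability) table."""
        import pandas as pd

        rows = []
        for t, (rs, ps) in enumerate(zip(self.support, self.probs)):
            rows.append(
                pd.DataFrame(
                    {"time": self.times[t], "run_length": rs, "probability": ps}
                )
            )
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Predictive-model adapters for the shared recursion
# ---------------------------------------------------------------------------


class _SMCModel:
    def __init__(
        self,
        prior,
        settings: SMCSettings,
        rng: np.random.Generator,
    ) -> None:
        self.prior = _as_parameter_prior(prior, settings.sigma_prior)
        self.settings = settings
        self.rng = rng
        self.hypotheses: list[ParticleSet] = []
        self.last_resampled = 0
        self._ll_cache: list[np.ndarray] = []
        self._ll_y: float | None = None

    def log_pred_new(self, y: float) -> float:
        return self.prior.log_prior_predictive(y)

    def log_pred_grow(self, y: float) -> np.ndarray:
        # Per-particle likelihoods are cached and reused by `advance`.
        out = np.empty(len(self.hypotheses))
        self._ll_cache = []
        self._ll_y = y
        for i, ps in enumerate(self.hypotheses):
            ll = _normal_logpdf(y, ps.mus, ps.sigmas)
            self._ll_cache.append(ll)
            out[i] = logsumexp(ps.log_weights + ll)
        return out

    def advance(self, y: float, keep_new: bool, keep_grow: np.ndarray) -> None:
        self.last_resampled = 0
        cached = self._ll_cache if self._ll_y == y else [None] * len(self.hypotheses)
        survivors: list[ParticleSet] = []
        if keep_new:
            ps = ParticleSet.from_prior(
                self.prior, self.settings.n_particles, self.rng,
                self.settings.sigma_prior,
            )
            _, res = smc_update(ps, y, self.settings, self.rng)
            self.last_resampled += int(res)
            survivors.append(ps)
        for ps, keep, ll in zip(self.hypotheses, keep_grow, cached):
            if keep:
                _, res = smc_update(ps, y, self.settings, self.rng, loglik=ll)
                self.last_resampled += int(res)
                survivors.append(ps)
        self.hypotheses = survivors
        self._ll_cache, self._ll_y = [], None

    def min_ess(self) -> float | None:
        if not self.hypotheses:
            return None
        return min(ps.ess() for ps in self.hypotheses)


class _ConjugateModel:
    def __init__(self, prior: NormalGammaPrior) -> None:
        self.prior = prior
        self.stats: list[tuple[int, float, float]] = []  # (n, sum_y, sum_y2)

    def log_pred_new(self, y: float) -> float:
        return cj.log_predictive(y, self.prior)

    def log_pred_grow(self, y: float) -> np.ndarray:
        return np.array(
            [cj.log_predictive(y, self.prior, n, s1, s2) for n, s1, s2 in self.stats]
        )

    def advance(self, y: float, keep_new: bool, keep_grow: np.ndarray) -> None:
        survivors = []
        if keep_new:
            survivors.append((1, y, y * y))
        for (n, s1, s2), keep in zip(self.stats, keep_grow):
            if keep:
                survivors.append((n + 1, s1 + y, s2 + y * y))
        self.stats = survivors

    def min_ess(self) -> float | None:
        return None


def _run_filter(
    series: TimeSeries,
    hazard: HazardPrior,
    model,
    prune_threshold: float,
    allow_gaps: bool,
) -> tuple[RunLengthPosterior, list[FilterStep]]:
    if len(series) < 2:
        raise ValueError("need at least 2 observations to filter")
    if series.has_gaps and not allow_gaps:
        raise ValueError(
            "series has gaps in its time index; pass allow_gaps=True to treat "
            "observations as consecutive steps (hazard applies per observation)"
        )
    values = series.values
    log_h = np.log(hazard.shift_prob)
    log_g = np.log(hazard.growth_prob)

    support: list[np.ndarray] = []
    probs: list[np.ndarray] = []
    emissions: list[tuple[np.ndarray, np.ndarray]] = []
    log_evidence = np.empty(len(values))
    steps: list[FilterStep] = []

    # First observation opens the series' first regime: p(r_1 = 0) = 1.
    y0 = float(values[0])
    log_e0 = model.log_pred_new(y0)
    model.advance(y0, keep_new=True, keep_grow=np.empty(0, dtype=bool))
    support.append(np.array([0]))
    probs.append(np.array([1.0]))
    emissions.append((np.array([0]), np.array([log_e0])))
    log_evidence[0] = log_e0
    steps.append(
        FilterStep(int(series.times[0]), log_e0, 1, model.min_ess(),
                   getattr(model, "last_resampled", 0))
    )

    for t in range(1, len(values)):
        y = float(values[t])
        rs_prev, logp_prev = support[-1], np.log(probs[-1])
        log_e0 = model.log_pred_new(y)
        log_eg = model.log_pred_grow(y)
        cand_rs = np.concatenate(([0], rs_prev + 1))
        cand_loge = np.concatenate(([log_e0], log_eg))
        # shift collects mass from every previous hypothesis (sums to 1)
        cand_logw = np.concatenate(
            ([log_h + log_e0], log_g + log_eg + logp_prev)
        )
        log_z = float(logsumexp(cand_logw))
        if not np.isfinite(log_z):
            raise FloatingPointError(
                f"filter underflow at time {series.times[t]}"
            )
        p = np.exp(cand_logw - log_z)
        keep = p >= prune_threshold
        keep[np.argmax(p)] = True  # never prune everything
        p_kept = p[keep]
        p_kept = p_kept / p_kept.sum()
        model.advance(y, keep_new=bool(keep[0]), keep_grow=keep[1:])
        support.append(cand_rs[keep])
        probs.append(p_kept)
        emissions.append((cand_rs, cand_loge))
        log_evidence[t] = log_z
        steps.append(
            FilterStep(int(series.times[t]), log_z, int(keep.sum()),
                       model.min_ess(), getattr(model, "last_resampled", 0))
        )
    posterior = RunLengthPosterior(
        times=series.times.copy(),
        support=support,
        probs=probs,
        log_emissions=emissions,
        log_evidence=log_evidence,
        kind="filtered",
    )
    return posterior, steps


def filter_series(
    series: TimeSeries,
    hazard: HazardPrior,
    priors,
    settings: SMCSettings | None = None,
    rng: np.random.Generator | int | None = None,
    prune_threshold: float = 1e-12,
    allow_gaps: bool = False,
) -> tuple[RunLengthPosterior, list[FilterStep]]:
    """Particle-filter run-length posterior.

    Each retained run-length hypothesis carries its own particle cloud,
    conditioned on exactly the observations of its hypothesized regime.
    Hypotheses whose posterior mass falls below ``prune_threshold`` are
    dropped and the mass renormalized, keeping the cost near O(T * K).

    Parameters
    ----------
    series, hazard, priors
        Data, constant-hazard prior, and parameter prior:
        :class:`UniformPriorBounds` for the analysis default (a warning is
        issued if the data leave the mu bounds), a
        :class:`~regimeshift.conjugate.NormalGammaPrior` (useful for
        cross-checking against :func:`conjugate_filter`), or any parameter
        prior object.
    settings
        SMC tuning; defaults to :class:`SMCSettings` (100,000 particles).
    rng
        Seed or generator driving all randomness in the run.
    """
    settings = settings or SMCSettings()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if isinstance(priors, UniformPriorBounds) and not priors.contains(series.values):
        warnings.warn(
            f"series {series.label!r} leaves the prior mu bounds "
            f"[{priors.mu_low}, {priors.mu_high}]; consider wider bounds",
            stacklevel=2,
        )
    model = _SMCModel(priors, settings, rng)
    return _run_filter(series, hazard, model, prune_threshold, allow_gaps)


def conjugate_filter(
    series: TimeSeries,
    hazard: HazardPrior,
    ng_prior: NormalGammaPrior,
    prune_threshold: float = 0.0,
    allow_gaps: bool = False,
) -> RunLengthPosterior:
    """Deterministic run-length posterior under the normal-gamma model.

    Identical recursion to :func:`filter_series` with closed-form Student-t
    predictive densities; no pruning by default, so small instances can be
    compared against exhaustive enumeration at machine precision.
    """
    model = _ConjugateModel(ng_prior)
    posterior, _ = _run_filter(series, hazard, model, prune_threshold, allow_gaps)
    return posterior
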
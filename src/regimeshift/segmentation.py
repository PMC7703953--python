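"""Retrospective segmentation from run-length posteriors.

Filtering is online; for retrospective regime identification the filtered
run-length distributions are smoothed against all data by a backward pass
over the run-length chain, and the most likely set of regimes is the
segmentation maximizing the product of smoothed run-length probabilities,
found exactly by dynamic programming under a minimum-regime-length
constraint M (not applied to the first and last regimes, whose true start
and end may lie outside the observed window).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp

from .bocpd import HazardPrior, RunLengthPosterior
from .series import TimeSeries
from .smc import (
    ParticleSet,
    SMCSettings,
    UniformPriorBounds,
    fit_posterior,
    predictive_interval,
)

__all__ = [
    "SegmentationConstraints",
    "Regime",
    "Segmentation",
    "smooth_run_lengths",
    "map_segmentation",
    "regime_summaries",
]


@dataclass(frozen=True)
class SegmentationConstraints:
    """Minimum regime length M, optionally exempting the first/last regime."""

    min_len: int = 10
    exempt_first_last: bool = True

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


@dataclass(frozen=True)
class Regime:
    """One regime: inclusive time span plus posterior predictive summary.

    ``cpi68`` is the 68% central probability interval of the posterior
    predictive distribution (16th-84th percentiles), so it reflects
    uncertainty in both the mean and the variance.
    """

    start: int
    end: int
    post_mean_mu: float = np.nan
    post_mean_sigma: float = np.nan
    cpi68: tuple[float, float] = (np.nan, np.nan)
    n_obs: int = 0
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("regime start must be <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Segmentation:
    """Ordered, contiguous regimes covering the series exactly."""

    regimes: tuple[Regime, ...]
    objective: float = np.nan

    def __post_init__(self) -> None:
        object.__setattr__(self, "regimes", tuple(self.regimes))
        for a, b in zip(self.regimes, self.regimes[1:]):
            if b.start != a.end + 1 and b.start <= a.end:
                raise ValueError("regimes must be ordered and non-overlapping")

    @property
    def n_regimes(self) -> int:
        return len(self.regimes)

    @property
    def change_points(self) -> list[int]:
        """Start times of every regime after the first."""
        return [r.start for r in self.regimes[1:]]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "start": [r.start for r in self.regimes],
                "end": [r.end for r in self.regimes],
                "length": [r.length for r in self.regimes],
                "post_mean_mu": [r.post_mean_mu for r in self.regimes],
                "post_mean_sigma": [r.post_mean_sigma for r in self.regimes],
                "cpi68_lo": [r.cpi68[0] for r in self.regimes],
                "cpi68_hi": [r.cpi68[1] for r in self.regimes],
            }
        )


def smooth_run_lengths(
    filtered: RunLengthPosterior, hazard: HazardPrior
) -> RunLengthPosterior:
    """Smoothed run-length probabilities p(r_t | y_1:T).

    Given the data, the run-length process is a Markov chain with the
    constant-hazard transition and an emission at step t that depends only
    on (t, r_t): the predictive density of y_t conditional on the previous
    r_t observations.  A standard backward pass over that chain, combined
    with the forward (filtered) distributions, yields the smoothed
    marginals; for the conjugate model the result is exact.  Emissions are
    the ones cached during filtering (no re-simulation).
    """
    T = len(filtered)
    log_h = np.log(hazard.shift_prob)
    log_g = np.log(hazard.growth_prob)
    log_beta: list[np.ndarray] = [np.zeros(0)] * T
    log_beta[T - 1] = np.zeros(len(filtered.support[T - 1]))
    for t in range(T - 2, -1, -1):
        rs = filtered.support[t]
        rs_next = filtered.support[t + 1]
        cand_rs, cand_loge = filtered.log_emissions[t + 1]

        def _lookup(target: np.ndarray, table_rs: np.ndarray, table_v: np.ndarray):
            idx = np.searchsorted(table_rs, target)
            ok = (idx < len(table_rs)) & (table_rs[np.minimum(idx, len(table_rs) - 1)] == target)
            out = np.full(len(target), -np.inf)
            out[ok] = table_v[idx[ok]]
            return out

        grow_e = _lookup(rs + 1, cand_rs, cand_loge)
        grow_b = _lookup(rs + 1, rs_next, log_beta[t + 1])
        shift_e = _lookup(np.array([0]), cand_rs, cand_loge)[0]
        shift_b = _lookup(np.array([0]), rs_next, log_beta[t + 1])[0]
        log_beta[t] = np.logaddexp(
            log_g + grow_e + grow_b, log_h + shift_e + shift_b
        )
    smoothed_probs = []
    with np.errstate(divide="ignore"):
        for t in range(T):
            logp = np.log(filtered.probs[t]) + log_beta[t]
            logp -= logsumexp(logp)
            smoothed_probs.append(np.exp(logp))
    return RunLengthPosterior(
        times=filtered.times,
        support=filtered.support,
        probs=smoothed_probs,
        log_emissions=filtered.log_emissions,
        log_evidence=filtered.log_evidence,
        kind="smoothed",
    )


def map_segmentation(
    smoothed: RunLengthPosterior, constraints: SegmentationConstraints
) -> Segmentation:
    """Most likely set of regimes under the minimum-length constraint.

    Maximizes ``sum_t log p(r_t = t - start_of_regime(t) | y_1:T)`` over
    all segmentations whose interior regimes span at least ``min_len``
    steps (first/last exempt when ``exempt_first_last``).  Solved exactly
    by dynamic programming over change-point positions; ties break toward
    the earlier change point.
    """
    T = len(smoothed)
    M = constraints.min_len
    # dense log-prob table; -inf off the retained support
    with np.errstate(divide="ignore"):
        dense = np.full((T, T), -np.inf)
        for t in range(T):
            dense[t, smoothed.support[t]] = np.log(
                np.maximum(smoothed.probs[t], 0.0)
            )
    # C[a, b] = score of a regime spanning positions a..b inclusive
    C = np.full((T, T), -np.inf)
    for a in range(T):
        diag = dense[a:, : T - a][np.arange(T - a), np.arange(T - a)]
        C[a, a:] = np.cumsum(diag)

    NEG = -np.inf
    best = np.full(T + 1, NEG)  # best[j]: positions 0..j-1 covered, regime starts at j
    prev = np.full(T + 1, -1, dtype=int)
    best[0] = 0.0
    for j in range(1, T):
        for i in range(j):
            length = j - i
            interior_ok = length >= M or (i == 0 and constraints.exempt_first_last)
            if not interior_ok:
                continue
            if best[i] == NEG:
                continue
            score = best[i] + C[i, j - 1]
            if score > best[j]:
                best[j] = score
                prev[j] = i
    # close with the final regime [i, T-1] (exempt from M if allowed)
    final_score, final_i = NEG, -1
    for i in range(T):
        if best[i] == NEG:
            continue
        length = T - i
        if length < M and not constraints.exempt_first_last:
            continue
        score = best[i] + C[i, T - 1]
        if score > final_score:
            final_score, final_i = score, i
    if not np.isfinite(final_score):
        raise ValueError(
            "no segmentation has positive probability under the constraints; "
            "try a smaller minimum regime length M or a different hazard rate"
        )
    starts = [final_i]
    while starts[-1] > 0:
        starts.append(int(prev[starts[-1]]))
    starts = starts[::-1]
    bounds_pos = starts + [T]
    times = smoothed.times
    regimes = tuple(
        Regime(start=int(times[a]), end=int(times[b - 1]), n_obs=b - a)
        for a, b in zip(bounds_pos[:-1], bounds_pos[1:])
    )
    return Segmentation(regimes=regimes, objective=float(final_score))


def regime_summaries(
    series: TimeSeries,
    seg: Segmentation,
    priors: UniformPriorBounds,
    settings: SMCSettings | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[Regime]:
    """Posterior predictive mean and 68% CPI for each regime.

    Refits the (mu, sigma) posterior on each regime's own observations
    with the same uniform priors, then summarizes the posterior predictive
    mixture: ``post_mean_mu`` is the predictive mean and ``cpi68`` its
    16th-84th percentile interval.  Regimes with fewer than two
    observations are summarized anyway but flagged ``low_confidence``.
    """
    settings = settings or SMCSettings()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = []
    for reg in seg.regimes:
        sub = series.slice_times(reg.start, reg.end)
        ps = fit_posterior(sub.values, priors, settings, rng)
        lo, hi = predictive_interval(ps, 0.68)
        out.append(
            replace(
                reg,
                post_mean_mu=ps.posterior_mean_mu(),
                post_mean_sigma=ps.posterior_mean_sigma(),
                cpi68=(lo, hi),
                n_obs=len(sub),
                low_confidence=len(sub) < 2,
            )
        )
    return out
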
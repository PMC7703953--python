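"""Brute-force segmentation posteriors for small series.

Under the constant-hazard prior, a segmentation of T points is a subset of
the positions 2..T at which a new regime starts; its prior probability is
the product of per-step shift/growth terms and its likelihood the product
of per-regime marginal likelihoods.  For the conjugate model these are
closed-form, so every posterior quantity the filter or smoother produces
can be recomputed by explicit summation over all 2^(T-1) segmentations.
Used as an independent oracle in tests and validation; feasible up to
T around 15.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.special import logsumexp

from scipy.special import ndtr

from .bocpd import HazardPrior, RunLengthPosterior, _run_filter
from .conjugate import NormalGammaPrior, log_marginal_likelihood
from .segmentation import SegmentationConstraints
from .series import TimeSeries
from .smc import UniformPriorBounds

__all__ = [
    "enumerate_log_joint",
    "enumerate_filtered",
    "enumerate_smoothed",
    "brute_force_map_segmentation",
    "quadrature_uniform_filter",
]


def _block_loglik(values: np.ndarray, prior: NormalGammaPrior) -> np.ndarray:
    """L[i, j] = log marginal likelihood of the block values[i..j]."""
    n = len(values)
    L = np.full((n, n), -np.inf)
    for i in range(n):
        for j in range(i, n):
            L[i, j] = log_marginal_likelihood(values[i : j + 1], prior)
    return L


def _segmentations(n: int):
    """All change-point position sets (0-based starts of later regimes)."""
    positions = range(1, n)
    for k in range(n):
        yield from combinations(positions, k)


def enumerate_log_joint(
    values: np.ndarray, hazard: HazardPrior, prior: NormalGammaPrior
) -> dict[tuple[int, ...], float]:
    """log p(segmentation, y_1:n) for every segmentation."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    L = _block_loglik(values, prior)
    log_h, log_g = np.log(hazard.shift_prob), np.log(hazard.growth_prob)
    out: dict[tuple[int, ...], float] = {}
    for cps in _segmentations(n):
        starts = (0,) + cps
        ends = cps + (n,)
        log_prior = len(cps) * log_h + (n - 1 - len(cps)) * log_g
        loglik = sum(L[a, b - 1] for a, b in zip(starts, ends))
        out[cps] = log_prior + loglik
    return out


def _run_lengths(cps: tuple[int, ...], n: int) -> np.ndarray:
    """Run length at each position implied by a change-point set."""
    r = np.empty(n, dtype=int)
    start = 0
    for t in range(n):
        if t in cps:
            start = t
        r[t] = t - start
    return r


def enumerate_filtered(
    values: np.ndarray, hazard: HazardPrior, prior: NormalGammaPrior
) -> list[np.ndarray]:
    """p(r_t = r | y_1:t) for every t, by enumerating prefix segmentations.

    Returns a list of length-n arrays; entry t has length t+1 with the
    probability of each run length 0..t.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    rows = []
    for t in range(1, n + 1):
        joint = enumerate_log_joint(values[:t], hazard, prior)
        mass = np.full(t, -np.inf)
        for cps, logp in joint.items():
            r_last = _run_lengths(cps, t)[t - 1]
            mass[r_last] = np.logaddexp(mass[r_last], logp)
        rows.append(np.exp(mass - logsumexp(mass)))
    return rows


def enumerate_smoothed(
    values: np.ndarray, hazard: HazardPrior, prior: NormalGammaPrior
) -> list[np.ndarray]:
    """p(r_t = r | y_1:n) for every t, from the full joint enumeration."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    joint = enumerate_log_joint(values, hazard, prior)
    mass = np.full((n, n), -np.inf)
    for cps, logp in joint.items():
        rl = _run_lengths(cps, n)
        for t in range(n):
            mass[t, rl[t]] = np.logaddexp(mass[t, rl[t]], logp)
    log_z = logsumexp(list(joint.values()))
    return [np.exp(mass[t, : t + 1] - log_z) for t in range(n)]


def brute_force_map_segmentation(
    smoothed_rows: list[np.ndarray],
    constraints: SegmentationConstraints,
) -> tuple[tuple[int, ...], float]:
    """Best constrained segmentation by exhaustive search.

    Maximizes the sum over t of the log smoothed probability of the
    segmentation-implied run length; same objective and constraint rules
    as the dynamic program, checked the slow way.  Returns (change-point
    positions, objective); ties resolve to the lexicographically earliest
    change-point set.
    """
    n = len(smoothed_rows)
    M = constraints.min_len
    best_cps, best_score = None, -np.inf
    with np.errstate(divide="ignore"):
        log_rows = [np.log(np.maximum(row, 0.0)) for row in smoothed_rows]
    for cps in sorted(_segmentations(n)):
        bounds = (0,) + cps + (n,)
        lengths = [b - a for a, b in zip(bounds[:-1], bounds[1:])]
        if constraints.exempt_first_last:
            interior = lengths[1:-1]
        else:
            interior = lengths
        if any(length < M for length in interior):
            continue
        rl = _run_lengths(cps, n)
        score = float(sum(log_rows[t][rl[t]] for t in range(n)))
        if score > best_score:
            best_score, best_cps = score, cps
    if best_cps is None:
        raise ValueError("no segmentation satisfies the constraints")
    return best_cps, best_score


class _QuadratureUniformModel:
    """Emission model integrating the uniform box prior numerically.

    The mu integral of a Gaussian block likelihood is a difference of
    normal CDFs; the remaining sigma integral is Gauss-Legendre.  Each
    hypothesis only needs its sufficient statistics, so the filter is
    deterministic — the Monte-Carlo-free reference for the particle
    implementation at the same prior.
    """

    def __init__(self, bounds: UniformPriorBounds, n_nodes: int = 400) -> None:
        self.bounds = bounds
        x, w = np.polynomial.legendre.leggauss(n_nodes)
        sl, sh = bounds.s_low, bounds.s_high
        self._sigma = 0.5 * (sh - sl) * x + 0.5 * (sh + sl)
        self._logw = (
            np.log(0.5 * (sh - sl) * w)
            - np.log(sh - sl)
            - np.log(bounds.mu_high - bounds.mu_low)
        )
        self.stats: list[tuple[int, float, float]] = []

    def _log_z(self, n: int, sum_y: float, sum_y2: float) -> float:
        b = self.bounds
        ybar = sum_y / n
        ss = max(sum_y2 - n * ybar * ybar, 0.0)
        s = self._sigma
        bracket = ndtr((b.mu_high - ybar) * np.sqrt(n) / s) - ndtr(
            (b.mu_low - ybar) * np.sqrt(n) / s
        )
        with np.errstate(divide="ignore"):
            log_int = (
                -0.5 * n * np.log(2.0 * np.pi)
                - n * np.log(s)
                - ss / (2.0 * s * s)
                + np.log(s)
                + 0.5 * np.log(2.0 * np.pi / n)
                + np.log(np.maximum(bracket, 1e-300))
            )
        return float(logsumexp(self._logw + log_int))

    def log_pred_new(self, y: float) -> float:
        return self._log_z(1, y, y * y)

    def log_pred_grow(self, y: float) -> np.ndarray:
        return np.array(
            [
                self._log_z(n + 1, sy + y, sy2 + y * y) - self._log_z(n, sy, sy2)
                for n, sy, sy2 in self.stats
            ]
        )

    def advance(self, y: float, keep_new: bool, keep_grow: np.ndarray) -> None:
        survivors = []
        if keep_new:
            survivors.append((1, y, y * y))
        for (n, sy, sy2), keep in zip(self.stats, keep_grow):
            if keep:
                survivors.append((n + 1, sy + y, sy2 + y * y))
        self.stats = survivors

    def min_ess(self):
        return None


def quadrature_uniform_filter(
    series: TimeSeries,
    hazard: HazardPrior,
    bounds: UniformPriorBounds,
    n_nodes: int = 400,
    prune_threshold: float = 1e-12,
) -> RunLengthPosterior:
    """Deterministic run-length posterior under the uniform box prior.

    Same recursion as the particle filter but with emissions computed by
    quadrature instead of Monte Carlo; serves as the same-prior oracle for
    the particle implementation.
    """
    model = _QuadratureUniformModel(bounds, n_nodes)
    posterior, _ = _run_filter(series, hazard, model, prune_threshold, False)
    return posterior
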
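"""Driver-response attribution between regime shifts.

Segmentations are reduced to shift events (regime start year, direction
and magnitude of the mean change); a driver shift is linked to a response
shift when the response follows within a fixed window (5 years in the
study, with coincident years counting as linked).  Shifts whose mean
change is negligible relative to the pooled spread are flagged as
variance-only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .segmentation import Segmentation

__all__ = [
    "ShiftEvent",
    "OverlapFinding",
    "shifts_from_segmentation",
    "overlap_within_window",
    "percent_change_between",
]

#: Relative mean-change threshold below which a shift is "variance-only":
#: |delta_mean| < VARIANCE_ONLY_EPS * pooled sigma of the two regimes.
VARIANCE_ONLY_EPS = 0.05


@dataclass(frozen=True)
class ShiftEvent:
    """Start of a new regime with the direction/magnitude of mean change."""

    series_label: str
    year: int
    direction: str  # "up" or "down"
    delta_mean: float
    variance_only: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if self.delta_mean > 0 and self.direction != "up":
            raise ValueError("direction inconsistent with positive delta_mean")
        if self.delta_mean < 0 and self.direction != "down":
            raise ValueError("direction inconsistent with negative delta_mean")


@dataclass(frozen=True)
class OverlapFinding:
    """A driver shift and the earliest response shift inside the window."""

    driver_event: ShiftEvent
    response_event: ShiftEvent | None
    lag_years: int | None
    linked: bool


def shifts_from_segmentation(
    seg: Segmentation,
    label: str = "",
    variance_only_eps: float = VARIANCE_ONLY_EPS,
) -> list[ShiftEvent]:
    """One event per regime after the first.

    ``delta_mean`` is the difference of consecutive posterior predictive
    means; events with |delta_mean| below ``variance_only_eps`` times the
    pooled sigma of the adjoining regimes are flagged variance-only.
    """
    events = []
    for prev, cur in zip(seg.regimes, seg.regimes[1:]):
        delta = cur.post_mean_mu - prev.post_mean_mu
        pooled_sigma = math.sqrt(
            0.5 * (prev.post_mean_sigma**2 + cur.post_mean_sigma**2)
        )
        events.append(
            ShiftEvent(
                series_label=label,
                year=cur.start,
                direction="up" if delta >= 0 else "down",
                delta_mean=float(delta),
                variance_only=bool(abs(delta) < variance_only_eps * pooled_sigma),
            )
        )
    return events


def overlap_within_window(
    drivers: list[ShiftEvent],
    responses: list[ShiftEvent],
    window: int = 5,
) -> list[OverlapFinding]:
    """Link each driver to the earliest response within the window.

    A driver at year d is linked to a response at year r when
    0 <= r - d <= window (coincident shifts count).  Responses may be
    linked by several drivers.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    findings = []
    for drv in drivers:
        candidates = sorted(
            (r for r in responses if 0 <= r.year - drv.year <= window),
            key=lambda r: r.year,
        )
        if candidates:
            resp = candidates[0]
            findings.append(
                OverlapFinding(drv, resp, resp.year - drv.year, True)
            )
        else:
            findings.append(OverlapFinding(drv, None, None, False))
    return findings


def percent_change_between(
    seg: Segmentation,
    baseline_regimes: list[int] | tuple[int, ...],
    comparison_regime: int,
) -> float:
    """Percent decline of one regime's mean relative to a baseline.

    The baseline is the average of posterior predictive means over the
    given regime indices; returns 100 * (1 - comparison / baseline), so a
    positive value is a decline and a negative one an increase.  A
    non-positive baseline makes the decline undefined: NaN is returned
    with a warning.
    """
    baseline_regimes = list(baseline_regimes)
    if not baseline_regimes:
        raise ValueError("baseline_regimes must be non-empty")
    means = [seg.regimes[i].post_mean_mu for i in baseline_regimes]
    baseline = float(np.mean(means))
    comparison = float(seg.regimes[comparison_regime].post_mean_mu)
    if baseline <= 0:
        warnings.warn(
            "baseline mean is non-positive; percent decline undefined",
            stacklevel=2,
        )
        return float("nan")
    return 100.0 * (1.0 - comparison / baseline)
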
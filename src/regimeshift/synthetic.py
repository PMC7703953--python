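"""Piecewise-stationary Gaussian simulators with known change points.

Every downstream stage of the package (run-length filtering, smoothing,
segmentation, attribution) is validated on series produced here: within
each regime the observations are i.i.d. Normal(mu, sigma), and regimes
switch abruptly at known boundaries.  :func:`generate_study_like` provides
fixed-seed fixtures whose regime layouts mimic the qualitative structure of
the six study series (NAO index, juvenile cod catch rate, *Calanus
finmarchicus* abundance, monthly sea-surface temperature, fishing
mortality).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .series import TimeSeries

__all__ = [
    "RegimeSpec",
    "SyntheticScenario",
    "generate_piecewise_normal",
    "generate_study_like",
    "read_scenario_file",
    "write_scenario_outputs",
    "STUDY_FIXTURES",
]


@dataclass(frozen=True)
class RegimeSpec:
    """One stationary regime: ``length`` steps of Normal(``mu``, ``sigma``)."""

    length: int
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"regime length must be >= 1, got {self.length}")
        if not self.sigma > 0:
            raise ValueError(f"regime sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class SyntheticScenario:
    """A full simulation scenario: ordered regimes plus sampling options.

    Change points are implied at the cumulative regime boundaries.  Missing
    observations (``missing_fraction``) are encoded as gaps in the time
    index, not NaNs.  ``ar1`` adds optional within-regime AR(1)
    autocorrelation; the default 0 gives the i.i.d. data model under which
    the detector's assumptions hold exactly.
    """

    regimes: tuple[RegimeSpec, ...]
    start_time: int = 0
    seed: int = 0
    missing_fraction: float = 0.0
    ar1: float = 0.0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "regimes", tuple(self.regimes))
        if len(self.regimes) == 0:
            raise ValueError("scenario must contain at least one regime")
        for r in self.regimes:
            if not isinstance(r, RegimeSpec):
                raise TypeError("regimes must be RegimeSpec instances")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")
        if not -1.0 < self.ar1 < 1.0:
            raise ValueError("ar1 must be in (-1, 1)")

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.regimes)

    @property
    def change_point_times(self) -> list[int]:
        """Time stamps of the first observation of each regime after the first."""
        cps, t = [], self.start_time
        for r in self.regimes[:-1]:
            t += r.length
            cps.append(t)
        return cps


def generate_piecewise_normal(
    scenario: SyntheticScenario,
) -> tuple[TimeSeries, list[int]]:
    """Draw one series from a scenario.

    Returns the series and the true change-point times (the time stamp of
    the first observation of each regime after the first).  The same
    scenario (seed included) always yields a bitwise-identical series.
    """
    rng = np.random.default_rng(scenario.seed)
    chunks = []
    for reg in scenario.regimes:
        z = rng.standard_normal(reg.length)
        if scenario.ar1 != 0.0:
            # stationary AR(1) innovations, unit marginal variance
            a = scenario.ar1
            x = np.empty(reg.length)
            x[0] = z[0]
            for i in range(1, reg.length):
                x[i] = a * x[i - 1] + np.sqrt(1.0 - a * a) * z[i]
            z = x
        chunks.append(reg.mu + reg.sigma * z)
    values = np.concatenate(chunks)
    times = scenario.start_time + np.arange(scenario.total_length)
    if scenario.missing_fraction > 0.0:
        keep = rng.random(len(values)) >= scenario.missing_fraction
        times, values = times[keep], values[keep]
    series = TimeSeries(times, values, label=scenario.label)
    return series, scenario.change_point_times


# ---------------------------------------------------------------------------
# Study-like fixtures
#
# Regime layouts (boundary years, means and spreads) transcribed from the
# study's reported segmentations so that the full pipeline can be exercised
# without any external data.  Seeds are fixed so fixtures are reproducible.
# ---------------------------------------------------------------------------

STUDY_FIXTURES: dict[str, SyntheticScenario] = {
    # Winter NAO index: long near-zero regime, a negative decade, a positive
    # quarter-century, then a weakly positive tail (shifts down, up, down).
    # The final 1.1-SD step sits near the detection limit by construction.
    "nao": SyntheticScenario(
        regimes=(
            RegimeSpec(97, 0.1, 0.9),   # 1864-1960
            RegimeSpec(11, -2.0, 0.9),  # 1961-1971
            RegimeSpec(24, 1.5, 0.9),   # 1972-1995
            RegimeSpec(23, 0.5, 0.9),   # 1996-2018
        ),
        start_time=1864,
        seed=20201,
        label="winter NAO index (synthetic)",
    ),
    # Juvenile cod catch per haul: first two regimes share the mean and
    # differ only in variability, then two stepwise mean declines.
    "cod": SyntheticScenario(
        regimes=(
            RegimeSpec(34, 18.5, 12.0),  # 1919-1952, highly variable
            RegimeSpec(22, 18.5, 4.0),   # 1953-1974, calmer
            RegimeSpec(24, 10.0, 4.0),   # 1975-1998
            RegimeSpec(16, 5.0, 2.5),    # 1999-2014
        ),
        start_time=1919,
        seed=20202,
        label="juvenile cod catch rate (synthetic)",
    ),
    # C. finmarchicus abundance: high early regime, ~75% drop, a further
    # drop to ~10% of the peak, recovery to the second level.
    "zooplankton": SyntheticScenario(
        regimes=(
            RegimeSpec(24, 100.0, 15.0),  # 1958-1981
            RegimeSpec(15, 25.0, 5.0),    # 1982-1996
            RegimeSpec(11, 10.0, 3.0),    # 1997-2007
            RegimeSpec(10, 25.0, 5.0),    # 2008-2017
        ),
        start_time=1958,
        seed=20203,
        label="C. finmarchicus abundance (synthetic)",
    ),
    # August sea-surface temperature: one warm step of +2 units.
    "sst_month": SyntheticScenario(
        regimes=(
            RegimeSpec(69, 16.7, 0.8),  # 1925-1993
            RegimeSpec(24, 18.7, 0.8),  # 1994-2017
        ),
        start_time=1925,
        seed=20204,
        label="August SST (synthetic)",
    ),
    # Fishing mortality F (ages 2-4): ratchet up to ~2 F_lim then decline;
    # regime lengths compatible with the shorter minimum length used for F.
    "fishing": SyntheticScenario(
        regimes=(
            RegimeSpec(17, 0.60, 0.06),  # 1963-1979
            RegimeSpec(18, 0.85, 0.07),  # 1980-1997
            RegimeSpec(9, 1.00, 0.06),   # 1998-2006
            RegimeSpec(11, 0.55, 0.08),  # 2007-2017
        ),
        start_time=1963,
        seed=20205,
        label="fishing mortality F (synthetic)",
    ),
}


def generate_study_like(name: str) -> tuple[TimeSeries, list[int]]:
    """Fixed-seed fixture shaped like one of the study series.

    ``name`` is one of ``nao``, ``cod``, ``zooplankton``, ``sst_month``,
    ``fishing``; anything else raises a ``ValueError`` listing the valid
    names.
    """
    try:
        scenario = STUDY_FIXTURES[name]
    except KeyError:
        valid = ", ".join(sorted(STUDY_FIXTURES))
        raise ValueError(f"unknown fixture {name!r}; valid names: {valid}") from None
    return generate_piecewise_normal(scenario)


# ---------------------------------------------------------------------------
# Scenario files: flat key-value text, one `regime = length mu sigma` line
# per regime.
# ---------------------------------------------------------------------------

def read_scenario_file(path: str | Path) -> SyntheticScenario:
    """Parse a flat key-value scenario file.

    Recognized keys: ``start_time``, ``seed``, ``missing_fraction``,
    ``ar1``, ``label``, and one ``regime = <length> <mu> <sigma>`` line per
    regime.  Lines starting with ``#`` are comments.
    """
    kw: dict = {"regimes": []}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, val = (s.strip() for s in line.partition("="))
        if key == "regime":
            parts = val.split()
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: regime needs 'length mu sigma', got {val!r}"
                )
            kw["regimes"].append(
                RegimeSpec(int(parts[0]), float(parts[1]), float(parts[2]))
            )
        elif key in ("start_time", "seed"):
            kw[key] = int(val)
        elif key in ("missing_fraction", "ar1"):
            kw[key] = float(val)
        elif key == "label":
            kw[key] = val
        else:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    if "seed" not in kw:
        raise ValueError(f"{path}: scenario files must set an explicit seed")
    kw["regimes"] = tuple(kw["regimes"])
    return SyntheticScenario(**kw)


def write_scenario_outputs(
    scenario: SyntheticScenario, out_dir: str | Path, stem: str = "synthetic"
) -> tuple[Path, Path]:
    """Simulate a scenario and write (time, value) plus true change points.

    Returns the paths of the series CSV and the change-point sidecar CSV.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series, cps = generate_piecewise_normal(scenario)
    series_path = out_dir / f"{stem}.csv"
    cps_path = out_dir / f"{stem}_changepoints.csv"
    series.to_frame().to_csv(series_path, index=False, float_format="%.17g")
    pd.DataFrame({"change_point_time": cps}).to_csv(cps_path, index=False)
    return series_path, cps_path
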
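"""Synthetic otolith-increment worlds with the statistical structure the
analysis assumes.

The generator inverts the fitted model: annual summer temperatures are
drawn per year; each fish gets a spawn year, a capture age (right-truncated
lifespans, most fish young), a fish-level random intercept, and shares
calendar-year random intercepts with its cohort; the first-annulus radius
follows the initial-size regression at the spawn-year temperature, later
radii follow the Walford recursion with the temperature of the formation
year, and total length follows the linear allometry.

The default :class:`TruthConfig` is the published-coefficient world:
b1 = 0.7033 mm/mm, b2 = -0.0631 mm/degC, a0 = 2.120 mm for growth,
2.937 - 0.0718*T for initial size, L = 176.38*Z - 74.62 for the allometry,
~400 fish spawned 2002-2012, ages 1-7, mean summer temperature 20.48 degC.
Residual SDs are not published for this system; the defaults (0.08 mm
growth, 0.20 mm initial, 20 mm length) are calibration choices documented
in the methods note.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import cipm
from .io import FISH_COLUMNS, INCREMENT_COLUMNS
from .models import phi_prime

__all__ = [
    "TruthConfig",
    "generate_temperatures",
    "generate_daily_temperatures",
    "generate_population",
    "truth_report",
]


@dataclass(frozen=True)
class TruthConfig:
    """True parameter values of a synthetic otolith world.

    Units: radii and SDs in mm unless noted; temperatures in degC;
    ``beta2`` in mm/degC, ``allo_slope`` in mm length per mm radius.
    """

    beta1: float = 0.7033
    beta2: float = -0.0631
    alpha0: float = 2.120
    sigma_growth: float = 0.08
    init_intercept: float = 2.937
    init_slope: float = -0.0718
    sigma_init: float = 0.20
    allo_slope: float = 176.38
    allo_intercept: float = -74.62
    sigma_length: float = 20.0
    sd_year: float = 0.05
    sd_fish: float = 0.04
    n_fish: int = 400
    spawn_years: tuple[int, int] = (2002, 2012)
    max_age: int = 7
    temp_mean: float = 20.48
    temp_sd: float = 0.5
    #: relative sampling weights of capture ages 1..max_age (renormalized,
    #: truncated/padded as needed); default favours ages 1-3
    age_weights: tuple[float, ...] = (0.28, 0.26, 0.20, 0.11, 0.07, 0.05, 0.03)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.beta1 < 1.0):
            raise ValueError("beta1 must lie in (0, 1)")
        for name in ("sigma_growth", "sigma_init", "sigma_length",
                     "sd_year", "sd_fish", "temp_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_fish < 0:
            raise ValueError("n_fish must be >= 0")
        if self.max_age < 1:
            raise ValueError("max_age must be >= 1")
        if self.spawn_years[1] < self.spawn_years[0]:
            raise ValueError("spawn_years range is empty")

    @property
    def years(self) -> range:
        """Every calendar year any increment can form in."""
        return range(self.spawn_years[0], self.spawn_years[1] + self.max_age)

    def growth_coefficients(self) -> cipm.GrowthCoefficients:
        return cipm.GrowthCoefficients(
            self.beta1, self.beta2, self.alpha0, self.sigma_growth
        )

    def initial_coefficients(self) -> cipm.InitialCoefficients:
        return cipm.InitialCoefficients(
            self.init_intercept, self.init_slope, self.sigma_init
        )

    def allometry_coefficients(self) -> cipm.AllometryCoefficients:
        return cipm.AllometryCoefficients(
            self.allo_slope, self.allo_intercept, self.sigma_length
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spawn_years"] = list(self.spawn_years)
        d["age_weights"] = list(self.age_weights)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "TruthConfig":
        d = dict(d)
        if "spawn_years" in d:
            d["spawn_years"] = tuple(d["spawn_years"])
        if "age_weights" in d:
            d["age_weights"] = tuple(d["age_weights"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "TruthConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# temperatures
# ---------------------------------------------------------------------------

def generate_temperatures(
    config: TruthConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Annual mean summer temperatures for every source and relevant year.

    The open-sea ("mediterranean") series is N(temp_mean, temp_sd^2); the
    lagoon groupings are correlated variants with small systematic offsets
    (shallow lagoons warmer, deep lagoons cooler), emulating the structure
    of a coastal-lagoon system without asserting real values.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed))
    years = list(config.years)
    med = config.temp_mean + config.temp_sd * rng.standard_normal(len(years))
    offsets = {"all_lagoons": 0.8, "shallow_lagoons": 1.5, "deep_lagoons": 0.3}
    frames = [
        pd.DataFrame(
            {"source": "mediterranean", "year": years, "temperature": med}
        )
    ]
    for source, off in offsets.items():
        jitter = 0.2 * rng.standard_normal(len(years))
        frames.append(
            pd.DataFrame(
                {"source": source, "year": years, "temperature": med + off + jitter}
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_daily_temperatures(
    config: TruthConfig,
    annual: pd.DataFrame,
    source: str = "mediterranean",
    noise_sd: float = 0.3,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Daily series (date, value) whose Jun-Aug mean matches the annual
    table for ``source``: seasonal sinusoid with the yearly level chosen so
    the summer-window mean of the deterministic part equals the annual
    value, plus i.i.d. day-to-day noise."""
    rng = rng or np.random.default_rng(np.random.SeedSequence((config.seed, 17)))
    sub = annual[annual["source"] == source]
    amplitude = 6.0
    rows = []
    for _, row in sub.iterrows():
        year = int(row["year"])
        days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        doy = days.dayofyear.to_numpy()
        seasonal = amplitude * np.sin(2 * np.pi * (doy - 110) / 365.25)
        summer = (days.month >= 6) & (days.month <= 8)
        level = row["temperature"] - seasonal[summer].mean()
        noise = noise_sd * rng.standard_normal(len(days))
        # day-to-day noise is centred over the summer window so the
        # Jun-Aug mean reproduces the annual value by construction
        noise -= noise[summer].mean()
        values = level + seasonal + noise
        rows.append(pd.DataFrame({"date": days, "value": values}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def _truncated_positive_growth(
    rng: np.random.Generator, mean: float, sd: float, lower: float
) -> float:
    """Draw Z' ~ N(mean, sd^2) conditional on Z' > lower (rejection with a
    deterministic truncated-Gaussian fallback for extreme cases)."""
    if sd == 0:
        return max(mean, np.nextafter(lower, np.inf))
    for _ in range(1000):
        draw = mean + sd * rng.standard_normal()
        if draw > lower:
            return draw
    # numerically extreme tail: inverse-CDF truncated draw
    from scipy import stats

    u = rng.uniform(stats.norm.cdf(lower, mean, sd), 1.0)
    return float(stats.norm.ppf(u, mean, sd))


def generate_population(
    config: TruthConfig,
    temps: pd.DataFrame | None = None,
    source: str = "mediterranean",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate increments, fish metadata and temperatures.

    Returns ``(increments, fish, temps)`` in the canonical CSV schemas.
    All randomness flows from ``config.seed``; each fish has its own
    deterministic substream, so populations are reproducible and
    insensitive to generation order.
    """
    root = np.random.SeedSequence(config.seed)
    ss_temp, ss_year, ss_fish_master = root.spawn(3)
    if temps is None:
        temps = generate_temperatures(config, np.random.default_rng(ss_temp))
    tseries = (
        temps[temps["source"] == source].set_index("year")["temperature"]
    )

    years = list(config.years)
    rng_year = np.random.default_rng(ss_year)
    year_effects = dict(
        zip(years, config.sd_year * rng_year.standard_normal(len(years)))
    )

    n = config.n_fish
    weights = np.asarray(config.age_weights, dtype=float)
    if len(weights) < config.max_age:
        weights = np.concatenate(
            [weights, np.full(config.max_age - len(weights), weights[-1] / 2)]
        )
    weights = weights[: config.max_age]
    weights = weights / weights.sum()

    inc_rows: list[tuple] = []
    fish_rows: list[tuple] = []
    fish_streams = ss_fish_master.spawn(n) if n else []
    locations = ("lagoon", "gulf")
    for i in range(n):
        rng = np.random.default_rng(fish_streams[i])
        fish_id = f"F{i + 1:04d}"
        spawn = int(rng.integers(config.spawn_years[0], config.spawn_years[1] + 1))
        age = int(rng.choice(np.arange(1, config.max_age + 1), p=weights))
        fish_eff = config.sd_fish * rng.standard_normal()

        # first annulus: age-0 growth in the spawn year
        T0 = float(tseries[spawn])
        z = _truncated_positive_growth(
            rng,
            config.init_intercept + config.init_slope * T0,
            config.sigma_init,
            0.0,
        )
        radii = [z]
        for j in range(1, age):
            year = spawn + j
            T = float(tseries[year])
            mean = (
                config.beta1 * radii[-1]
                + config.beta2 * T
                + config.alpha0
                + year_effects[year]
                + fish_eff
            )
            radii.append(
                _truncated_positive_growth(
                    rng, mean, config.sigma_growth, radii[-1]
                )
            )
        widths = np.diff([0.0] + radii)
        for j in range(age):
            inc_rows.append(
                (fish_id, spawn, j, spawn + j, float(widths[j]), float(radii[j]))
            )

        z4 = radii[-1]
        length = (
            config.allo_slope * z4
            + config.allo_intercept
            + config.sigma_length * rng.standard_normal()
        )
        length = max(length, 10.0)
        weight = max(1e-5 * length**3 * np.exp(0.1 * rng.standard_normal()), 1.0)
        # secondary axes: shorter, noisier views of the primary dorsal radius
        z1 = max(0.80 * z4 + 0.15 * rng.standard_normal(), 0.05)
        z2 = max(0.85 * z4 + 0.15 * rng.standard_normal(), 0.05)
        z3 = max(0.90 * z4 + 0.15 * rng.standard_normal(), 0.05)
        fish_rows.append(
            (
                fish_id,
                date(spawn + age, 6, 15).isoformat(),
                locations[int(rng.integers(0, 2))],
                float(length),
                float(weight),
                age,
                float(z1),
                float(z2),
                float(z3),
                float(z4),
            )
        )

    increments = pd.DataFrame(inc_rows, columns=list(INCREMENT_COLUMNS))
    fish = pd.DataFrame(fish_rows, columns=list(FISH_COLUMNS))
    return increments, fish, temps


# ---------------------------------------------------------------------------
# truth report
# ---------------------------------------------------------------------------

def truth_report(config: TruthConfig, T: float | None = None) -> dict:
    """Expected downstream quantities implied by a config, for use as test
    and pipeline expectations: von Bertalanffy K, asymptotic otolith radius
    and length at temperature T, growth-performance index, and closed-form
    per-age moments."""
    T = config.temp_mean if T is None else float(T)
    growth = config.growth_coefficients()
    allo = config.allometry_coefficients()
    K = -float(np.log(config.beta1))
    Z_inf = growth.fixed_point(T)
    L_inf = float(allo.mean(Z_inf))
    moments = cipm.closed_form_moments(
        config.initial_coefficients(), growth, allo, T, config.max_age
    )
    return {
        "temperature": T,
        "K_per_year": K,
        "Z_inf_mm": Z_inf,
        "L_inf_mm": L_inf,
        "phi_prime": phi_prime(K, L_inf),
        "age_moments": moments.to_dict("records"),
        "config": config.to_dict(),
    }
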
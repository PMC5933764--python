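"""Cohort integral projection model (cIPM) for otolith size and body length.

The cIPM advances a continuous density of otolith radii one age class at a
time,

    n(Z', a+1) = integral g(Z'|Z; T) n(Z, a) dZ,

with a Gaussian growth kernel g whose mean is the affine Walford map
b1*Z + b2*T + a0 and whose SD is the residual SD of the growth fit.  The
initial density (radius at the first birthday, age 1) is Gaussian with
mean from the initial-size regression at temperature T.  Body-length
densities follow from a second integral against the allometry size kernel
s(L|Z).  There is no mortality: every density is conditional on survival
and integrates to one.

Discretization is the canonical midpoint rule on a uniform mesh.  Because
every kernel is affine-Gaussian, exact moment recursions exist
(:func:`closed_form_moments`) and serve as an independent oracle for the
numerical projection.

Parameter uncertainty is propagated with a nonparametric bootstrap: each
replicate resamples the fitting tables, refits the three regressions, and
re-runs the whole projection per temperature scenario.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import join_temperature
from .models import LinearFitResults

logger = logging.getLogger(__name__)

__all__ = [
    "GrowthCoefficients",
    "InitialCoefficients",
    "AllometryCoefficients",
    "Mesh",
    "GrowthKernel",
    "SizeDistribution",
    "AgeSummary",
    "ScenarioResult",
    "CohortProjection",
    "make_initial_distribution",
    "project_step",
    "project_cohort",
    "map_to_length",
    "closed_form_moments",
    "bootstrap_projection",
    "compare_scenarios",
    "plot_scenarios",
    "scenario_label",
]

#: reference mean summer temperature (deg C) used as the projection default
REFERENCE_TEMPERATURE = 20.48


# ---------------------------------------------------------------------------
# coefficient containers (fit results or injected values)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthCoefficients:
    """Walford growth-kernel coefficients: Z' ~ N(beta1*Z + beta2*T + alpha0, sigma^2)."""

    beta1: float
    beta2: float
    alpha0: float
    sigma: float

    def mean_intercept(self, T: float) -> float:
        return self.beta2 * T + self.alpha0

    def fixed_point(self, T: float) -> float:
        """Asymptotic otolith radius at temperature T (Walford fixed point)."""
        return self.mean_intercept(T) / (1.0 - self.beta1)

    @classmethod
    def from_results(cls, fit: LinearFitResults) -> "GrowthCoefficients":
        return cls(
            beta1=float(fit.params["Z"]),
            beta2=float(fit.params.get("T", 0.0)),
            alpha0=float(fit.params["intercept"]),
            sigma=float(fit.resid_sd),
        )


@dataclass(frozen=True)
class InitialCoefficients:
    """Initial-size model: radius at first birthday ~ N(intercept + slope*T, sigma^2)."""

    intercept: float
    slope: float
    sigma: float

    def mean(self, T: float) -> float:
        return self.intercept + self.slope * T

    @classmethod
    def from_results(cls, fit: LinearFitResults) -> "InitialCoefficients":
        return cls(
            intercept=float(fit.params["intercept"]),
            slope=float(fit.params["T"]),
            sigma=float(fit.resid_sd),
        )


@dataclass(frozen=True)
class AllometryCoefficients:
    """Size kernel: L ~ N(slope*Z + intercept, sigma^2) (constant SD)."""

    slope: float
    intercept: float
    sigma: float

    def mean(self, Z):
        return self.slope * np.asarray(Z) + self.intercept

    @classmethod
    def from_results(cls, fit: LinearFitResults) -> "AllometryCoefficients":
        return cls(
            slope=float(fit.params["Z"]),
            intercept=float(fit.params["intercept"]),
            sigma=float(fit.resid_sd),
        )


# ---------------------------------------------------------------------------
# mesh / kernel / distribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Mesh:
    """Uniform midpoint mesh on [z_min, z_max] with n_nodes cells."""

    z_min: float
    z_max: float
    n_nodes: int = 500

    def __post_init__(self):
        if not (self.z_max > self.z_min):
            raise ValueError("z_max must exceed z_min")
        if self.n_nodes < 2:
            raise ValueError("need at least 2 mesh nodes")

    @property
    def dz(self) -> float:
        return (self.z_max - self.z_min) / self.n_nodes

    @property
    def nodes(self) -> np.ndarray:
        return self.z_min + (np.arange(self.n_nodes) + 0.5) * self.dz


@dataclass(frozen=True)
class GrowthKernel:
    """Gaussian transition density g(Z'|Z) = N(beta1*Z + intercept, sd^2)."""

    beta1: float
    intercept: float
    sd: float
    temperature: float | None = None

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("kernel SD must be > 0")

    @classmethod
    def from_coefficients(
        cls, coefs: GrowthCoefficients, T: float
    ) -> "GrowthKernel":
        return cls(
            beta1=coefs.beta1,
            intercept=coefs.mean_intercept(T),
            sd=coefs.sigma,
            temperature=T,
        )

    def matrix(self, mesh: Mesh, out_mesh: Mesh | None = None) -> np.ndarray:
        """Discretized operator: M[j, i] = g(z'_j | z_i) * dz_in."""
        out_mesh = out_mesh or mesh
        means = self.beta1 * mesh.nodes + self.intercept
        M = stats.norm.pdf(out_mesh.nodes[:, None], loc=means[None, :], scale=self.sd)
        return M * mesh.dz


class SizeDistribution:
    """Density of otolith radius (or body length) on a midpoint mesh at one age."""

    def __init__(
        self,
        mesh: Mesh,
        density: np.ndarray,
        age: int,
        variable: str = "otolith_radius",
        normalize: bool = True,
    ):
        density = np.asarray(density, dtype=float)
        if density.shape != (mesh.n_nodes,):
            raise ValueError("density shape does not match mesh")
        if not np.all(np.isfinite(density)):
            raise FloatingPointError("non-finite density values")
        if np.any(density < -1e-12):
            raise ValueError("negative density values")
        density = np.clip(density, 0.0, None)
        if normalize:
            total = density.sum() * mesh.dz
            if total <= 0:
                raise ValueError("density integrates to zero")
            density = density / total
        self.mesh = mesh
        self.density = density
        self.age = int(age)
        self.variable = variable

    def integral(self) -> float:
        return float(self.density.sum() * self.mesh.dz)

    def mean(self) -> float:
        return float(np.sum(self.mesh.nodes * self.density) * self.mesh.dz)

    def var(self) -> float:
        m = self.mean()
        return float(np.sum((self.mesh.nodes - m) ** 2 * self.density) * self.mesh.dz)

    def sd(self) -> float:
        return float(np.sqrt(self.var()))

    def quantile(self, q) -> np.ndarray:
        cdf = np.cumsum(self.density) * self.mesh.dz
        return np.interp(np.atleast_1d(q), cdf, self.mesh.nodes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node": self.mesh.nodes, "density": self.density,
             "age": self.age, "variable": self.variable}
        )

    def __repr__(self):  # pragma: no cover - cosmetic
        return (
            f"<SizeDistribution {self.variable} age={self.age} "
            f"mean={self.mean():.3f}>"
        )


def _check_truncation(mesh: Mesh, mean: float, sd: float, what: str) -> None:
    mass = stats.norm.cdf(mesh.z_max, mean, sd) - stats.norm.cdf(mesh.z_min, mean, sd)
    if 1.0 - mass > 1e-3:
        warnings.warn(
            f"{what}: mesh [{mesh.z_min:.3g}, {mesh.z_max:.3g}] truncates "
            f"{100 * (1 - mass):.2g}% of the density mass",
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# core projection operations
# ---------------------------------------------------------------------------

def make_initial_distribution(
    init: InitialCoefficients | LinearFitResults,
    T: float,
    mesh: Mesh,
) -> SizeDistribution:
    """Gaussian otolith-radius density at the first birthday (age 1)."""
    if isinstance(init, LinearFitResults):
        init = InitialCoefficients.from_results(init)
    if init.sigma <= 0:
        raise ValueError("initial-size residual SD must be > 0")
    mu = init.mean(T)
    _check_truncation(mesh, mu, init.sigma, "initial distribution")
    density = stats.norm.pdf(mesh.nodes, mu, init.sigma)
    return SizeDistribution(mesh, density, age=1)


def project_step(dist: SizeDistribution, kernel: GrowthKernel) -> SizeDistribution:
    """One cIPM step: midpoint-rule application of the growth kernel."""
    new = kernel.matrix(dist.mesh) @ dist.density
    return SizeDistribution(dist.mesh, new, age=dist.age + 1, variable=dist.variable)


def project_cohort(
    init: InitialCoefficients | LinearFitResults,
    growth: GrowthCoefficients | LinearFitResults,
    T: float,
    max_age: int = 7,
    mesh: Mesh | None = None,
) -> list[SizeDistribution]:
    """Otolith-radius densities at ages 1..max_age at temperature T."""
    if max_age < 1:
        raise ValueError("max_age must be >= 1")
    if isinstance(init, LinearFitResults):
        init = InitialCoefficients.from_results(init)
    if isinstance(growth, LinearFitResults):
        growth = GrowthCoefficients.from_results(growth)
    if mesh is None:
        mesh = default_mesh(init, growth, [T])
    dists = [make_initial_distribution(init, T, mesh)]
    if max_age > 1:
        kernel = GrowthKernel.from_coefficients(growth, T)
        K = kernel.matrix(mesh)
        for _ in range(max_age - 1):
            new = K @ dists[-1].density
            dists.append(
                SizeDistribution(mesh, new, age=dists[-1].age + 1)
            )
    return dists


def map_to_length(
    dist: SizeDistribution,
    allometry: AllometryCoefficients | LinearFitResults,
    length_mesh: Mesh | None = None,
    n_sd: float = 8.0,
) -> SizeDistribution:
    """Map an otolith-radius density to a total-length density through the
    Gaussian allometry size kernel s(L|Z) (constant SD)."""
    if dist.variable != "otolith_radius":
        raise ValueError("input must be an otolith-radius density")
    if isinstance(allometry, LinearFitResults):
        allometry = AllometryCoefficients.from_results(allometry)
    if allometry.sigma <= 0:
        raise ValueError("allometry residual SD must be > 0")
    if length_mesh is None:
        lo = allometry.mean(dist.mesh.z_min)
        hi = allometry.mean(dist.mesh.z_max)
        lo, hi = min(lo, hi), max(lo, hi)
        pad = n_sd * allometry.sigma
        length_mesh = Mesh(lo - pad, hi + pad, dist.mesh.n_nodes)
    means = allometry.mean(dist.mesh.nodes)
    M = stats.norm.pdf(
        length_mesh.nodes[:, None], loc=means[None, :], scale=allometry.sigma
    )
    density = (M * dist.mesh.dz) @ dist.density
    return SizeDistribution(length_mesh, density, age=dist.age, variable="total_length")


def default_mesh(
    init: InitialCoefficients,
    growth: GrowthCoefficients,
    temperatures: Sequence[float],
    n_nodes: int = 500,
    n_sd: float = 8.0,
) -> Mesh:
    """Mesh wide enough for every scenario: [coldest-scenario initial mean
    - n_sd*s, warmest fixed point + n_sd*s] with s the larger of the
    initial SD and the stationary SD of the growth recursion."""
    temperatures = list(temperatures)
    init_means = [init.mean(T) for T in temperatures]
    fixed_points = [growth.fixed_point(T) for T in temperatures]
    stat_sd = growth.sigma / np.sqrt(1.0 - growth.beta1**2)
    s = max(init.sigma, stat_sd)
    lo = min(init_means + fixed_points) - n_sd * s
    hi = max(init_means + fixed_points) + n_sd * s
    return Mesh(lo, hi, n_nodes)


def closed_form_moments(
    init: InitialCoefficients | LinearFitResults,
    growth: GrowthCoefficients | LinearFitResults,
    allometry: AllometryCoefficients | LinearFitResults | None,
    T: float,
    max_age: int = 7,
) -> pd.DataFrame:
    """Exact affine-Gaussian moment recursion (independent oracle for the
    numerical projection):

        mu_{a+1} = b1 mu_a + b2 T + a0,   s2_{a+1} = b1^2 s2_a + sigma^2

    with length moments through the affine allometry.  Returns a DataFrame
    with columns age, z_mean, z_sd, length_mean, length_sd.
    """
    if isinstance(init, LinearFitResults):
        init = InitialCoefficients.from_results(init)
    if isinstance(growth, LinearFitResults):
        growth = GrowthCoefficients.from_results(growth)
    if isinstance(allometry, LinearFitResults):
        allometry = AllometryCoefficients.from_results(allometry)
    mu, s2 = init.mean(T), init.sigma**2
    rows = [(1, mu, np.sqrt(s2))]
    for age in range(2, max_age + 1):
        mu = growth.beta1 * mu + growth.mean_intercept(T)
        s2 = growth.beta1**2 * s2 + growth.sigma**2
        rows.append((age, mu, np.sqrt(s2)))
    out = pd.DataFrame(rows, columns=["age", "z_mean", "z_sd"])
    if allometry is not None:
        out["length_mean"] = allometry.slope * out["z_mean"] + allometry.intercept
        out["length_sd"] = np.sqrt(
            allometry.slope**2 * out["z_sd"] ** 2 + allometry.sigma**2
        )
    return out


# ---------------------------------------------------------------------------
# scenario summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeSummary:
    """Per-age summary of projected sizes across bootstrap replicates (mm).

    ``mean`` and ``ci95`` describe the bootstrap distribution of the mean
    size; ``sd`` and ``pi95`` describe the pooled predictive distribution
    of individual sizes (parameter plus residual variability).
    """

    age: int
    mean: float
    sd: float
    ci95: tuple[float, float]
    pi95: tuple[float, float]

    def __post_init__(self):
        if not (self.ci95[0] <= self.mean <= self.ci95[1]):
            raise ValueError("mean outside its confidence interval")


@dataclass
class ScenarioResult:
    """Scenario comparison: per-scenario temperature and per-age summaries.

    ``percent_change`` is 100*(reference mean - scenario mean)/reference
    mean per age — positive values mean the scenario's fish are smaller.
    """

    temperatures: dict[str, float]
    summaries: dict[str, list[AgeSummary]]
    reference: str = "reference"
    n_replicates: int = 1
    n_discarded: int = 0
    seed: int | None = None

    @property
    def max_age(self) -> int:
        return max(s.age for s in self.summaries[self.reference])

    def percent_change(self, scenario: str, age: int) -> float:
        ref = {s.age: s.mean for s in self.summaries[self.reference]}
        scen = {s.age: s.mean for s in self.summaries[scenario]}
        if age not in ref:
            raise ValueError(f"age {age} beyond projected range")
        return 100.0 * (ref[age] - scen[age]) / ref[age]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, summaries in self.summaries.items():
            for s in summaries:
                rows.append(
                    {
                        "scenario": label,
                        "temperature": self.temperatures[label],
                        "age": s.age,
                        "mean": s.mean,
                        "sd": s.sd,
                        "ci_lo": s.ci95[0],
                        "ci_hi": s.ci95[1],
                        "pi_lo": s.pi95[0],
                        "pi_hi": s.pi95[1],
                        "percent_change": self.percent_change(label, s.age),
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "n_replicates": self.n_replicates,
            "n_discarded": self.n_discarded,
            "seed": self.seed,
            "temperatures": self.temperatures,
            "scenarios": {
                label: [
                    {
                        "age": s.age,
                        "mean": s.mean,
                        "sd": s.sd,
                        "ci95": list(s.ci95),
                        "pi95": list(s.pi95),
                        "percent_change": self.percent_change(label, s.age),
                    }
                    for s in summaries
                ]
                for label, summaries in self.summaries.items()
            },
        }


def plot_scenarios(result: ScenarioResult, ax=None, intervals: str = "ci"):
    """Mean length-at-age per temperature scenario with interval bands.

    ``intervals`` selects the band: ``"ci"`` (95% CI of the mean),
    ``"pi"`` (95% prediction interval) or ``"none"``.  Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, summaries in result.summaries.items():
        ages = [s.age for s in summaries]
        means = [s.mean for s in summaries]
        (line,) = ax.plot(
            ages,
            means,
            marker="o",
            label=f"{label} ({result.temperatures[label]:.2f} \N{DEGREE SIGN}C)",
        )
        if intervals in ("ci", "pi"):
            bands = [(s.ci95 if intervals == "ci" else s.pi95) for s in summaries]
            ax.fill_between(
                ages,
                [b[0] for b in bands],
                [b[1] for b in bands],
                color=line.get_color(),
                alpha=0.2,
            )
    ax.set_xlabel("age (years)")
    ax.set_ylabel("mean total length (mm)")
    ax.legend()
    return ax


def scenario_label(offset: float) -> str:
    if offset == 0:
        return "reference"
    sign = "plus" if offset > 0 else "minus"
    return f"{sign}{abs(offset):g}"


def compare_scenarios(
    result: ScenarioResult, ages: Iterable[int] | None = None
) -> pd.DataFrame:
    """Percent change in mean size relative to the reference scenario."""
    if ages is None:
        ages = range(1, result.max_age + 1)
    ages = list(ages)
    bad = [a for a in ages if a > result.max_age or a < 1]
    if bad:
        raise ValueError(f"ages {bad} beyond projected range 1..{result.max_age}")
    rows = []
    for label in result.summaries:
        for age in ages:
            rows.append(
                {
                    "scenario": label,
                    "age": age,
                    "percent_change": result.percent_change(label, age),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# high-level projection object
# ---------------------------------------------------------------------------

class CohortProjection:
    """Deterministic cIPM built from fitted (or injected) coefficients.

    Construct from fit results (:meth:`from_results`) or plain coefficient
    mappings (:meth:`from_coefficients` — the "coefficient injection" mode
    that reproduces published projections without raw data).
    """

    def __init__(
        self,
        growth: GrowthCoefficients,
        initial: InitialCoefficients,
        allometry: AllometryCoefficients,
        n_nodes: int = 500,
        n_sd: float = 8.0,
    ):
        self.growth = growth
        self.initial = initial
        self.allometry = allometry
        self.n_nodes = n_nodes
        self.n_sd = n_sd

    @classmethod
    def from_results(
        cls,
        growth_fit: LinearFitResults,
        initial_fit: LinearFitResults,
        allometry_fit: LinearFitResults,
        **kwargs,
    ) -> "CohortProjection":
        return cls(
            GrowthCoefficients.from_results(growth_fit),
            InitialCoefficients.from_results(initial_fit),
            AllometryCoefficients.from_results(allometry_fit),
            **kwargs,
        )

    @classmethod
    def from_coefficients(
        cls,
        growth: Mapping[str, float],
        initial: Mapping[str, float],
        allometry: Mapping[str, float],
        **kwargs,
    ) -> "CohortProjection":
        return cls(
            GrowthCoefficients(**growth),
            InitialCoefficients(**initial),
            AllometryCoefficients(**allometry),
            **kwargs,
        )

    def mesh_for(self, temperatures: Sequence[float]) -> Mesh:
        return default_mesh(
            self.initial, self.growth, temperatures, self.n_nodes, self.n_sd
        )

    def project(
        self, T: float, max_age: int = 7, mesh: Mesh | None = None
    ) -> list[SizeDistribution]:
        mesh = mesh or self.mesh_for([T])
        return project_cohort(self.initial, self.growth, T, max_age, mesh)

    def length_distributions(
        self, T: float, max_age: int = 7, mesh: Mesh | None = None
    ) -> list[SizeDistribution]:
        return [
            map_to_length(d, self.allometry, n_sd=self.n_sd)
            for d in self.project(T, max_age, mesh)
        ]

    def mean_length_at_age(self, T: float, max_age: int = 7) -> pd.Series:
        dists = self.length_distributions(T, max_age)
        return pd.Series(
            {d.age: d.mean() for d in dists}, name="mean_length_mm"
        )

    def moments(self, T: float, max_age: int = 7) -> pd.DataFrame:
        return closed_form_moments(
            self.initial, self.growth, self.allometry, T, max_age
        )

    def scenarios(
        self,
        reference_T: float = REFERENCE_TEMPERATURE,
        offsets: Sequence[float] = (-1.0, 0.0, 1.0),
        max_age: int = 7,
    ) -> ScenarioResult:
        """Point-estimate scenario projection (no bootstrap; degenerate CIs)."""
        temps = {scenario_label(o): reference_T + o for o in offsets}
        mesh = self.mesh_for(list(temps.values()))
        summaries = {}
        for label, T in temps.items():
            dists = [
                map_to_length(d, self.allometry, n_sd=self.n_sd)
                for d in project_cohort(self.initial, self.growth, T, max_age, mesh)
            ]
            summaries[label] = [
                AgeSummary(
                    age=d.age,
                    mean=d.mean(),
                    sd=d.sd(),
                    ci95=(d.mean(), d.mean()),
                    pi95=tuple(d.quantile([0.025, 0.975])),
                )
                for d in dists
            ]
        return ScenarioResult(temperatures=temps, summaries=summaries)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _ols_coefs(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Plain normal-equation OLS with rank check; returns (beta, resid_sd)."""
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(y) - X.shape[1], 1)
    return beta, float(np.sqrt(resid @ resid / dof))


def _mixture_quantile(means, sds, q):
    """Quantile of an equal-weight Gaussian mixture, by bracketing the CDF."""
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)

    def cdf(x):
        return float(np.mean(stats.norm.cdf(x, means, sds)))

    lo = float(np.min(means - 10 * sds))
    hi = float(np.max(means + 10 * sds))
    return float(optimize.brentq(lambda x: cdf(x) - q, lo, hi, xtol=1e-10))


def bootstrap_projection(
    pairs: pd.DataFrame,
    first: pd.DataFrame,
    fish: pd.DataFrame,
    temps: pd.DataFrame,
    source: str = "mediterranean",
    reference_T: float = REFERENCE_TEMPERATURE,
    offsets: Sequence[float] = (-1.0, 0.0, 1.0),
    B: int = 1000,
    seed: int = 0,
    n_nodes: int = 200,
    max_age: int = 7,
    radius: str = "z4",
    resample: str = "rows",
    max_discard_frac: float = 0.05,
) -> ScenarioResult:
    """Bootstrap the whole projection pipeline under temperature scenarios.

    Each replicate case-resamples the three fitting tables independently,
    refits the temperature growth model, the initial-size model and the
    allometry by OLS, and runs the full cIPM projection for every scenario.
    Replicates whose resampled design is singular are discarded and
    counted; more than ``max_discard_frac`` of them is an error.

    ``resample`` sets the resampling unit of the growth-pair table:
    ``"rows"`` treats pairs as exchangeable; ``"fish"`` resamples whole
    fish (within-fish correlation); ``"year"`` resamples whole formation
    years, which is the appropriate unit when growth shares year-level
    shocks (a common year effect shifts every increment formed that year,
    so pair-level resampling understates the uncertainty of the
    temperature-dependent intercept).  The first-increment and fish tables
    are always resampled by row: their rows are single measurements per
    fish and carry no shared-year term in this model.

    Summaries per scenario and age: the bootstrap mean of projected mean
    lengths, a 95% CI of the mean, and a 95% prediction interval from the
    pooled equal-weight mixture of per-replicate predictive densities.
    Under row resampling the CI is the percentile interval; under cluster
    resampling it is mean +/- t_{G-1} x bootstrap SD with G the number of
    clusters, the standard few-clusters correction (percentile intervals
    undercover when the effective sample is a handful of clusters).
    Identical seed and inputs give identical results.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    pairs_T = join_temperature(pairs.reset_index(drop=True), temps, source)
    first_T = join_temperature(first.reset_index(drop=True), temps, source)
    fish_tab = fish[[radius, "total_length"]].dropna().reset_index(drop=True)

    yP = pairs_T["Zprime"].to_numpy()
    XP = np.column_stack(
        [pairs_T["Z"].to_numpy(), pairs_T["T"].to_numpy(), np.ones(len(pairs_T))]
    )
    yI = first_T["Z"].to_numpy()
    XI = np.column_stack([first_T["T"].to_numpy(), np.ones(len(first_T))])
    yA = fish_tab["total_length"].to_numpy()
    XA = np.column_stack([fish_tab[radius].to_numpy(), np.ones(len(fish_tab))])

    # point-estimate fits fix the shared mesh across replicates
    bP, sP = _ols_coefs(yP, XP)
    bI, sI = _ols_coefs(yI, XI)
    growth0 = GrowthCoefficients(bP[0], bP[1], bP[2], max(sP, 1e-6))
    init0 = InitialCoefficients(bI[1], bI[0], max(sI, 1e-6))
    temps_scen = {scenario_label(o): reference_T + o for o in offsets}
    mesh = default_mesh(init0, growth0, list(temps_scen.values()), n_nodes, n_sd=10.0)

    if resample not in ("rows", "fish", "year"):
        raise ValueError(f"unknown resampling unit {resample!r}")
    pair_groups = None
    if resample != "rows":
        key = "fish_id" if resample == "fish" else "year"
        pair_groups = [
            g.index.to_numpy() for _, g in pairs_T.groupby(key, sort=False)
        ]

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(B)
    per_scenario_means: dict[str, list[np.ndarray]] = {k: [] for k in temps_scen}
    per_scenario_sds: dict[str, list[np.ndarray]] = {k: [] for k in temps_scen}
    n_discarded = 0
    for r in range(B):
        rng = np.random.default_rng(children[r])
        try:
            if B == 1:
                idxP = np.arange(len(yP))
                idxI = np.arange(len(yI))
                idxA = np.arange(len(yA))
            else:
                if pair_groups is not None:
                    picked = rng.integers(0, len(pair_groups), len(pair_groups))
                    idxP = np.concatenate([pair_groups[i] for i in picked])
                else:
                    idxP = rng.integers(0, len(yP), len(yP))
                idxI = rng.integers(0, len(yI), len(yI))
                idxA = rng.integers(0, len(yA), len(yA))
            cP, sP = _ols_coefs(yP[idxP], XP[idxP])
            cI, sI = _ols_coefs(yI[idxI], XI[idxI])
            cA, sA = _ols_coefs(yA[idxA], XA[idxA])
        except np.linalg.LinAlgError:
            n_discarded += 1
            continue
        growth = GrowthCoefficients(cP[0], cP[1], cP[2], max(sP, 1e-9))
        init = InitialCoefficients(cI[1], cI[0], max(sI, 1e-9))
        allo = AllometryCoefficients(cA[0], cA[1], max(sA, 1e-9))
        for label, T in temps_scen.items():
            dists = project_cohort(init, growth, T, max_age, mesh)
            # length mapping: exact affine-Gaussian form of the constant-SD
            # size kernel, identical to the midpoint-rule map_to_length
            means = np.array(
                [allo.slope * d.mean() + allo.intercept for d in dists]
            )
            sds = np.sqrt(
                allo.slope**2 * np.array([d.var() for d in dists]) + allo.sigma**2
            )
            per_scenario_means[label].append(means)
            per_scenario_sds[label].append(sds)
    n_ok = B - n_discarded
    if n_ok == 0 or n_discarded > max_discard_frac * B:
        raise RuntimeError(
            f"{n_discarded}/{B} bootstrap replicates discarded (singular fits)"
        )

    summaries: dict[str, list[AgeSummary]] = {}
    for label in temps_scen:
        M = np.vstack(per_scenario_means[label])  # (n_ok, max_age)
        S = np.vstack(per_scenario_sds[label])
        out = []
        for a in range(max_age):
            means_a, sds_a = M[:, a], S[:, a]
            mean = float(means_a.mean())
            if n_ok == 1:
                ci = (mean, mean)
            elif pair_groups is not None:
                half = float(
                    stats.t.ppf(0.975, len(pair_groups) - 1)
                    * means_a.std(ddof=1)
                )
                ci = (mean - half, mean + half)
            else:
                ci = tuple(np.quantile(means_a, [0.025, 0.975]))
                ci = (min(ci[0], mean), max(ci[1], mean))
            # pooled predictive mixture across replicates
            pooled_var = float(np.mean(sds_a**2 + means_a**2) - mean**2)
            pi = (
                _mixture_quantile(means_a, sds_a, 0.025),
                _mixture_quantile(means_a, sds_a, 0.975),
            )
            pi = (min(pi[0], ci[0]), max(pi[1], ci[1]))
            out.append(
                AgeSummary(
                    age=a + 1,
                    mean=mean,
                    sd=float(np.sqrt(max(pooled_var, 0.0))),
                    ci95=ci,
                    pi95=pi,
                )
            )
        summaries[label] = out
    return ScenarioResult(
        temperatures=temps_scen,
        summaries=summaries,
        n_replicates=n_ok,
        n_discarded=n_discarded,
        seed=seed,
    )
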
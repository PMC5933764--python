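"""Size-size (Walford) growth models, allometry, and von Bertalanffy algebra.

The model suite mirrors the standard sclerochronology workflow:

* ``lm1``-style: Z' = b1*Z + a0 + e, the Walford regression of otolith
  radius in year t on radius in year t-1;
* ``lm2``-style: Z' = b1*Z + b2*T + a0 + e, adding the mean summer
  temperature of the year in which the increment grew;
* ``lm3``-style: Z = b1*T + a0 + e, first-annulus radius on the summer
  temperature of the first year of life (the initial-size model);
* ``lm4``-style: L = b1*Z + a0 + e, the otolith-radius -> body-length
  allometry, optionally with exponential variance Var(e) = s^2*exp(g*mu);
* ``mod1``..``mod3``-style: the Walford model with crossed random
  intercepts for formation year and individual fish, with or without the
  temperature fixed effect, fitted by maximum likelihood.

A Walford slope b1 in (0,1) maps onto von Bertalanffy parameters:
K = -ln(b1), Z_inf = a0/(1-b1) (at fixed temperature, the intercept is
b2*T + a0), L_inf through the allometry, and the growth-performance index
phi' = ln K + 2 ln(L_inf in cm).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import join_temperature

logger = logging.getLogger(__name__)

__all__ = [
    "SingularFitError",
    "LinearFitResults",
    "MixedFitResults",
    "VBParams",
    "WalfordModel",
    "InitialSizeModel",
    "AllometryModel",
    "MixedGrowthModel",
    "select_best_radius",
    "compare_models",
    "vb_transform",
    "phi_prime",
]


class SingularFitError(np.linalg.LinAlgError):
    """The design matrix is rank deficient (e.g. a constant covariate)."""


def _check_full_rank(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularFitError(
            f"design matrix is rank deficient ({X.shape[1]} columns, "
            f"rank {np.linalg.matrix_rank(X)})"
        )


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

class LinearFitResults:
    """Fitted linear model: named coefficients, covariance, residual SD.

    Attributes
    ----------
    params : pd.Series of named coefficients.
    bse : pd.Series of coefficient standard errors.
    cov_params : pd.DataFrame coefficient covariance matrix.
    resid_sd : residual standard deviation, response units.  For the
        exponential-variance model this is the *baseline* sigma of
        Var(e_i) = sigma^2 * exp(gamma * mu_i).
    rsquared, aic, llf, nobs : the usual fit statistics.
    variance_model : "constant" or "exp_in_covariate".
    gamma : exponential-variance coefficient (None for constant variance).
    """

    def __init__(
        self,
        name: str,
        params: Mapping[str, float],
        cov_params: pd.DataFrame,
        resid_sd: float,
        nobs: int,
        rsquared: float,
        llf: float,
        aic: float,
        response: str = "Zprime",
        variance_model: str = "constant",
        gamma: float | None = None,
    ):
        self.name = name
        self.params = pd.Series(dict(params), dtype=float)
        self.cov_params = cov_params
        self.bse = pd.Series(
            np.sqrt(np.diag(cov_params.to_numpy())), index=self.params.index
        )
        self.resid_sd = float(resid_sd)
        self.nobs = int(nobs)
        self.rsquared = float(rsquared)
        self.llf = float(llf)
        self.aic = float(aic)
        self.response = response
        self.variance_model = variance_model
        self.gamma = None if gamma is None else float(gamma)

    @property
    def is_mixed(self) -> bool:
        return False

    def predict(self, exog: pd.DataFrame | Mapping[str, float]) -> np.ndarray:
        """Evaluate the fitted mean at new covariate values."""
        if isinstance(exog, Mapping):
            exog = pd.DataFrame({k: np.atleast_1d(v) for k, v in exog.items()})
        out = np.full(len(exog), self.params.get("intercept", 0.0))
        for name, value in self.params.items():
            if name != "intercept":
                out = out + value * exog[name].to_numpy()
        return out

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "response": self.response,
            "params": self.params.to_dict(),
            "cov_params": self.cov_params.to_numpy().tolist(),
            "param_names": list(self.params.index),
            "resid_sd": self.resid_sd,
            "nobs": self.nobs,
            "rsquared": self.rsquared,
            "llf": self.llf,
            "aic": self.aic,
            "variance_model": self.variance_model,
            "gamma": self.gamma,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = [
            f"{self.name}: {self.response} ~ "
            + " + ".join(n for n in self.params.index),
            f"  n = {self.nobs}   R2 = {self.rsquared:.4f}   "
            f"AIC = {self.aic:.2f}",
        ]
        for name in self.params.index:
            lines.append(
                f"  {name:<12} {self.params[name]: .5f}  "
                f"(se {self.bse[name]:.5f})"
            )
        lines.append(f"  residual SD  {self.resid_sd:.5f}")
        if self.gamma is not None:
            lines.append(f"  variance model exp(gamma*mu), gamma = {self.gamma:.4f}")
        return "\n".join(lines)

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"<{type(self).__name__} {self.name} n={self.nobs}>"


class MixedFitResults(LinearFitResults):
    """Linear mixed model with crossed year/fish random intercepts.

    ``rsquared`` holds the marginal R^2 (fixed-effects variance over total
    variance); ``sd_year``/``sd_fish`` are the random-intercept SDs, with
    ``boundary`` flagging components estimated at the zero boundary.
    """

    def __init__(
        self,
        *args,
        sd_year: float | None = None,
        sd_fish: float | None = None,
        boundary: Mapping[str, bool] | None = None,
        converged: bool = True,
        **kwargs,
    ):
        super().__init__(*args, **kwargs)
        self.sd_year = None if sd_year is None else float(sd_year)
        self.sd_fish = None if sd_fish is None else float(sd_fish)
        self.boundary = dict(boundary or {})
        self.converged = bool(converged)

    @property
    def is_mixed(self) -> bool:
        return True

    @property
    def marginal_rsquared(self) -> float:
        return self.rsquared

    def to_dict(self) -> dict:
        out = super().to_dict()
        out.update(
            sd_year=self.sd_year,
            sd_fish=self.sd_fish,
            boundary=self.boundary,
            marginal_rsquared=self.rsquared,
            converged=self.converged,
        )
        return out

    def summary(self) -> str:
        lines = [super().summary()]
        if self.sd_year is not None:
            flag = " (boundary)" if self.boundary.get("year") else ""
            lines.append(f"  sd(year)     {self.sd_year:.5f}{flag}")
        if self.sd_fish is not None:
            flag = " (boundary)" if self.boundary.get("fish") else ""
            lines.append(f"  sd(fish)     {self.sd_fish:.5f}{flag}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# OLS helper
# ---------------------------------------------------------------------------

def _ols_fit(
    name: str,
    y: np.ndarray,
    X: pd.DataFrame,
    response: str,
) -> LinearFitResults:
    Xc = sm.add_constant(X, prepend=False, has_constant="add")
    Xc = Xc.rename(columns={"const": "intercept"})
    _check_full_rank(Xc.to_numpy())
    res = sm.OLS(y, Xc).fit()
    resid_sd = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
    return LinearFitResults(
        name=name,
        params=res.params.to_dict(),
        cov_params=res.cov_params(),
        resid_sd=resid_sd,
        nobs=int(res.nobs),
        rsquared=float(res.rsquared),
        llf=float(res.llf),
        aic=float(res.aic),
        response=response,
    )


# ---------------------------------------------------------------------------
# model classes
# ---------------------------------------------------------------------------

class WalfordModel:
    """Size-size growth regression Z' ~ Z (+ T), built from a growth-pair table.

    Parameters
    ----------
    pairs : growth-pair table with columns ``fish_id, year, Z, Zprime``.
    temps : optional annual temperature table; when given, the summer
        temperature of each pair's growth year enters as a covariate.
    source : temperature source label used for the join.
    name : label used in comparison tables; defaults to "walford" /
        "walford+T".
    """

    def __init__(
        self,
        pairs: pd.DataFrame,
        temps: pd.DataFrame | None = None,
        source: str = "mediterranean",
        name: str | None = None,
    ):
        if len(pairs) < 3:
            raise ValueError("need at least 3 growth pairs")
        self.pairs = pairs.reset_index(drop=True)
        self.temps = temps
        self.source = source
        self.with_temperature = temps is not None
        self.name = name or ("walford+T" if self.with_temperature else "walford")
        if self.with_temperature:
            self._data = join_temperature(self.pairs, temps, source)
        else:
            self._data = self.pairs

    def fit(self) -> LinearFitResults:
        cols = ["Z", "T"] if self.with_temperature else ["Z"]
        return _ols_fit(
            self.name,
            self._data["Zprime"].to_numpy(),
            self._data[cols],
            response="Zprime",
        )


class InitialSizeModel:
    """First-annulus radius on the summer temperature of the first year of
    life: Z = b1*T + a0 + e.  Input is a first-increments table
    (``year, Z``) plus the annual temperature table."""

    def __init__(
        self,
        first: pd.DataFrame,
        temps: pd.DataFrame,
        source: str = "mediterranean",
        name: str = "initial_size",
    ):
        if len(first) < 3:
            raise ValueError("need at least 3 first-increment rows")
        self.name = name
        self._data = join_temperature(first.reset_index(drop=True), temps, source)

    def fit(self) -> LinearFitResults:
        return _ols_fit(
            self.name,
            self._data["Z"].to_numpy(),
            self._data[["T"]],
            response="Z",
        )


class AllometryModel:
    """Otolith radius -> body size allometry: L = b1*Z + a0 + e.

    ``variance_model="constant"`` is ordinary least squares.
    ``variance_model="exp_in_covariate"`` models Var(e_i) =
    sigma^2 * exp(gamma * mu_i) with mu_i the fitted mean, estimated by
    iteratively re-weighted least squares (gamma from the regression of
    log squared residuals on the fitted mean).
    """

    MAX_ITER = 100
    TOL = 1e-8

    def __init__(
        self,
        fish: pd.DataFrame,
        response: str = "length",
        radius: str = "z4",
        variance_model: str = "constant",
        name: str = "allometry",
    ):
        if response not in ("length", "weight"):
            raise ValueError("response must be 'length' or 'weight'")
        if variance_model not in ("constant", "exp_in_covariate"):
            raise ValueError(f"unknown variance model {variance_model!r}")
        col = "total_length" if response == "length" else "weight"
        data = fish[[radius, col]].dropna()
        if len(data) < 3:
            raise ValueError("need at least 3 complete (Z, response) pairs")
        self.response = response
        self.radius = radius
        self.variance_model = variance_model
        self.name = name
        self._y = data[col].to_numpy(dtype=float)
        self._z = data[radius].to_numpy(dtype=float)

    def fit(self) -> LinearFitResults:
        X = pd.DataFrame({"Z": self._z})
        base = _ols_fit(self.name, self._y, X, response=self.response)
        if self.variance_model == "constant":
            return base
        return self._fit_exp_variance(base)

    def _fit_exp_variance(self, start: LinearFitResults) -> LinearFitResults:
        y, z = self._y, self._z
        Xc = np.column_stack([z, np.ones_like(z)])
        _check_full_rank(Xc)
        beta = np.array([start.params["Z"], start.params["intercept"]])
        gamma = 0.0
        for _ in range(self.MAX_ITER):
            mu = Xc @ beta
            resid = y - mu
            # log squared residuals regressed on the mean: slope estimates gamma
            lr = np.log(np.maximum(resid**2, 1e-300))
            A = np.column_stack([mu, np.ones_like(mu)])
            gamma_new = np.linalg.lstsq(A, lr, rcond=None)[0][0]
            w = np.exp(-gamma_new * mu)
            w = w / w.mean()
            WX = Xc * w[:, None]
            beta_new = np.linalg.solve(Xc.T @ WX, WX.T @ y)
            if (
                np.max(np.abs(beta_new - beta)) < self.TOL
                and abs(gamma_new - gamma) < self.TOL
            ):
                beta, gamma = beta_new, gamma_new
                break
            beta, gamma = beta_new, gamma_new
        else:
            raise RuntimeError(
                f"exponential-variance IRLS did not converge in "
                f"{self.MAX_ITER} iterations"
            )
        mu = Xc @ beta
        w = np.exp(-gamma * mu)
        res = sm.WLS(y, pd.DataFrame({"Z": z, "intercept": 1.0}), weights=w).fit()
        resid = y - mu
        # baseline sigma^2 of Var = sigma^2 exp(gamma mu)
        sigma2 = float(np.sum(resid**2 * w) / (len(y) - 2))
        return LinearFitResults(
            name=self.name,
            params={"Z": beta[0], "intercept": beta[1]},
            cov_params=res.cov_params(),
            resid_sd=np.sqrt(sigma2),
            nobs=len(y),
            rsquared=float(res.rsquared),
            llf=float(res.llf),
            aic=float(res.aic),
            response=self.response,
            variance_model="exp_in_covariate",
            gamma=gamma,
        )


class MixedGrowthModel:
    """Walford growth model with crossed random intercepts for formation
    year and individual fish, fitted by maximum likelihood.

    ML (not REML) is used throughout so that likelihoods and AICs remain
    comparable across models with different fixed-effects structures.
    Marginal R^2 follows Nakagawa & Schielzeth: variance of the fixed-effect
    predictions over the sum of fixed, random and residual variances.
    """

    #: variance components smaller than this (as SD, in response units of
    #: mm) are indistinguishable from the optimizer's boundary and flagged
    BOUNDARY_TOL = 1e-4

    def __init__(
        self,
        pairs: pd.DataFrame,
        temps: pd.DataFrame | None = None,
        source: str = "mediterranean",
        random_year: bool = True,
        random_fish: bool = True,
        name: str | None = None,
    ):
        self.random_year = bool(random_year)
        self.random_fish = bool(random_fish)
        if name is None:
            parts = ["mixed"]
            if random_year:
                parts.append("year")
            if random_fish:
                parts.append("fish")
            if temps is not None:
                parts.append("T")
            name = "+".join(parts)
        self.name = name
        self.with_temperature = temps is not None
        self._walford = WalfordModel(pairs, temps, source, name=name)
        self._data = self._walford._data
        if self.random_year and self._data["year"].nunique() < 2:
            raise ValueError("random year effect requires >= 2 years")
        if self.random_fish and self._data["fish_id"].nunique() < 2:
            raise ValueError("random fish effect requires >= 2 fish")

    def fit(self) -> LinearFitResults:
        if not (self.random_year or self.random_fish):
            # no random effects requested: plain OLS
            return self._walford.fit()
        data = self._data.copy()
        fixed_cols = ["Z", "T"] if self.with_temperature else ["Z"]
        exog = sm.add_constant(data[fixed_cols], prepend=False).rename(
            columns={"const": "intercept"}
        )
        _check_full_rank(exog.to_numpy())
        vc_formula = {}
        if self.random_year:
            vc_formula["year"] = "0 + C(year)"
        if self.random_fish:
            vc_formula["fish"] = "0 + C(fish_id)"
        data["_grp"] = 1  # single group: purely crossed variance components
        formula = "Zprime ~ " + " + ".join(fixed_cols)
        model = sm.MixedLM.from_formula(
            formula,
            groups="_grp",
            vc_formula=vc_formula,
            re_formula="0",
            data=data,
        )
        import warnings as _warnings

        # ML surfaces with near-boundary variance components can trap
        # gradient optimizers in local optima; fit with two optimizers and
        # keep the higher likelihood
        res = None
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            for method in ("lbfgs", "powell"):
                try:
                    cand = model.fit(reml=False, method=method, maxiter=1000)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if res is None or (cand.llf > res.llf and np.isfinite(cand.llf)):
                    res = cand
        if res is None:
            raise SingularFitError("mixed-model likelihood could not be optimized")

        k_fe = len(res.fe_params)
        cov = pd.DataFrame(
            np.asarray(res.cov_params())[:k_fe, :k_fe],
            index=res.fe_params.index,
            columns=res.fe_params.index,
        ).rename(index={"Intercept": "intercept"}, columns={"Intercept": "intercept"})
        params = res.fe_params.rename(index={"Intercept": "intercept"})
        # reorder to match the package convention (covariates then intercept)
        order = list(exog.columns)
        params = params.reindex(order)
        cov = cov.loc[order, order]
        vc_names = list(getattr(res.model.exog_vc, "names", vc_formula.keys()))
        vcomp = dict(zip(vc_names, np.asarray(res.vcomp, dtype=float)))
        sd_year = np.sqrt(max(vcomp.get("year", 0.0), 0.0)) if self.random_year else None
        sd_fish = np.sqrt(max(vcomp.get("fish", 0.0), 0.0)) if self.random_fish else None
        boundary = {}
        if sd_year is not None:
            boundary["year"] = bool(sd_year < self.BOUNDARY_TOL)
        if sd_fish is not None:
            boundary["fish"] = bool(sd_fish < self.BOUNDARY_TOL)
        resid_sd = float(np.sqrt(res.scale))

        # Nakagawa-Schielzeth marginal R^2
        fitted_fixed = exog.to_numpy() @ params.to_numpy()
        var_fixed = float(np.var(fitted_fixed))
        var_random = sum(max(v, 0.0) for v in vcomp.values())
        marginal_r2 = var_fixed / (var_fixed + var_random + res.scale)

        k_params = len(params) + len(vcomp) + 1  # fixed + vcomps + residual
        aic = -2.0 * float(res.llf) + 2.0 * k_params
        return MixedFitResults(
            name=self.name,
            params=params.to_dict(),
            cov_params=cov,
            resid_sd=resid_sd,
            nobs=len(data),
            rsquared=float(marginal_r2),
            llf=float(res.llf),
            aic=aic,
            response="Zprime",
            sd_year=sd_year,
            sd_fish=sd_fish,
            boundary=boundary,
            converged=bool(res.converged),
        )


# ---------------------------------------------------------------------------
# radius selection, model comparison
# ---------------------------------------------------------------------------

def select_best_radius(
    fish: pd.DataFrame, axes: Sequence[str] = ("z1", "z2", "z3", "z4")
) -> tuple[str, dict[str, float]]:
    """Pick the otolith growth axis whose lifetime radius best predicts
    total length (highest OLS R^2).  Ties break to the lowest axis index;
    axes with no data are excluded with a warning.
    """
    r2: dict[str, float] = {}
    for ax in axes:
        sub = fish[[ax, "total_length"]].dropna()
        if len(sub) < 3:
            logger.warning("axis %s excluded: fewer than 3 complete rows", ax)
            continue
        z = sub[ax].to_numpy(dtype=float)
        y = sub["total_length"].to_numpy(dtype=float)
        try:
            fit = _ols_fit(f"L~{ax}", y, pd.DataFrame({"Z": z}), "length")
        except SingularFitError:
            logger.warning("axis %s excluded: singular fit", ax)
            continue
        r2[ax] = fit.rsquared
    if not r2:
        raise ValueError("no usable radius axis")
    best = max(r2, key=lambda ax: (r2[ax], -axes.index(ax)))
    return best, r2


def compare_models(fits: Iterable[LinearFitResults]) -> pd.DataFrame:
    """AIC comparison table: delta AIC relative to the minimum-AIC model,
    sorted by AIC.  All fits must share the same number of rows (AICs are
    only comparable on identical response data)."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    ns = {f.nobs for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits have mismatched row counts {sorted(ns)}; "
                         "AIC values are not comparable")
    rows = [
        {
            "model": f.name,
            "mixed": f.is_mixed,
            "n": f.nobs,
            "r2": None if f.is_mixed else f.rsquared,
            "marginal_r2": f.rsquared if f.is_mixed else None,
            "aic": f.aic,
        }
        for f in fits
    ]
    table = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    return table


# ---------------------------------------------------------------------------
# von Bertalanffy algebra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VBParams:
    """von Bertalanffy quantities derived from a Walford fit.

    K in 1/yr; Z_inf (asymptotic otolith radius) in mm; L_inf (asymptotic
    total length) in mm; phi_prime = ln K + 2 ln(L_inf/10), i.e. with
    length in centimetres, the convention under which published values for
    this index are comparable.
    """

    K: float
    Z_inf: float
    L_inf: float
    phi_prime: float

    def to_dict(self) -> dict:
        return {
            "K_per_year": self.K,
            "Z_inf_mm": self.Z_inf,
            "L_inf_mm": self.L_inf,
            "phi_prime": self.phi_prime,
        }


def phi_prime(K: float, L_inf_mm: float) -> float:
    """Growth-performance index phi' = ln K + 2 ln(L_inf in cm).

    NaN when L_inf is non-positive (the allometry extrapolated below its
    support), since the index is undefined there.
    """
    if K <= 0 or L_inf_mm <= 0:
        return float("nan")
    return float(np.log(K) + 2.0 * np.log(L_inf_mm / 10.0))


def vb_transform(
    walford: LinearFitResults | tuple[float, float],
    allometry: LinearFitResults | tuple[float, float],
) -> VBParams:
    """Map a Walford fit (slope, intercept) and an allometry fit to
    von Bertalanffy parameters.

    K = -ln(slope); Z_inf = intercept/(1 - slope) (the fixed point of the
    Walford recursion); L_inf = allometry applied to Z_inf.  Requires the
    Walford slope in (0, 1), otherwise the recursion has no finite
    attracting fixed point.

    Both arguments accept either a fitted results object or a plain
    ``(slope, intercept)`` tuple.
    """
    if isinstance(walford, LinearFitResults):
        slope, intercept = float(walford.params["Z"]), float(
            walford.params["intercept"]
        )
    else:
        slope, intercept = map(float, walford)
    if isinstance(allometry, LinearFitResults):
        a_slope, a_intercept = float(allometry.params["Z"]), float(
            allometry.params["intercept"]
        )
    else:
        a_slope, a_intercept = map(float, allometry)
    if not (0.0 < slope < 1.0):
        raise ValueError(
            f"Walford slope {slope} outside (0, 1): no finite asymptote"
        )
    K = -float(np.log(slope))
    Z_inf = intercept / (1.0 - slope)
    L_inf = a_slope * Z_inf + a_intercept
    return VBParams(K=K, Z_inf=Z_inf, L_inf=L_inf, phi_prime=phi_prime(K, L_inf))
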
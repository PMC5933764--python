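"""Growth regressions, mixed models, model comparison and VB algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from otogrowth import (
    AllometryModel,
    InitialSizeModel,
    MixedGrowthModel,
    WalfordModel,
    compare_models,
    select_best_radius,
    vb_transform,
)
from otogrowth.io import TemperatureJoinError
from otogrowth.models import SingularFitError, phi_prime

from conftest import constant_temps


def pair_table(Z, Zprime, years=None, fish=None):
    n = len(Z)
    return pd.DataFrame(
        {
            "fish_id": fish if fish is not None else [f"F{i}" for i in range(n)],
            "year": years if years is not None else np.full(n, 2005),
            "Z": Z,
            "Zprime": Zprime,
        }
    )


class TestWalford:
    def test_noiseless_exact(self):
        Z = np.linspace(1.0, 2.5, 10)
        fit = WalfordModel(pair_table(Z, 0.7 * Z + 0.8)).fit()
        assert fit.params["Z"] == pytest.approx(0.7, abs=1e-12)
        assert fit.params["intercept"] == pytest.approx(0.8, abs=1e-12)
        assert fit.resid_sd == pytest.approx(0.0, abs=1e-10)
        assert fit.rsquared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        Z = rng.uniform(1.0, 2.5, 180)
        Zp = 0.71 * Z + 0.815 + rng.normal(0, 0.08, 180)
        fit = WalfordModel(pair_table(Z, Zp)).fit()
        # independent normal-equations solution
        X = np.column_stack([Z, np.ones_like(Z)])
        beta = np.linalg.solve(X.T @ X, X.T @ Zp)
        assert fit.params["Z"] == pytest.approx(beta[0], abs=1e-10)
        assert fit.params["intercept"] == pytest.approx(beta[1], abs=1e-10)
        # and estimates land within 3 SE of the generating truth
        assert abs(fit.params["Z"] - 0.71) < 3 * fit.bse["Z"]
        assert abs(fit.params["intercept"] - 0.815) < 3 * fit.bse["intercept"]

    def test_constant_Z_is_singular(self):
        with pytest.raises(SingularFitError):
            WalfordModel(pair_table(np.full(5, 1.5), np.full(5, 1.9))).fit()

    def test_needs_three_rows(self):
        with pytest.raises(ValueError):
            WalfordModel(pair_table([1.0, 2.0], [1.5, 2.5]))


class TestWalfordTemperature:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(0)
        years = np.repeat(np.arange(2001, 2011), 10)
        temps = constant_temps(range(2001, 2011), 0.0)
        temps["temperature"] = 20.0 + 0.8 * np.sin(np.arange(len(temps)))
        tmap = temps.set_index("year")["temperature"]
        Z = rng.uniform(1.0, 2.5, len(years))
        T = tmap[years].to_numpy()
        Zp = 0.7033 * Z - 0.0631 * T + 2.120
        fit = WalfordModel(pair_table(Z, Zp, years=years), temps).fit()
        assert fit.params["Z"] == pytest.approx(0.7033, abs=1e-9)
        assert fit.params["T"] == pytest.approx(-0.0631, abs=1e-9)
        assert fit.params["intercept"] == pytest.approx(2.120, abs=1e-7)

    def test_negative_temperature_effect_recovered(self):
        # repeated-simulation tally: with a true effect of -0.063 mm/degC
        # the sign should be recovered in at least 95/100 replicates
        hits = 0
        root = np.random.SeedSequence(7)
        for child in root.spawn(100):
            rng = np.random.default_rng(child)
            years = rng.integers(2001, 2012, 400)
            t_by_year = dict(
                zip(range(2001, 2012), 20.5 + 0.5 * rng.standard_normal(11))
            )
            T = np.array([t_by_year[y] for y in years])
            Z = rng.uniform(1.0, 2.5, 400)
            Zp = 0.7033 * Z - 0.063 * T + 2.12 + rng.normal(0, 0.08, 400)
            X = np.column_stack([Z, T, np.ones_like(Z)])
            beta = np.linalg.lstsq(X, Zp, rcond=None)[0]
            hits += beta[1] < 0
        assert hits >= 95

    def test_year_without_temperature_is_join_error(self):
        temps = constant_temps([2001], 20.0)
        with pytest.raises(TemperatureJoinError):
            WalfordModel(
                pair_table([1.0, 1.5, 2.0], [1.5, 1.9, 2.2],
                           years=[2001, 2001, 2002]),
                temps,
            ).fit()


class TestInitialSize:
    def test_noiseless_exact(self):
        years = np.arange(2001, 2011)
        temps = constant_temps(years, 0.0)
        temps["temperature"] = 19.0 + 0.3 * np.arange(10)
        T = temps["temperature"].to_numpy()
        first = pd.DataFrame({"year": years, "Z": 2.937 - 0.0718 * T})
        fit = InitialSizeModel(first, temps).fit()
        assert fit.params["T"] == pytest.approx(-0.0718, abs=1e-10)
        assert fit.params["intercept"] == pytest.approx(2.937, abs=1e-8)
        # fitted line at the reference summer temperature
        assert fit.predict({"T": 20.48})[0] == pytest.approx(
            2.937 - 0.0718 * 20.48, abs=1e-9
        )
        assert fit.predict({"T": 20.48})[0] == pytest.approx(1.4665, abs=5e-5)

    def test_constant_temperature_singular(self):
        years = np.arange(2001, 2006)
        temps = constant_temps(years, 20.0)
        first = pd.DataFrame({"year": years, "Z": np.linspace(1.3, 1.6, 5)})
        with pytest.raises(SingularFitError):
            InitialSizeModel(first, temps).fit()


class TestAllometry:
    @staticmethod
    def fish_frame(Z, L, W=None):
        return pd.DataFrame(
            {
                "z4": Z,
                "total_length": L,
                "weight": W if W is not None else np.full(len(Z), np.nan),
            }
        )

    def test_noiseless_exact(self):
        Z = np.linspace(1.0, 3.0, 20)
        fit = AllometryModel(self.fish_frame(Z, 176.38 * Z - 74.62)).fit()
        assert fit.params["Z"] == pytest.approx(176.38, abs=1e-8)
        assert fit.params["intercept"] == pytest.approx(-74.62, abs=1e-7)

    def test_weight_response_label(self):
        Z = np.linspace(1.0, 3.0, 20)
        fit = AllometryModel(
            self.fish_frame(Z, 100 * Z, W=50 * Z + 5), response="weight"
        ).fit()
        assert fit.response == "weight"
        assert fit.params["Z"] == pytest.approx(50.0, abs=1e-8)

    def test_variance_models_agree_within_2se(self):
        rng = np.random.default_rng(3)
        Z = rng.uniform(0.8, 3.0, 400)
        mu = 176.0 * Z - 74.0
        sd = 8.0 * np.exp(0.0015 * mu)  # mild exponential heteroscedasticity
        L = mu + rng.normal(0, sd)
        fish = self.fish_frame(Z, L)
        ols = AllometryModel(fish).fit()
        het = AllometryModel(fish, variance_model="exp_in_covariate").fit()
        assert het.gamma is not None and het.gamma > 0
        for name in ("Z", "intercept"):
            se = max(ols.bse[name], het.bse[name])
            assert abs(ols.params[name] - het.params[name]) < 2 * se
            assert abs(het.params[name] - (176.0 if name == "Z" else -74.0)) < 3 * se


class TestRadiusSelection:
    def test_constructed_ordering_selects_informative_axis(self):
        rng = np.random.default_rng(5)
        z4 = rng.uniform(1.0, 3.0, 100)
        fish = pd.DataFrame(
            {
                "z1": z4 * 0.8 + rng.normal(0, 0.6, 100),
                "z2": z4 * 0.85 + rng.normal(0, 0.6, 100),
                "z3": z4 * 0.9 + rng.normal(0, 0.6, 100),
                "z4": z4,
                "total_length": 176.0 * z4 - 74.0 + rng.normal(0, 5, 100),
            }
        )
        best, r2 = select_best_radius(fish)
        assert best == "z4"
        assert r2["z4"] == max(r2.values())

    def test_identical_axes_tie_breaks_to_lowest(self):
        z = np.linspace(1, 3, 30)
        fish = pd.DataFrame(
            {"z1": z, "z2": z, "z3": z, "z4": z, "total_length": 100 * z + 1}
        )
        best, r2 = select_best_radius(fish)
        assert best == "z1"

    def test_noiseless_axis_has_unit_r2(self):
        rng = np.random.default_rng(6)
        z2 = np.linspace(1, 3, 30)
        fish = pd.DataFrame(
            {
                "z1": rng.uniform(1, 3, 30),
                "z2": z2,
                "z3": rng.uniform(1, 3, 30),
                "z4": rng.uniform(1, 3, 30),
                "total_length": 150 * z2 + 3,
            }
        )
        best, r2 = select_best_radius(fish)
        assert best == "z2"
        assert r2["z2"] == pytest.approx(1.0)


class TestMixedGrowth:
    def test_no_random_effects_degenerates_to_ols(self, small_tables):
        pairs, _, _, temps = small_tables
        mixed = MixedGrowthModel(
            pairs, temps, random_year=False, random_fish=False
        ).fit()
        ols = WalfordModel(pairs, temps).fit()
        assert np.allclose(mixed.params, ols.params)

    def test_zero_variance_world_matches_ols(self):
        # generate pairs with no year/fish structure at all
        rng = np.random.default_rng(10)
        years = rng.integers(2001, 2011, 400)
        fish_ids = [f"F{i // 2}" for i in range(400)]
        Z = rng.uniform(1.0, 2.5, 400)
        Zp = 0.7 * Z + 0.8 + rng.normal(0, 0.08, 400)
        pairs = pair_table(Z, Zp, years=years, fish=fish_ids)
        mixed = MixedGrowthModel(pairs).fit()
        X = np.column_stack([Z, np.ones_like(Z)])
        beta = np.linalg.solve(X.T @ X, X.T @ Zp)
        assert mixed.params["Z"] == pytest.approx(beta[0], abs=1e-4)
        assert mixed.params["intercept"] == pytest.approx(beta[1], abs=1e-4)
        # variance components land on the zero boundary: flagged, not an error
        assert mixed.boundary == {"year": True, "fish": True}

    def test_variance_components_recovered(self, small_world):
        config, increments, _, temps = small_world
        from otogrowth.io import build_growth_pairs

        pairs = build_growth_pairs(increments)
        fit = MixedGrowthModel(pairs, temps).fit()
        assert fit.sd_year == pytest.approx(config.sd_year, rel=1.0)
        assert fit.sd_fish == pytest.approx(config.sd_fish, rel=1.0)
        assert fit.resid_sd == pytest.approx(config.sigma_growth, rel=0.5)
        assert 0.0 <= fit.marginal_rsquared <= 1.0


class TestComparison:
    def test_single_model_delta_zero(self, small_tables):
        pairs, _, _, temps = small_tables
        table = compare_models([WalfordModel(pairs).fit()])
        assert table["delta_aic"].tolist() == [0.0]

    def test_identical_fits_both_zero(self, small_tables):
        pairs, _, _, temps = small_tables
        fit = WalfordModel(pairs).fit()
        table = compare_models([fit, fit])
        assert np.allclose(table["delta_aic"], 0.0)

    def test_mismatched_n_rejected(self, small_tables):
        pairs, _, _, temps = small_tables
        f1 = WalfordModel(pairs).fit()
        f2 = WalfordModel(pairs.iloc[:-5], temps).fit()
        with pytest.raises(ValueError, match="not comparable"):
            compare_models([f1, f2])

    def test_temperature_model_wins_aic_under_true_effect(self):
        # simulation tally: with a real temperature effect the
        # temperature model should attain the lower AIC almost always
        wins = 0
        root = np.random.SeedSequence(21)
        for child in root.spawn(100):
            rng = np.random.default_rng(child)
            years = rng.integers(2001, 2012, 500)
            t_by_year = dict(
                zip(range(2001, 2012), 20.5 + 0.5 * rng.standard_normal(11))
            )
            temps = pd.DataFrame(
                {
                    "source": "mediterranean",
                    "year": list(t_by_year),
                    "temperature": list(t_by_year.values()),
                }
            )
            T = np.array([t_by_year[y] for y in years])
            Z = rng.uniform(1.0, 2.5, 500)
            Zp = 0.7033 * Z - 0.063 * T + 2.12 + rng.normal(0, 0.08, 500)
            pairs = pair_table(Z, Zp, years=years)
            aic_plain = WalfordModel(pairs).fit().aic
            aic_temp = WalfordModel(pairs, temps).fit().aic
            wins += aic_temp < aic_plain
        assert wins >= 90


class TestVonBertalanffy:
    def test_closed_form_simple_case(self):
        vb = vb_transform((0.5, 1.0), (1.0, 0.0))
        assert vb.Z_inf == pytest.approx(2.0, abs=1e-14)
        assert vb.K == pytest.approx(np.log(2.0), abs=1e-14)

    def test_slope_outside_unit_interval_rejected(self):
        for slope in (1.0, 1.2, 0.0, -0.5):
            with pytest.raises(ValueError):
                vb_transform((slope, 1.0), (176.0, -74.0))

    def test_phi_prime_uses_centimetres(self):
        assert phi_prime(0.343, 420.0) == pytest.approx(
            np.log(0.343) + 2 * np.log(42.0), abs=1e-12
        )

    @given(
        slope=st.floats(0.05, 0.95),
        intercept=st.floats(0.1, 3.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_fixed_point_identities(self, slope, intercept):
        vb = vb_transform((slope, intercept), (176.38, -74.62))
        # Z_inf * (1 - slope) = intercept, exactly
        assert vb.Z_inf * (1 - slope) == pytest.approx(intercept, rel=1e-12)
        # applying the Walford map at Z_inf returns Z_inf
        assert slope * vb.Z_inf + intercept == pytest.approx(vb.Z_inf, rel=1e-12)
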
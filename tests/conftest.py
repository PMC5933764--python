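"""Shared fixtures: published reference coefficients and synthetic worlds."""

import numpy as np
import pandas as pd
import pytest

from otogrowth import CohortProjection, io, synthetic

# Published bootstrap-mean regression coefficients for Gulf of Lions
# gilthead seabream (growth kernel, initial-size model, length allometry).
# Residual SDs are unpublished; the values here are the package defaults.
REF_GROWTH = dict(beta1=0.7033, beta2=-0.0631, alpha0=2.120, sigma=0.08)
REF_INITIAL = dict(intercept=2.937, slope=-0.0718, sigma=0.20)
REF_ALLOMETRY = dict(slope=176.38, intercept=-74.62, sigma=20.0)
REFERENCE_T = 20.48


@pytest.fixture(scope="session")
def ref_projection() -> CohortProjection:
    return CohortProjection.from_coefficients(
        REF_GROWTH, REF_INITIAL, REF_ALLOMETRY, n_nodes=500
    )


@pytest.fixture(scope="session")
def small_world():
    """A modest synthetic population shared by read-only tests."""
    config = synthetic.TruthConfig(seed=11, n_fish=150)
    increments, fish, temps = synthetic.generate_population(config)
    return config, increments, fish, temps


@pytest.fixture(scope="session")
def small_tables(small_world):
    _, increments, fish, temps = small_world
    return (
        io.build_growth_pairs(increments),
        io.first_increments(increments),
        fish,
        temps,
    )


def make_increments(radii_by_fish: dict[str, list[float]], spawn_year: int = 2000):
    """Increment table from per-fish cumulative radii lists."""
    rows = []
    for fish_id, radii in radii_by_fish.items():
        prev = 0.0
        for j, r in enumerate(radii):
            rows.append(
                dict(
                    fish_id=fish_id,
                    spawn_year=spawn_year,
                    increment_index=j,
                    formation_year=spawn_year + j,
                    width=r - prev,
                    cumulative_radius=r,
                )
            )
            prev = r
    return pd.DataFrame(rows)


def constant_temps(years, value, source="mediterranean"):
    return pd.DataFrame(
        {"source": source, "year": list(years), "temperature": value}
    )
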
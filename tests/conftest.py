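"""Shared fixtures: small unit tables and simulation designs used across tests."""

import numpy as np
import pandas as pd
import pytest

from nbrspf import Region, SimulationSpec, UnitTable


def make_covariate_units(n, seed, covs=("x",), radius=100.0):
    """Unit table with random uniform/normal covariates (no geometry semantics)."""
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "unit_id": [f"u{i:05d}" for i in range(n)],
            "center_x": rng.uniform(0, 1000, n),
            "center_y": rng.uniform(0, 1000, n),
            "radius": radius,
        }
    )
    for i, c in enumerate(covs):
        frame[c] = rng.uniform(0, 1, n) if i == 0 else rng.normal(0, 1, n)
    return UnitTable(frame)


L_SMALL = 3200.0

#: covariates that are linear at the scale of a sampling unit, so the
#: log-linear unit-count model holds exactly and truth is known
LINEAR_SURFACES = {
    "gx": lambda x, y: x / 1000.0,
    "gy": lambda x, y: y / 1000.0,
}

#: adds a fine-scale habitat field left out of the fitted model
PANEL_SURFACES = dict(
    LINEAR_SURFACES,
    ridge=lambda x, y: np.sin(2 * np.pi * x / 1500.0) * np.sin(2 * np.pi * y / 1500.0),
)


def homogeneous_spec(n_animals=10, fixes=200):
    """All animals share one coefficient vector; model correctly specified."""
    return SimulationSpec(
        region=Region(0.0, 0.0, L_SMALL, L_SMALL),
        surfaces=LINEAR_SURFACES,
        beta={"gx": 0.8, "gy": -0.6},
        coef_sd={},
        n_animals=n_animals,
        fixes_per_animal=fixes,
        lattice_resolution=50.0,
        unit_radius=150.0,
        unit_spacing=320.0,
    )


def panel_spec(n_animals=10, fixes=250):
    """Among-animal coefficient heterogeneity plus an unmodelled habitat field."""
    return SimulationSpec(
        region=Region(0.0, 0.0, L_SMALL, L_SMALL),
        surfaces=PANEL_SURFACES,
        beta={"gx": 0.8, "gy": -0.6, "ridge": 1.8},
        coef_sd={"gx": 0.4, "gy": 0.4, "ridge": 0.6},
        n_animals=n_animals,
        fixes_per_animal=fixes,
        lattice_resolution=50.0,
        unit_radius=150.0,
        unit_spacing=320.0,
        fit_covariates=("gx", "gy"),
    )


@pytest.fixture(scope="session")
def small_units():
    return make_covariate_units(400, seed=7, covs=("x", "z"))
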
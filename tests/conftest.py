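"""Shared fixtures: small synthetic study configurations and toy isoscapes."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from isoassign.grids import Grid, Raster
from isoassign.isoscape import Isoscape
from isoassign.simulate import SimConfig, generate_true_field, simulate_individuals
from isoassign.variogram import VariogramModel

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Down-scaled study: 12 locations over 220x260 km, short-range field."""
    return SimConfig(
        extent=(0.0, 220.0, 0.0, 260.0),
        n_locations=12,
        grid_cell=10.0,
        spatial_range=60.0,
        district_center=(60.0, 190.0),
        min_separation=25.0,
        n_late_year_locations=(2, 2),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_fields(small_config):
    return {
        iso: generate_true_field(small_config, iso) for iso in ("d2H", "d34S")
    }


@pytest.fixture(scope="session")
def small_records(small_config, small_fields) -> pd.DataFrame:
    return simulate_individuals(small_config, small_fields)


def make_isoscape(grid: Grid, values, isotope: str = "d2H") -> Isoscape:
    """Isoscape wrapper around explicit per-cell means (no kriging)."""
    values = np.broadcast_to(np.asarray(values, dtype=float), (grid.ny, grid.nx))
    model = VariogramModel("spherical", nugget=0.0, partial_sill=1.0, range_=50.0)
    return Isoscape(
        isotope=isotope,
        mean=Raster(grid, np.array(values)),
        variance=Raster(grid, np.zeros((grid.ny, grid.nx))),
        model=model,
    )


@pytest.fixture
def toy_grid() -> Grid:
    return Grid(xmin=0.0, ymin=0.0, cell=2.0, nx=8, ny=6)
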
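import numpy as np
import pytest

from phanerodiv import ModelParams, WorldConfig, build_world
from phanerodiv.world import GONE, LAND, OCEAN, SHELF, AnnotatedGrid, WorldHistory


@pytest.fixture(scope="session")
def tiny_world():
    """A small drifting world exercising every habitat transition."""
    cfg = WorldConfig(
        n_slices=20,
        slice_spacing=5.0,
        start_age=541.0,
        grid_resolution=6.0,
        n_continental_points=40,
        n_ocean_points=120,
        seed=42,
    )
    return build_world(cfg)


@pytest.fixture(scope="session")
def constant_env_world():
    """One permanently flooded shelf point in a constant environment.

    101 slices at 1 Myr spacing give a 100 Myr run with no habitat change,
    no noise and a degenerate (single-value) environment envelope.
    """
    cfg = WorldConfig(
        n_slices=101,
        slice_spacing=1.0,
        start_age=100.0,
        grid_resolution=6.0,
        n_continental_points=1,
        n_ocean_points=0,
        temp_equator=20.0,
        temp_pole=20.0,
        temp_noise=0.0,
        poc_noise=0.0,
        flood_cycle_params={"kind": "fixed", "mean_flooded": 1000, "mean_emergent": 1, "start_flooded": True},
        seed=0,
    )
    return build_world(cfg)


@pytest.fixture
def saturating_params():
    """Rate pinned at 0.035 Myr^-1 and carrying capacity pinned at 123."""
    return ModelParams(rho_min=0.035, rho_max=0.035, k_min=123.0, k_max=123.0)


def manual_world(lat, lon, habitat, temp, poc, slice_ages, resolution=6.0, age=None):
    """Hand-built WorldHistory from (S, P) state arrays, for engine tests."""
    lat = np.asarray(lat, dtype=float)
    habitat = np.asarray(habitat, dtype=np.int8)
    S, P = habitat.shape
    nlat = int(round(180.0 / resolution))
    nlon = 2 * nlat
    if age is None:
        age = np.where((habitat == OCEAN) | (habitat == SHELF), 0.0, np.nan)
    grids = [
        AnnotatedGrid(
            class_map=np.full((nlat, nlon), OCEAN, dtype=np.int8),
            age_map=np.full((nlat, nlon), np.nan),
        )
        for _ in range(S)
    ]
    cfg = WorldConfig(
        n_slices=S,
        slice_spacing=float(slice_ages[0] - slice_ages[1]),
        start_age=float(slice_ages[0]),
        grid_resolution=resolution,
        n_continental_points=0,
        n_ocean_points=0,
    )
    return WorldHistory(
        config=cfg,
        slice_ages=np.asarray(slice_ages, dtype=float),
        point_ids=np.arange(P),
        origin=np.array(["continental"] * P),
        lat=lat,
        lon=np.asarray(lon, dtype=float),
        habitat=habitat,
        age=np.asarray(age, dtype=float),
        temp=np.asarray(temp, dtype=float),
        poc=np.asarray(poc, dtype=float),
        grids=grids,
    )
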
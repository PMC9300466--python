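"""Saturation diagnostics, zonal summaries and in-silico experiments.

The saturation ratio D/K_eff measures how close a regional biota sits to
its ecological limit (ratios near one: saturated hotspots; near zero: far
from the limit). Area weighting uses cos(latitude) cell weights. The two
in-silico experiments re-run the engine under modified forcing: a static
(frozen-geography) null, and toggling of individual mass-extinction events.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import DiversityHistory, ModelParams, simulate
from .transects import DecayParams, DiversityGrid, global_diversity_curve, slice_diversity_grid
from .world import LAND, SHELF, ExtinctionSchedule, WorldHistory, cell_centers

__all__ = [
    "SaturationMap",
    "ExperimentReport",
    "saturation_ratio_map",
    "area_weighted_histogram",
    "zonal_mean_profile",
    "quantile_normalize_map",
    "freeze_world",
    "static_geography_experiment",
    "extinction_toggle_experiment",
]


@dataclass
class SaturationMap:
    """Per-cell D/K_eff ratios with habitat classes and cos-latitude weights."""

    ratio: np.ndarray  # (nlat, nlon), NaN = unpopulated
    class_map: np.ndarray
    weights: np.ndarray  # (nlat,) cell-area weights proportional to cos(lat)
    resolution: float


@dataclass
class ExperimentReport:
    """Paired-run comparison: per-cell log differences and/or curves."""

    label: str
    cell_table: pd.DataFrame | None = None  # row, col, log10_diff
    curve_table: pd.DataFrame | None = None  # age_ma, gamma_default, gamma_experiment, ratio
    summary: dict | None = None


def saturation_ratio_map(
    history: DiversityHistory,
    world: WorldHistory,
    s: int,
    decay: DecayParams | None = None,
) -> SaturationMap:
    """Rasterized D/K_eff for one slice of a logistic run."""
    if history.model_kind != "logistic":
        raise ValueError("saturation ratios require a logistic run with recorded K_eff")
    decay = decay or DecayParams()
    act = world.active(s)
    ratio_points = history.D[s, act] / history.k_eff[s, act]
    from .transects import rasterize_points

    grid = rasterize_points(
        world.lat[s, act],
        world.lon[s, act],
        ratio_points,
        world.habitat[s, act],
        world.grids[s],
        world.config.grid_resolution,
        radius_km=decay.interp_radius_km,
        trough_backfill=False,  # the unit-richness trough convention is not a ratio
    )
    ratio = grid.diversity
    lat_c, _ = cell_centers(world.config.grid_resolution)
    return SaturationMap(
        ratio=ratio,
        class_map=grid.class_map,
        weights=np.cos(np.radians(lat_c)),
        resolution=world.config.grid_resolution,
    )


def area_weighted_histogram(
    smap: SaturationMap,
    bins=(0.0, 0.25, 0.5, 0.75, 1.0),
    habitat_class: int | None = SHELF,
) -> pd.DataFrame:
    """Cos-latitude-weighted area percentages of the ratio per bin."""
    bins = np.asarray(bins, dtype=float)
    mask = np.isfinite(smap.ratio)
    if habitat_class is not None:
        mask &= smap.class_map == habitat_class
    if not mask.any():
        raise ValueError("no populated cells in the selected class")
    w2d = np.broadcast_to(smap.weights[:, None], smap.ratio.shape)
    vals = smap.ratio[mask]
    wts = w2d[mask]
    idx = np.clip(np.digitize(vals, bins) - 1, 0, len(bins) - 2)
    pct = np.zeros(len(bins) - 1)
    for i in range(len(bins) - 1):
        pct[i] = wts[idx == i].sum()
    pct = 100.0 * pct / wts.sum()
    return pd.DataFrame({"bin_lo": bins[:-1], "bin_hi": bins[1:], "pct": pct})


def zonal_mean_profile(grid: DiversityGrid, band_width: float = 20.0) -> pd.DataFrame:
    """Area-weighted mean diversity per latitudinal band (9 bands at 20 deg)."""
    nlat, _ = grid.shape
    lat_c, _ = cell_centers(grid.resolution)
    w2d = np.broadcast_to(np.cos(np.radians(lat_c))[:, None], grid.diversity.shape)
    edges = np.arange(-90.0, 90.0 + band_width / 2, band_width)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = np.isfinite(grid.diversity) & (lat_c[:, None] >= lo) & (lat_c[:, None] < hi)
        if m.any():
            mean = float(np.average(grid.diversity[m], weights=w2d[m]))
        else:
            mean = np.nan
        rows.append((lo, hi, mean))
    return pd.DataFrame(rows, columns=["band_lo", "band_hi", "mean_diversity"])


def quantile_normalize_map(grid: DiversityGrid, lower: float = 0.05, upper: float = 0.95) -> np.ndarray:
    """Affine map of [q_lower, q_upper] onto [0, 1], clamped outside."""
    vals = grid.diversity[np.isfinite(grid.diversity)]
    if vals.size < 2 or vals.min() == vals.max():
        raise ValueError("need at least two distinct populated values")
    qlo, qhi = np.quantile(vals, [lower, upper])
    if qhi == qlo:
        raise ValueError("degenerate quantile range")
    return np.clip((grid.diversity - qlo) / (qhi - qlo), 0.0, 1.0)


def freeze_world(world: WorldHistory, freeze_slice: int) -> WorldHistory:
    """A copy of the world with geography and environment frozen at one slice.

    Every slice repeats the frozen slice's point states, environments and
    raster; slice ages are kept so the run spans the same duration.
    """
    if not 0 <= freeze_slice < world.n_slices:
        raise IndexError(f"freeze_slice {freeze_slice} out of range")
    S = world.n_slices
    frozen = copy.deepcopy(world)
    for arr_name in ("lat", "lon", "habitat", "age", "temp", "poc"):
        arr = getattr(frozen, arr_name)
        arr[:] = np.broadcast_to(arr[freeze_slice], arr.shape).copy()
    frozen.grids = [copy.deepcopy(world.grids[freeze_slice]) for _ in range(S)]
    return frozen


def _normalized_log_grid(history, world, s, decay, floor=1e-6):
    grid = slice_diversity_grid(history, world, s, decay)
    vals = grid.diversity[np.isfinite(grid.diversity)]
    if vals.size < 2 or vals.min() == vals.max():
        raise ValueError("cannot normalize a constant or empty diversity map")
    norm = (grid.diversity - vals.min()) / (vals.max() - vals.min())
    return grid, np.log10(np.maximum(norm, floor))


def static_geography_experiment(
    world: WorldHistory,
    params: ModelParams | None = None,
    schedule: ExtinctionSchedule | None = None,
    freeze_slice: int = 0,
    decay: DecayParams | None = None,
    compare_slice: int | None = None,
) -> ExperimentReport:
    """Frozen-geography null run compared against the moving-geography run.

    Both runs are rasterized at ``compare_slice`` (default: the last slice),
    min-max normalized, and compared cell-by-cell as log10 differences
    (experiment minus default). Cells populated in only one run are missing.
    """
    params = params or ModelParams()
    decay = decay or DecayParams()
    compare_slice = world.n_slices - 1 if compare_slice is None else compare_slice
    default_hist = simulate(world, params, schedule)
    frozen = freeze_world(world, freeze_slice)
    frozen_hist = simulate(frozen, params, schedule)
    _, log_def = _normalized_log_grid(default_hist, world, compare_slice, decay)
    _, log_frz = _normalized_log_grid(frozen_hist, frozen, compare_slice, decay)
    both = np.isfinite(log_def) & np.isfinite(log_frz)
    r, c = np.where(both)
    diff = log_frz[both] - log_def[both]
    table = pd.DataFrame({"row": r, "col": c, "log10_diff": diff})
    summary = {
        "n_cells": int(both.sum()),
        "mean_log10_diff": float(diff.mean()) if diff.size else np.nan,
        "max_abs_log10_diff": float(np.abs(diff).max()) if diff.size else np.nan,
    }
    return ExperimentReport(label="static_geography", cell_table=table, summary=summary)


def extinction_toggle_experiment(
    world: WorldHistory,
    params: ModelParams | None = None,
    schedule: ExtinctionSchedule | None = None,
    disabled_event_ids=(),
    decay: DecayParams | None = None,
) -> ExperimentReport:
    """Paired runs with and without selected mass-extinction events.

    Reports the two global curves and their ratio through time."""
    params = params or ModelParams()
    decay = decay or DecayParams()
    if schedule is None:
        schedule = ExtinctionSchedule(np.empty(0), np.empty(0), np.empty(0))
    toggled = schedule.drop_events(list(disabled_event_ids))
    hist_def = simulate(world, params, schedule)
    hist_tog = simulate(world, params, toggled)
    curve_def = global_diversity_curve(hist_def, world, decay).table
    curve_tog = global_diversity_curve(hist_tog, world, decay).table
    out = pd.DataFrame(
        {
            "age_ma": curve_def["age_ma"],
            "gamma_default": curve_def["gamma_total"],
            "gamma_experiment": curve_tog["gamma_total"],
        }
    )
    out["ratio"] = out["gamma_experiment"] / out["gamma_default"]
    summary = {
        "disabled_events": list(map(int, disabled_event_ids)),
        "max_ratio": float(np.nanmax(out["ratio"])) if len(out) else np.nan,
    }
    return ExperimentReport(label="extinction_toggle", curve_table=out, summary=summary)
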
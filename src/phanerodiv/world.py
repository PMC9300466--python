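"""Synthetic Phanerozoic-style world histories.

A world is a set of Lagrangian seafloor points tracked through time slices:

* **continental points** are fixed in space and alternate between flooded
  (epeiric/shelf sea) and emergent stints, resetting their seafloor age to
  zero on each re-flooding;
* **ocean points** are born at a mid-ocean ridge meridian with age zero,
  drift away at a constant speed, and are destroyed at subduction (randomly,
  or on colliding with a continental cell).

Each slice also carries an annotated raster (habitat class + seafloor age)
and environmental fields: a latitudinal seawater-temperature gradient and a
particulate-organic-carbon (POC) export flux that is higher over flooded
shelves than over the deep sea. These synthetic fields emulate the
statistical structure of reconstruction-driven inputs (habitat classes,
habitat lifespans, temperature gradient, shelf-enhanced food flux) without
any plate-tectonic or climate physics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._geo import wrap_lon

# habitat codes used in point tables and rasters
OCEAN = 0
SHELF = 1  # flooded continental shelf
LAND = 2  # emergent continental point: no marine habitat
GONE = 3  # destroyed (subducted) or not yet born

HABITAT_NAMES = {OCEAN: "ocean", SHELF: "flooded_shelf", LAND: "emergent_land", GONE: "destroyed"}


class WorldConfigError(ValueError):
    """Raised when a WorldConfig field violates its constraints."""


@dataclass
class WorldConfig:
    """Configuration of the synthetic world generator.

    Defaults emulate the study conditions at desk scale: 82 evenly spaced
    slices from 541 Ma to the present, a few hundred tracked points (the
    real reconstructions track ~6,000 shelf and ~44,000 ocean points), a
    modern-like equator-to-pole temperature gradient, and a roughly
    thirty-fold shelf/deep-sea contrast in POC export.
    """

    n_slices: int = 82
    slice_spacing: float | None = None  # Myr; None -> start_age/(n_slices-1)
    start_age: float = 541.0  # Ma
    grid_resolution: float = 2.0  # degrees
    n_continental_points: int = 300
    n_ocean_points: int = 1200
    temp_equator: float = 30.0  # °C
    temp_pole: float = 0.0  # °C
    shelf_poc_mean: float = 3.0  # mol C m^-2 yr^-1
    ocean_poc_mean: float = 0.1  # mol C m^-2 yr^-1
    temp_noise: float = 1.0  # °C, s.d. of cell-level additive noise
    poc_noise: float = 0.3  # s.d. of cell-level lognormal factor
    drift_speed: float = 0.5  # degrees longitude / Myr
    flood_cycle_params: dict = field(
        default_factory=lambda: {"kind": "geometric", "mean_flooded": 8.0, "mean_emergent": 4.0}
    )
    ridge_birth_rate: float = 0.05  # fraction of n_ocean_points born per slice
    subduction_rate: float = 0.05  # per-slice destruction probability
    ridge_lon: float = 0.0  # degrees
    n_continents: int = 3
    continent_scatter: float = 12.0  # degrees, spread of points around a continent centre
    polar_land_lat: float = 90.0  # empty cells poleward of this default to land
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_slices < 2:
            raise WorldConfigError("n_slices must be >= 2")
        if self.slice_spacing is not None and self.slice_spacing <= 0:
            raise WorldConfigError("slice_spacing must be > 0")
        if self.start_age <= 0:
            raise WorldConfigError("start_age must be > 0")
        if self.temp_equator < self.temp_pole:
            raise WorldConfigError("temp_equator must be >= temp_pole")
        if not np.isclose(round(180.0 / self.grid_resolution) * self.grid_resolution, 180.0):
            raise WorldConfigError("grid_resolution must divide 180 exactly")
        for name in ("ridge_birth_rate", "subduction_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise WorldConfigError(f"{name} must lie in [0, 1]")
        for name in ("n_continental_points", "n_ocean_points"):
            if getattr(self, name) < 0:
                raise WorldConfigError(f"{name} must be >= 0")
        for name in ("temp_noise", "poc_noise", "drift_speed", "shelf_poc_mean", "ocean_poc_mean"):
            if getattr(self, name) < 0:
                raise WorldConfigError(f"{name} must be >= 0")

    @property
    def spacing(self) -> float:
        """Effective slice spacing in Myr."""
        if self.slice_spacing is not None:
            return float(self.slice_spacing)
        return float(self.start_age) / (self.n_slices - 1)

    @property
    def slice_ages(self) -> np.ndarray:
        """Slice ages in Ma, strictly decreasing toward the present."""
        return self.start_age - np.arange(self.n_slices) * self.spacing

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "WorldConfig":
        return cls(**d)


@dataclass
class AnnotatedGrid:
    """Per-slice raster: habitat class codes and seafloor age (NaN = no habitat)."""

    class_map: np.ndarray  # (nlat, nlon) int8 in {OCEAN, SHELF, LAND}
    age_map: np.ndarray  # (nlat, nlon) float, Myr

    @property
    def shape(self):
        return self.class_map.shape


@dataclass
class WorldHistory:
    """Full synthetic world: tracked points, rasters and environments.

    Point state is stored as dense (n_slices, n_points) arrays; inactive
    entries (destroyed / unborn / emergent environment) are NaN. ``habitat``
    holds the integer codes of this module.
    """

    config: WorldConfig
    slice_ages: np.ndarray  # (S,)
    point_ids: np.ndarray  # (P,)
    origin: np.ndarray  # (P,) "continental" | "ocean"
    lat: np.ndarray  # (S, P)
    lon: np.ndarray  # (S, P)
    habitat: np.ndarray  # (S, P) int8
    age: np.ndarray  # (S, P) Myr, NaN when no habitat
    temp: np.ndarray  # (S, P) °C, NaN when inactive
    poc: np.ndarray  # (S, P) mol C m^-2 yr^-1, NaN when inactive
    grids: list[AnnotatedGrid]

    @property
    def n_slices(self) -> int:
        return len(self.slice_ages)

    @property
    def n_points(self) -> int:
        return len(self.point_ids)

    def active(self, s: int) -> np.ndarray:
        """Boolean mask of points holding marine habitat at slice s."""
        return (self.habitat[s] == OCEAN) | (self.habitat[s] == SHELF)

    def points_frame(self) -> pd.DataFrame:
        """Long-format table of every point/slice record (inactive rows kept)."""
        S, P = self.habitat.shape
        rows = {
            "point_id": np.tile(self.point_ids, S),
            "slice": np.repeat(np.arange(S), P),
            "age_ma": np.repeat(self.slice_ages, P),
            "lat": self.lat.ravel(),
            "lon": self.lon.ravel(),
            "habitat": [HABITAT_NAMES[h] for h in self.habitat.ravel()],
            "seafloor_age": self.age.ravel(),
            "temp": self.temp.ravel(),
            "poc": self.poc.ravel(),
        }
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------ io
    def save(self, outdir: str | Path) -> None:
        """Serialize to a directory: points.csv, grid_<slice>.csv, config.yaml."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.points_frame().to_csv(outdir / "points.csv", index=False)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh)
        for s, grid in enumerate(self.grids):
            nlat, nlon = grid.shape
            r, c = np.divmod(np.arange(nlat * nlon), nlon)
            pd.DataFrame(
                {
                    "row": r,
                    "col": c,
                    "class": grid.class_map.ravel(),
                    "age": grid.age_map.ravel(),
                }
            ).to_csv(outdir / f"grid_{s}.csv", index=False)

    @classmethod
    def load(cls, indir: str | Path) -> "WorldHistory":
        indir = Path(indir)
        with open(indir / "config.yaml") as fh:
            config = WorldConfig.from_dict(yaml.safe_load(fh))
        pts = pd.read_csv(indir / "points.csv")
        S = config.n_slices
        ids = np.sort(pts["point_id"].unique())
        P = len(ids)
        idx = {pid: j for j, pid in enumerate(ids)}
        name_to_code = {v: k for k, v in HABITAT_NAMES.items()}
        lat = np.full((S, P), np.nan)
        lon = np.full((S, P), np.nan)
        hab = np.full((S, P), GONE, dtype=np.int8)
        age = np.full((S, P), np.nan)
        temp = np.full((S, P), np.nan)
        poc = np.full((S, P), np.nan)
        jj = pts["point_id"].map(idx).to_numpy()
        ss = pts["slice"].to_numpy()
        lat[ss, jj] = pts["lat"]
        lon[ss, jj] = pts["lon"]
        hab[ss, jj] = pts["habitat"].map(name_to_code)
        age[ss, jj] = pts["seafloor_age"]
        temp[ss, jj] = pts["temp"]
        poc[ss, jj] = pts["poc"]
        ever_ocean = pts.groupby("point_id")["habitat"].apply(lambda h: (h == "ocean").any())
        origin = np.where(ever_ocean.reindex(ids, fill_value=False), "ocean", "continental")
        grids = []
        nlat = int(round(180.0 / config.grid_resolution))
        nlon = 2 * nlat
        for s in range(S):
            g = pd.read_csv(indir / f"grid_{s}.csv")
            grids.append(
                AnnotatedGrid(
                    class_map=g["class"].to_numpy(dtype=np.int8).reshape(nlat, nlon),
                    age_map=g["age"].to_numpy(dtype=float).reshape(nlat, nlon),
                )
            )
        return cls(
            config=config,
            slice_ages=config.slice_ages,
            point_ids=ids,
            origin=origin,
            lat=lat,
            lon=lon,
            habitat=hab,
            age=age,
            temp=temp,
            poc=poc,
            grids=grids,
        )


@dataclass
class ExtinctionSchedule:
    """Ordered mass-extinction events (oldest first) with imputed rates.

    Each event removes ``loss_fraction`` of standing diversity over
    ``duration`` Myr via a constant negative per-capita rate
    ln(1 - loss) / duration that replaces the environmental rate while the
    event is active (non-selective, field-of-bullets extinction).
    """

    start_ma: np.ndarray  # event onset ages, Ma
    duration_myr: np.ndarray
    loss_fraction: np.ndarray

    @property
    def n_events(self) -> int:
        return len(self.start_ma)

    @property
    def imputed_rate(self) -> np.ndarray:
        """Constant per-capita rates, Myr^-1 (negative)."""
        return np.log1p(-self.loss_fraction) / self.duration_myr

    def drop_events(self, event_ids) -> "ExtinctionSchedule":
        keep = np.setdiff1d(np.arange(self.n_events), np.asarray(event_ids, dtype=int))
        bad = np.setdiff1d(np.asarray(event_ids, dtype=int), np.arange(self.n_events))
        if bad.size:
            raise ValueError(f"unknown extinction event ids: {bad.tolist()}")
        return ExtinctionSchedule(
            self.start_ma[keep], self.duration_myr[keep], self.loss_fraction[keep]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_ma": self.start_ma,
                "duration_myr": self.duration_myr,
                "loss_fraction": self.loss_fraction,
                "imputed_rate": self.imputed_rate,
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame()[["start_ma", "duration_myr", "loss_fraction"]].to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "ExtinctionSchedule":
        return make_extinction_schedule(pd.read_csv(path))


def make_extinction_schedule(events) -> ExtinctionSchedule:
    """Build a validated schedule from an iterable/table of events.

    ``events`` may be a DataFrame with columns (start_ma, duration_myr,
    loss_fraction) or an iterable of such triples. Events are sorted oldest
    first and must not overlap in time.
    """
    if isinstance(events, pd.DataFrame):
        df = events.rename(
            columns={"start": "start_ma", "duration": "duration_myr", "loss": "loss_fraction"}
        )
        triples = df[["start_ma", "duration_myr", "loss_fraction"]].to_numpy(dtype=float)
    else:
        triples = np.asarray([tuple(e) for e in events], dtype=float).reshape(-1, 3)
    if triples.size == 0:
        z = np.empty(0)
        return ExtinctionSchedule(z.copy(), z.copy(), z.copy())
    order = np.argsort(-triples[:, 0])
    triples = triples[order]
    start, dur, loss = triples.T
    if np.any(dur <= 0):
        raise ValueError("event duration must be > 0")
    if np.any((loss <= 0) | (loss >= 1)):
        raise ValueError("loss_fraction must lie in the open interval (0, 1)")
    ends = start - dur
    if np.any(start[1:] > ends[:-1]):
        raise ValueError("extinction events must not overlap in time")
    return ExtinctionSchedule(start, dur, loss)


# --------------------------------------------------------------------------
# generator internals


def _cell_index(lat, lon, res):
    """Row/col of the cell containing each point. Rows count from the north pole."""
    nlat = int(round(180.0 / res))
    nlon = 2 * nlat
    r = np.clip(((90.0 - np.asarray(lat)) / res).astype(int), 0, nlat - 1)
    c = np.clip(((np.asarray(lon) + 180.0) / res).astype(int), 0, nlon - 1)
    return r, c


def cell_centers(res):
    """(lat_centers, lon_centers) of the global grid at resolution ``res``."""
    nlat = int(round(180.0 / res))
    nlon = 2 * nlat
    lat_c = 90.0 - (np.arange(nlat) + 0.5) * res
    lon_c = -180.0 + (np.arange(nlon) + 0.5) * res
    return lat_c, lon_c


def _stint_lengths(rng, kind, mean_flooded, mean_emergent, n_slices, start_flooded):
    """Alternating flooded/emergent stint lengths covering n_slices."""
    states = np.empty(n_slices, dtype=bool)
    pos = 0
    flooded = start_flooded
    while pos < n_slices:
        if kind == "fixed":
            length = int(mean_flooded if flooded else mean_emergent)
        else:  # geometric with the given mean (support >= 1)
            mean = mean_flooded if flooded else mean_emergent
            p = min(1.0, 1.0 / max(mean, 1.0))
            length = int(rng.geometric(p))
        length = max(length, 1)
        states[pos : pos + length] = flooded
        pos += length
        flooded = not flooded
    return states


def build_world(config: WorldConfig) -> WorldHistory:
    """Generate a world history. Deterministic for a fixed (config, seed).

    The seeded random stream is consumed in a fixed documented order:
    continent centres, continental point positions, flood/emerge schedules,
    initial ocean points, then per slice (drift sides for newborns,
    subduction draws, birth latitudes), and finally per-slice noise fields.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    S = config.n_slices
    ages = config.slice_ages
    spacing = config.spacing
    res = config.grid_resolution
    nlat = int(round(180.0 / res))
    nlon = 2 * nlat

    fc = dict(config.flood_cycle_params)
    kind = fc.get("kind", "geometric")
    mean_f = float(fc.get("mean_flooded", 8.0))
    mean_e = float(fc.get("mean_emergent", 4.0))

    # 1-2. continental geography (fixed through time)
    Nc = config.n_continental_points
    centers_lon = rng.uniform(-180.0, 180.0, size=config.n_continents)
    centers_lat = rng.uniform(-55.0, 55.0, size=config.n_continents)
    if Nc > 0:
        which = rng.integers(0, config.n_continents, size=Nc)
        clat = np.clip(
            centers_lat[which] + rng.normal(0.0, config.continent_scatter, size=Nc), -85.0, 85.0
        )
        clon = wrap_lon(centers_lon[which] + rng.normal(0.0, config.continent_scatter, size=Nc))
    else:
        clat = np.empty(0)
        clon = np.empty(0)

    # 3. flood/emerge schedules
    start_flooded = (
        rng.random(Nc) < (mean_f / (mean_f + mean_e)) if kind == "geometric" else np.ones(Nc, bool)
    )
    if "start_flooded" in fc:
        start_flooded = np.full(Nc, bool(fc["start_flooded"]))
    flooded = np.empty((S, Nc), dtype=bool)
    for j in range(Nc):
        flooded[:, j] = _stint_lengths(rng, kind, mean_f, mean_e, S, start_flooded[j])

    cont_cells = set(zip(*_cell_index(clat, clon, res))) if Nc else set()

    def in_cont_cell(la, lo):
        r, c = _cell_index(la, lo, res)
        return np.fromiter(
            ((rr, cc) in cont_cells for rr, cc in zip(np.atleast_1d(r), np.atleast_1d(c))),
            dtype=bool,
            count=np.atleast_1d(r).size,
        )

    # 4-5. initial ocean points (rejection-sample away from continental cells)
    No0 = config.n_ocean_points
    n_births = int(round(config.ridge_birth_rate * config.n_ocean_points))
    P_ocean = No0 + n_births * (S - 1)
    olat = np.full(P_ocean, np.nan)
    olon0 = np.full(P_ocean, np.nan)
    oside = np.zeros(P_ocean)
    born = np.full(P_ocean, S, dtype=int)  # slice of birth

    def sample_ocean(n, at_ridge):
        la = np.empty(n)
        lo = np.empty(n)
        filled = 0
        while filled < n:
            m = n - filled
            cand_lat = np.degrees(np.arcsin(rng.uniform(-np.sin(np.radians(75.0)), np.sin(np.radians(75.0)), m)))
            cand_lon = (
                np.full(m, config.ridge_lon) if at_ridge else wrap_lon(rng.uniform(-180.0, 180.0, m))
            )
            ok = ~in_cont_cell(cand_lat, cand_lon) if cont_cells else np.ones(m, bool)
            k = int(ok.sum())
            la[filled : filled + k] = cand_lat[ok]
            lo[filled : filled + k] = cand_lon[ok]
            filled += k
        return la, lo

    if No0 > 0:
        olat[:No0], olon0[:No0] = sample_ocean(No0, at_ridge=False)
        oside[:No0] = np.where(
            np.isclose(olon0[:No0], config.ridge_lon),
            np.where(rng.random(No0) < 0.5, -1.0, 1.0),
            np.sign(wrap_lon(olon0[:No0] - config.ridge_lon)),
        )
        born[:No0] = 0

    # 6. march ocean points through time
    olon = np.full((S, P_ocean), np.nan)
    oalive = np.zeros((S, P_ocean), dtype=bool)
    oage = np.full((S, P_ocean), np.nan)
    olon[0, :No0] = olon0[:No0]
    oalive[0, :No0] = True
    oage[0, :No0] = 0.0
    next_id = No0
    for s in range(1, S):
        prev = oalive[s - 1]
        # drift
        moved = wrap_lon(olon[s - 1, prev] + oside[prev] * config.drift_speed * spacing)
        alive = prev.copy()
        olon[s, prev] = moved
        # collision with continental cells -> subduction
        if cont_cells and prev.any():
            hit = in_cont_cell(olat[prev], moved)
            idx = np.where(prev)[0][hit]
            alive[idx] = False
        # random subduction
        survivors = np.where(alive)[0]
        if survivors.size:
            killed = survivors[rng.random(survivors.size) < config.subduction_rate]
            alive[killed] = False
        # ridge births
        if n_births > 0:
            ids = np.arange(next_id, next_id + n_births)
            la, lo = sample_ocean(n_births, at_ridge=True)
            olat[ids] = la
            olon0[ids] = lo
            oside[ids] = np.where(rng.random(n_births) < 0.5, -1.0, 1.0)
            born[ids] = s
            olon[s, ids] = lo
            alive[ids] = True
            oage[s, ids] = 0.0
            next_id += n_births
        oalive[s] = alive
        cont_alive = alive & prev
        oage[s, cont_alive] = oage[s - 1, cont_alive] + spacing

    P_ocean = next_id
    # assemble combined point arrays: continental points first
    P = Nc + P_ocean
    point_ids = np.arange(P)
    origin = np.array(["continental"] * Nc + ["ocean"] * P_ocean)
    lat = np.full((S, P), np.nan)
    lon = np.full((S, P), np.nan)
    hab = np.full((S, P), GONE, dtype=np.int8)
    age = np.full((S, P), np.nan)

    if Nc:
        lat[:, :Nc] = clat
        lon[:, :Nc] = clon
        hab[:, :Nc] = np.where(flooded, SHELF, LAND)
        # seafloor age accumulates within flooded stints, resets on re-flooding
        cage = np.full((S, Nc), np.nan)
        cage[0, flooded[0]] = 0.0
        for s in range(1, S):
            newly = flooded[s] & ~flooded[s - 1]
            cont = flooded[s] & flooded[s - 1]
            cage[s, newly] = 0.0
            cage[s, cont] = cage[s - 1, cont] + spacing
        age[:, :Nc] = cage

    lat[:, Nc:] = olat[:P_ocean]
    lon[:, Nc:] = olon[:, :P_ocean]
    hab[:, Nc:][oalive[:, :P_ocean]] = OCEAN
    age[:, Nc:] = np.where(oalive[:, :P_ocean], oage[:, :P_ocean], np.nan)

    # 7. per-slice noise fields and environments
    lat_c, _ = cell_centers(res)
    base_T = config.temp_equator - (config.temp_equator - config.temp_pole) * np.abs(lat_c) / 90.0
    temp = np.full((S, P), np.nan)
    poc = np.full((S, P), np.nan)
    grids: list[AnnotatedGrid] = []
    for s in range(S):
        t_noise = rng.normal(0.0, config.temp_noise, size=(nlat, nlon)) if config.temp_noise > 0 else np.zeros((nlat, nlon))
        p_fac = (
            np.exp(rng.normal(0.0, config.poc_noise, size=(nlat, nlon)))
            if config.poc_noise > 0
            else np.ones((nlat, nlon))
        )
        T_field = base_T[:, None] + t_noise

        active = (hab[s] == OCEAN) | (hab[s] == SHELF)
        if active.any():
            r, c = _cell_index(lat[s, active], lon[s, active], res)
            temp[s, active] = T_field[r, c]
            mean = np.where(hab[s, active] == SHELF, config.shelf_poc_mean, config.ocean_poc_mean)
            poc[s, active] = mean * p_fac[r, c]

        # annotated raster: majority class per cell, empty cells default ocean
        class_map = np.full((nlat, nlon), OCEAN, dtype=np.int8)
        if config.polar_land_lat < 90.0:
            class_map[np.abs(lat_c) > config.polar_land_lat, :] = LAND
        age_map = np.full((nlat, nlon), np.nan)
        if Nc:
            r, c = _cell_index(clat, clon, res)
            df = pd.DataFrame({"r": r, "c": c, "fl": flooded[s], "age": age[s, :Nc]})
            for (rr, cc), grp in df.groupby(["r", "c"]):
                # ties go to flooded shelf (marine habitat wins)
                is_shelf = grp["fl"].mean() >= 0.5
                class_map[rr, cc] = SHELF if is_shelf else LAND
                if is_shelf and grp["fl"].any():
                    age_map[rr, cc] = grp.loc[grp["fl"], "age"].mean()
        omask = hab[s] == OCEAN
        if omask.any():
            r, c = _cell_index(lat[s, omask], lon[s, omask], res)
            df = pd.DataFrame({"r": r, "c": c, "age": age[s, omask]})
            for (rr, cc), grp in df.groupby(["r", "c"]):
                if class_map[rr, cc] == OCEAN:
                    age_map[rr, cc] = grp["age"].mean()
        grids.append(AnnotatedGrid(class_map=class_map, age_map=age_map))

    return WorldHistory(
        config=config,
        slice_ages=ages,
        point_ids=point_ids,
        origin=origin,
        lat=lat,
        lon=lon,
        habitat=hab,
        age=age,
        temp=temp,
        poc=poc,
        grids=grids,
    )


def sample_environment(world: WorldHistory, slice_index: int) -> pd.DataFrame:
    """Per-point (temperature, poc_flux) for active points at one slice."""
    if not 0 <= slice_index < world.n_slices:
        raise IndexError(f"slice {slice_index} out of range [0, {world.n_slices})")
    m = world.active(slice_index)
    return pd.DataFrame(
        {
            "point_id": world.point_ids[m],
            "temperature": world.temp[slice_index, m],
            "poc_flux": world.poc[slice_index, m],
        }
    )


def age_points(world: WorldHistory) -> pd.DataFrame:
    """Per-point seafloor-age series (slices as rows, point ids as columns)."""
    return pd.DataFrame(world.age, columns=world.point_ids, index=world.slice_ages)
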
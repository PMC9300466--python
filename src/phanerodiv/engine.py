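"""Environment-dependent logistic/exponential diversification engine.

Regional genus richness D on each seafloor point evolves by

    dD/dt = rho * D * (1 - D / K_eff)       (logistic)
    dD/dt = rho * D                         (exponential)

with a net per-capita diversification rate

    rho = rho_max - (rho_max - rho_min) * (1 - Q_temp * Q_food)

where Q_temp is a Q10 temperature-sensitivity term normalized to the
per-slice 1st-99th percentile temperature envelope and Q_food is a
Michaelis-Menten saturation of the particulate-organic-carbon (POC) export
flux. The effective carrying capacity K_eff maps the whole-run POC envelope
linearly onto [K_min, K_max]. The ODEs are stepped with explicit Euler at a
fixed substep (1 Myr by default), with the environment held constant within
each time slice.

Mass extinctions are imposed as external forcing: while an event is active,
the environmental rate is replaced by the event's constant negative imputed
rate ln(1 - loss) / duration, applied to every active point (non-selective,
"field of bullets").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._geo import haversine_km
from .world import GONE, LAND, OCEAN, SHELF, ExtinctionSchedule, WorldHistory

__all__ = [
    "ModelParams",
    "EnvEnvelope",
    "DiversityHistory",
    "temperature_limitation",
    "food_limitation",
    "net_diversification_rate",
    "effective_carrying_capacity",
    "step_logistic",
    "step_exponential",
    "extinction_rate_from_loss",
    "env_percentiles",
    "simulate",
]


@dataclass
class ModelParams:
    """Tunable parameters of the diversification model.

    Defaults are the calibrated values: Q10 = 1.75, K_food = 0.5
    mol C m^-2 yr^-1, rate limits 0.001-0.035 Myr^-1 and carrying-capacity
    bounds 12-123 genera per cell.
    """

    rho_min: float = 0.001  # Myr^-1 per capita
    rho_max: float = 0.035
    q10: float = 1.75
    k_food: float = 0.5  # mol C m^-2 yr^-1
    k_min: float = 12.0  # genera per cell
    k_max: float = 123.0
    temp_quantiles: tuple[float, float] = (0.01, 0.99)
    poc_quantiles: tuple[float, float] = (0.01, 0.99)
    ode_step: float = 1.0  # Myr
    model_kind: str = "logistic"  # or "exponential"

    def __post_init__(self):
        if not 0 < self.rho_min <= self.rho_max:
            raise ValueError("require 0 < rho_min <= rho_max")
        if self.q10 < 1:
            raise ValueError("q10 must be >= 1")
        if self.k_food <= 0:
            raise ValueError("k_food must be > 0")
        if not 0 < self.k_min <= self.k_max:
            raise ValueError("require 0 < k_min <= k_max")
        if self.ode_step <= 0:
            raise ValueError("ode_step must be > 0")
        if self.model_kind not in ("logistic", "exponential"):
            raise ValueError("model_kind must be 'logistic' or 'exponential'")

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass
class EnvEnvelope:
    """Temperature envelope of one slice plus the whole-run POC envelope."""

    t_min: float
    t_max: float
    poc_min: float
    poc_max: float
    degenerate: bool = False  # no active points in the slice

    def __post_init__(self):
        if not self.degenerate:
            if self.t_min > self.t_max:
                raise ValueError("t_min must be <= t_max")
            if self.poc_min > self.poc_max:
                raise ValueError("poc_min must be <= poc_max")


def temperature_limitation(T, envelope: EnvEnvelope, q10: float):
    """Q10 temperature limitation in [0, 1].

    Q10^((T - T_min)/10) / Q10^((T_max - T_min)/10), with T clamped to the
    envelope. A degenerate envelope (t_min == t_max) yields 1.
    """
    if envelope.t_max == envelope.t_min:
        return np.ones_like(np.asarray(T, dtype=float))
    T = np.clip(np.asarray(T, dtype=float), envelope.t_min, envelope.t_max)
    return q10 ** ((T - envelope.t_min) / 10.0) / q10 ** ((envelope.t_max - envelope.t_min) / 10.0)


def food_limitation(poc, k_food: float):
    """Michaelis-Menten food limitation poc / (k_food + poc), in [0, 1)."""
    poc = np.asarray(poc, dtype=float)
    if np.any(poc < 0):
        raise ValueError("poc flux must be >= 0")
    return poc / (k_food + poc)


def net_diversification_rate(q_temp, q_food, params: ModelParams):
    """Net per-capita rate rho in [rho_min, rho_max], Myr^-1."""
    q = np.asarray(q_temp, dtype=float) * np.asarray(q_food, dtype=float)
    return params.rho_max - (params.rho_max - params.rho_min) * (1.0 - q)


def effective_carrying_capacity(poc, envelope: EnvEnvelope, params: ModelParams):
    """Linear map of the POC envelope onto [k_min, k_max], clamped outside.

    With a degenerate POC envelope (poc_min == poc_max) every flux maps to
    k_max, consistent with poc_max -> k_max.
    """
    poc = np.asarray(poc, dtype=float)
    if envelope.poc_max == envelope.poc_min:
        return np.full_like(poc, params.k_max)
    k = params.k_max - (params.k_max - params.k_min) * (envelope.poc_max - poc) / (
        envelope.poc_max - envelope.poc_min
    )
    return np.clip(k, params.k_min, params.k_max)


def step_logistic(D, rho, k_eff, dt: float):
    """One explicit Euler step of the logistic ODE.

    A point arriving with D above its carrying capacity is reset to K_eff
    (local extinction) instead of being stepped.
    """
    D = np.asarray(D, dtype=float)
    stepped = D + rho * D * (1.0 - D / k_eff) * dt
    return np.where(D > k_eff, k_eff, stepped)


def step_exponential(D, rho, dt: float):
    """One explicit Euler step of exponential growth/decay."""
    return np.asarray(D, dtype=float) * (1.0 + np.asarray(rho, dtype=float) * dt)


def extinction_rate_from_loss(loss_fraction: float, duration: float) -> float:
    """Constant per-capita rate removing ``loss_fraction`` over ``duration`` Myr."""
    if not 0 < loss_fraction < 1:
        raise ValueError("loss_fraction must lie in (0, 1)")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    return math.log1p(-loss_fraction) / duration


def env_percentiles(world: WorldHistory, params: ModelParams | None = None) -> list[EnvEnvelope]:
    """Per-slice temperature envelopes sharing one whole-run POC envelope.

    Temperature bounds are the 1st/99th empirical percentiles of active-point
    temperatures, recomputed each slice (thermal adaptation to the changing
    climate); the POC bounds are computed once over all slices and points.
    Slices without active points yield a degenerate envelope.
    """
    params = params or ModelParams()
    tq = params.temp_quantiles
    pq = params.poc_quantiles
    all_poc = world.poc[np.isfinite(world.poc)]
    if all_poc.size:
        poc_min, poc_max = np.quantile(all_poc, pq)
    else:
        poc_min = poc_max = np.nan
    envelopes = []
    for s in range(world.n_slices):
        t = world.temp[s, world.active(s)]
        t = t[np.isfinite(t)]
        if t.size == 0:
            envelopes.append(
                EnvEnvelope(np.nan, np.nan, float(poc_min), float(poc_max), degenerate=True)
            )
            continue
        t_min, t_max = np.quantile(t, tq)
        envelopes.append(EnvEnvelope(float(t_min), float(t_max), float(poc_min), float(poc_max)))
    return envelopes


@dataclass
class DiversityHistory:
    """Recorded per-slice state of a simulation.

    ``D``, ``k_eff`` and ``rho`` are (n_slices, n_points) arrays; NaN marks
    inactive points (and ``k_eff`` is NaN throughout for exponential runs).
    ``rho`` is the environmental rate at each slice, before any extinction
    override.
    """

    point_ids: np.ndarray
    slice_ages: np.ndarray
    D: np.ndarray
    k_eff: np.ndarray
    rho: np.ndarray
    model_kind: str
    envelopes: list[EnvEnvelope] = field(default_factory=list, repr=False)

    def to_frame(self) -> pd.DataFrame:
        S, P = self.D.shape
        return pd.DataFrame(
            {
                "point_id": np.tile(self.point_ids, S),
                "slice": np.repeat(np.arange(S), P),
                "age_ma": np.repeat(self.slice_ages, P),
                "D": self.D.ravel(),
                "k_eff": self.k_eff.ravel(),
                "rho": self.rho.ravel(),
            }
        )

    def save(self, path) -> None:
        df = self.to_frame()
        df[np.isfinite(df["D"])].to_csv(path, index=False)


def _event_rate_at(ages_mid: np.ndarray, schedule: ExtinctionSchedule) -> np.ndarray:
    """Imputed rate for substep midpoints inside an event window, NaN outside."""
    out = np.full(ages_mid.shape, np.nan)
    rates = schedule.imputed_rate
    for i in range(schedule.n_events):
        start = schedule.start_ma[i]
        end = start - schedule.duration_myr[i]
        inside = (ages_mid <= start) & (ages_mid > end)
        out[inside] = rates[i]
    return out


def simulate(
    world: WorldHistory,
    params: ModelParams | None = None,
    schedule: ExtinctionSchedule | None = None,
) -> DiversityHistory:
    """Run the Lagrangian diversification model over a world history.

    Every active point starts with a single genus (D0 = 1) at the oldest
    slice. Between consecutive slices the ODE is substepped at
    ``params.ode_step`` using the arrival slice's environment. Continental
    points that emerge record D = 0; on re-flooding they are seeded with the
    richness of the nearest flooded continental point with D > 1 (coastal
    recolonization), or 1 if none exists. Ridge-born ocean points start at
    D = 1; subducted points disappear and their diversity is lost. Logistic
    runs clip D to K_eff at every substep, and surviving active points are
    floored at one genus after each slice.
    """
    params = params or ModelParams()
    schedule = schedule if schedule is not None else ExtinctionSchedule(
        np.empty(0), np.empty(0), np.empty(0)
    )
    logistic = params.model_kind == "logistic"
    S, P = world.habitat.shape
    envelopes = env_percentiles(world, params)

    D = np.full((S, P), np.nan)
    K = np.full((S, P), np.nan)
    RHO = np.full((S, P), np.nan)

    def env_fields(s, mask):
        env = envelopes[s]
        t = world.temp[s, mask]
        p = world.poc[s, mask]
        if np.any(~np.isfinite(t)) or np.any(~np.isfinite(p)):
            bad = world.point_ids[mask][~np.isfinite(t) | ~np.isfinite(p)]
            raise ValueError(f"missing environment for active points {bad.tolist()} at slice {s}")
        rho = net_diversification_rate(
            temperature_limitation(t, env, params.q10),
            food_limitation(p, params.k_food),
            params,
        )
        k = effective_carrying_capacity(p, env, params) if logistic else np.full(t.shape, np.nan)
        return rho, k

    act0 = world.active(0)
    D[0, act0] = 1.0
    rho0, k0 = env_fields(0, act0)
    RHO[0, act0] = rho0
    if logistic:
        K[0, act0] = k0

    for s in range(1, S):
        dt_total = world.slice_ages[s - 1] - world.slice_ages[s]
        n_sub = max(1, int(math.ceil(dt_total / params.ode_step - 1e-9)))
        dt = dt_total / n_sub
        act_prev = world.active(s - 1)
        act_now = world.active(s)
        cont = act_prev & act_now  # points active through the transition
        rho_env, k_now = env_fields(s, cont)

        # substep midpoints in absolute age, oldest first
        mids = world.slice_ages[s - 1] - (np.arange(n_sub) + 0.5) * dt
        forced = _event_rate_at(mids, schedule)
        d = D[s - 1, cont].copy()
        for j in range(n_sub):
            rho_j = np.full(d.shape, forced[j]) if np.isfinite(forced[j]) else rho_env
            if logistic:
                d = step_logistic(d, rho_j, k_now, dt)
            else:
                d = step_exponential(d, rho_j, dt)
        d = np.maximum(d, 1.0)  # survivors retain at least one genus
        D[s, cont] = d

        # emergent continental points: habitat interrupted, D set to 0
        D[s, world.habitat[s] == LAND] = 0.0

        # newly active points: ridge births (D=1) and re-flooded shelves (seeded)
        new = act_now & ~act_prev
        if new.any():
            is_shelf = new & (world.habitat[s] == SHELF)
            is_ocean = new & (world.habitat[s] == OCEAN)
            D[s, is_ocean] = 1.0
            if is_shelf.any():
                donors = cont & (world.habitat[s] == SHELF) & (D[s] > 1.0)
                didx = np.where(donors)[0]
                for j in np.where(is_shelf)[0]:
                    if didx.size == 0:
                        D[s, j] = 1.0
                        continue
                    dist = haversine_km(
                        world.lat[s, j], world.lon[s, j], world.lat[s, didx], world.lon[s, didx]
                    )
                    # nearest donor; ties resolved toward the lowest point id
                    best = didx[np.lexsort((didx, np.round(dist, 9)))][0]
                    D[s, j] = D[s, best]

        rho_all, k_all = env_fields(s, act_now)
        RHO[s, act_now] = rho_all
        if logistic:
            K[s, act_now] = k_all
            # arrival in a poorer environment than accumulated diversity
            D[s, act_now] = np.minimum(D[s, act_now], k_all)

    return DiversityHistory(
        point_ids=world.point_ids,
        slice_ages=world.slice_ages,
        D=D,
        k_eff=K,
        rho=RHO,
        model_kind=params.model_kind,
        envelopes=envelopes,
    )
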
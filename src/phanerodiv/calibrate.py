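"""Comparison with reference diversity curves and carrying-capacity calibration.

Model and reference global diversity curves are min-max normalized and
compared with Lin's concordance correlation coefficient (CCC), computed on
the concatenation of the rising inter-extinction segments (between the end
of one mass extinction and the start of the next) so that agreement is
judged on recovery/diversification trends rather than on the externally
imposed extinction drops. Serial correlation is deliberately ignored: the
comparison targets long-term trends.

The carrying-capacity bounds (K_min, K_max) are calibrated by a grid search
over all ordered pairs from a base-2 geometric sequence 2..256 (28 pairs),
re-running the full logistic pipeline for each pair and averaging the pairs
whose CCC exceeds a threshold (0.70 by default).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import ModelParams, simulate
from .transects import DecayParams, global_diversity_curve
from .world import ExtinctionSchedule, WorldHistory

__all__ = [
    "FossilCurve",
    "CalibrationResult",
    "minmax_normalize",
    "lin_ccc",
    "rising_segments",
    "curve_concordance",
    "k_bounds_grid_search",
    "calibrate_bounds",
    "parameter_sweep",
]

K_SEQUENCE = (2, 4, 8, 16, 32, 64, 128, 256)


@dataclass
class FossilCurve:
    """A reference global diversity curve: (age, richness), oldest first."""

    age_ma: np.ndarray
    diversity: np.ndarray

    def __post_init__(self):
        self.age_ma = np.asarray(self.age_ma, dtype=float)
        self.diversity = np.asarray(self.diversity, dtype=float)
        if np.any(np.diff(self.age_ma) >= 0):
            raise ValueError("ages must be strictly decreasing")
        if np.any(self.diversity <= 0):
            raise ValueError("diversity must be > 0")

    def interpolate_to(self, ages) -> np.ndarray:
        """Linear interpolation onto model slice ages (Ma)."""
        # negate so the abscissa is increasing, as np.interp requires
        return np.interp(-np.asarray(ages, dtype=float), -self.age_ma, self.diversity)

    def save(self, path) -> None:
        pd.DataFrame({"age_ma": self.age_ma, "diversity": self.diversity}).to_csv(path, index=False)

    @classmethod
    def load(cls, path) -> "FossilCurve":
        df = pd.read_csv(path)
        return cls(df["age_ma"].to_numpy(), df["diversity"].to_numpy())


def minmax_normalize(x) -> np.ndarray:
    """Rescale a series to [0, 1]; a constant series is an error."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        raise ValueError("cannot min-max normalize a constant series")
    return (x - lo) / (hi - lo)


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments).

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (mean x - mean y)^2), combining the
    precision of the fit (correlation) and its accuracy (distance of the
    reduced major axis from the 1:1 line).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("series must have equal length >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("series must be finite")
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    denom = x.var() + y.var() + (x.mean() - y.mean()) ** 2
    if denom == 0:
        raise ValueError("zero total variance with equal means: CCC undefined")
    return float(2.0 * sxy / denom)


def rising_segments(age_ma, schedule: ExtinctionSchedule) -> list[np.ndarray]:
    """Index ranges of a curve lying outside every extinction window.

    Returns the maximal runs of slice indices between the end of one event
    and the start of the next (including the leading and trailing runs);
    empty runs are dropped.
    """
    age_ma = np.asarray(age_ma, dtype=float)
    in_event = np.zeros(age_ma.shape, dtype=bool)
    for i in range(schedule.n_events):
        start = schedule.start_ma[i]
        end = start - schedule.duration_myr[i]
        in_event |= (age_ma <= start) & (age_ma >= end)
    segments = []
    idx = np.where(~in_event)[0]
    if idx.size == 0:
        return segments
    breaks = np.where(np.diff(idx) > 1)[0]
    for chunk in np.split(idx, breaks + 1):
        if chunk.size:
            segments.append(chunk)
    return segments


def curve_concordance(
    model_age, model_gamma, reference: FossilCurve, schedule: ExtinctionSchedule
) -> float:
    """CCC between normalized model and reference curves on rising segments."""
    model_age = np.asarray(model_age, dtype=float)
    model_gamma = np.asarray(model_gamma, dtype=float)
    ok = np.isfinite(model_gamma)
    model_age, model_gamma = model_age[ok], model_gamma[ok]
    ref = reference.interpolate_to(model_age)
    m = minmax_normalize(model_gamma)
    r = minmax_normalize(ref)
    segs = rising_segments(model_age, schedule)
    if not segs:
        raise ValueError("no rising segments outside extinction windows")
    sel = np.concatenate(segs)
    return lin_ccc(m[sel], r[sel])


@dataclass
class CalibrationResult:
    """Grid-search table of (k_min, k_max, ccc) and the selection threshold."""

    table: pd.DataFrame
    threshold: float = 0.70
    params_template: ModelParams | None = field(default=None, repr=False)

    @property
    def selected(self) -> pd.DataFrame:
        ok = self.table["ccc"] > self.threshold
        return self.table[ok & np.isfinite(self.table["ccc"])]

    @property
    def best(self) -> tuple[float, float]:
        t = self.table[np.isfinite(self.table["ccc"])]
        row = t.loc[t["ccc"].idxmax()]
        return (float(row["k_min"]), float(row["k_max"]))

    def save(self, path) -> None:
        out = self.table.copy()
        out["selected"] = out.index.isin(self.selected.index)
        out.to_csv(path, index=False)


def _run_pipeline(world, params, schedule, decay):
    history = simulate(world, params, schedule)
    curve = global_diversity_curve(history, world, decay)
    return curve


def k_bounds_grid_search(
    world: WorldHistory,
    params_template: ModelParams,
    schedule: ExtinctionSchedule,
    reference: FossilCurve,
    decay: DecayParams | None = None,
    k_sequence=K_SEQUENCE,
    threshold: float = 0.70,
) -> CalibrationResult:
    """Run the logistic pipeline for every ordered pair of the K sequence.

    All pairs K_min < K_max from the base-2 sequence are enumerated (28 for
    the default 2..256); failures on a pair are recorded as missing rather
    than aborting the search.
    """
    decay = decay or DecayParams()
    rows = []
    for k_min, k_max in itertools.combinations(sorted(k_sequence), 2):
        params = params_template.replace(k_min=float(k_min), k_max=float(k_max), model_kind="logistic")
        try:
            curve = _run_pipeline(world, params, schedule, decay)
            ccc = curve_concordance(
                curve.table["age_ma"], curve.table["gamma_total"], reference, schedule
            )
        except (ValueError, FloatingPointError):
            ccc = np.nan
        rows.append((float(k_min), float(k_max), ccc))
    table = pd.DataFrame(rows, columns=["k_min", "k_max", "ccc"])
    return CalibrationResult(table=table, threshold=threshold, params_template=params_template)


def calibrate_bounds(result: CalibrationResult) -> tuple[float, float]:
    """Average the (K_min, K_max) pairs whose CCC exceeds the threshold."""
    sel = result.selected
    if sel.empty:
        raise ValueError(
            f"no K pair exceeds CCC threshold {result.threshold}; lower the threshold"
        )
    return (float(sel["k_min"].mean()), float(sel["k_max"].mean()))


def parameter_sweep(
    grid,
    world: WorldHistory,
    schedule: ExtinctionSchedule,
    reference: FossilCurve,
    params_template: ModelParams | None = None,
    decay: DecayParams | None = None,
    top_n: int = 15,
) -> pd.DataFrame:
    """CCC for each parameter combination; the top ``top_n`` are flagged.

    ``grid`` is an iterable of dicts of ModelParams overrides (for example
    q10, k_food, rho_min, rho_max). The result is deterministic for a fixed
    world and contains one row per input combination, ranked by CCC.
    """
    params_template = params_template or ModelParams()
    decay = decay or DecayParams()
    rows = []
    for combo in grid:
        params = params_template.replace(**combo)
        try:
            curve = _run_pipeline(world, params, schedule, decay)
            ccc = curve_concordance(
                curve.table["age_ma"], curve.table["gamma_total"], reference, schedule
            )
        except (ValueError, FloatingPointError):
            ccc = np.nan
        rows.append({**combo, "ccc": ccc})
    out = pd.DataFrame(rows)
    order = out["ccc"].rank(ascending=False, method="first")
    out["rank"] = order.astype("Int64")
    out["selected"] = order <= top_n
    return out
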
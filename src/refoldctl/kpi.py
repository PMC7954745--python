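"""Key performance indicators of a refolding run.

Two KPIs summarise a dilution-refolding process: the refolding yield
(native over total protein concentration, dimensionless) and the
space-time-yield (native protein produced per vessel volume and process
time, g/(L h)).  Both act as soft sensors: they need only the native
protein concentration and the total-protein feed balance, which are
available online.  The feed-rate sweep exposes the yield/productivity
tradeoff as a Pareto frontier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import FeedPolicy, KineticParameters, ReservoirSpec, VesselState
from .simulate import Trajectory, simulate

__all__ = [
    "KpiSeries",
    "ParetoResult",
    "refolding_yield",
    "space_time_yield",
    "kpi_series",
    "pareto_sweep",
    "ml_min_to_l_h",
]

#: 1 mL/min = 0.06 L/h
ML_MIN_TO_L_H = 0.06


def ml_min_to_l_h(rate_ml_min: float | np.ndarray) -> float | np.ndarray:
    """Convert a feed rate from mL/min (user-facing) to L/h (internal)."""
    return np.asarray(rate_ml_min, dtype=float) * ML_MIN_TO_L_H if np.ndim(rate_ml_min) else float(rate_ml_min) * ML_MIN_TO_L_H


def refolding_yield(c_NL, c_PL):
    """Refolding yield = c_NL / c_PL (native over total protein).

    Scalar or elementwise.  A zero total protein concentration makes the
    yield undefined and raises; series builders handle that case by
    reporting NaN before the first feed instead.
    """
    c_NL = np.asarray(c_NL, dtype=float)
    c_PL = np.asarray(c_PL, dtype=float)
    if np.any(c_NL < 0) or np.any(c_PL < 0):
        raise ValueError("concentrations must be >= 0")
    if np.any(c_PL == 0):
        raise ValueError("yield undefined: total protein concentration is zero")
    out = c_NL / c_PL
    return float(out) if out.ndim == 0 else out


def space_time_yield(c_NL, t):
    """Space-time-yield = c_NL / t [g/(L h)], with STY(0) = 0 by convention.

    From an initially protein-free vessel c_NL grows as O(t^2), so the
    t -> 0 limit of c_NL/t is 0; the convention makes the series start
    well-defined.
    """
    c_NL = np.asarray(c_NL, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("process time must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(t > 0, c_NL / np.where(t > 0, t, 1.0), 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class KpiSeries:
    """Yield and space-time-yield along a trajectory.

    ``yield_`` is NaN wherever total protein is zero (before the first
    feed in an initially empty vessel).  ``mean_sty`` is the trapezoidal
    time-average of instantaneous STY over the fed-batch phase [0, t_dep]
    (over the whole run if the reservoir never empties).
    """

    t: np.ndarray
    yield_: np.ndarray
    sty: np.ndarray
    max_yield: float
    mean_sty: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_h": self.t, "yield": self.yield_, "sty_g_L_h": self.sty})


def kpi_series(traj: Trajectory) -> KpiSeries:
    """Evaluate both KPIs along a simulated trajectory."""
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(traj.c_PL > 0, traj.c_NL / np.where(traj.c_PL > 0, traj.c_PL, 1.0), np.nan)
    y = np.where(np.isnan(y), np.nan, np.clip(y, 0.0, 1.0 + 1e-12))
    sty = space_time_yield(traj.c_NL, traj.t)
    t_hi = traj.t_dep if traj.t_dep is not None else traj.t[-1]
    mask = traj.t <= t_hi + 1e-12
    if mask.sum() >= 2:
        mean_sty = float(np.trapezoid(sty[mask], traj.t[mask]) / (traj.t[mask][-1] - traj.t[mask][0]))
    else:
        mean_sty = 0.0
    max_yield = float(np.nanmax(y)) if np.any(~np.isnan(y)) else np.nan
    return KpiSeries(t=traj.t, yield_=y, sty=sty, max_yield=max_yield, mean_sty=mean_sty)


@dataclass
class ParetoResult:
    """Per-feed-rate KPI summary from a sweep at otherwise equal conditions."""

    feed_rates_l_h: np.ndarray
    max_yield: np.ndarray
    mean_sty: np.ndarray
    errors: dict[int, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feed_rate_mL_min": self.feed_rates_l_h / ML_MIN_TO_L_H,
                "max_yield": self.max_yield,
                "mean_sty_g_L_h": self.mean_sty,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\r\n")

    def frontier_order(self) -> np.ndarray:
        """Indices sorted by increasing mean STY (frontier ordering)."""
        return np.argsort(self.mean_sty, kind="stable")


def pareto_sweep(
    initial: VesselState,
    res: ReservoirSpec,
    params: KineticParameters,
    feed_rates_l_h,
    t_end: float,
    output_grid=None,
) -> ParetoResult:
    """Simulate one run per constant feed rate and collect (max yield, mean STY).

    Every run shares the initial state, reservoir, kinetics and end time;
    only the constant feed rate differs.  Max yield is taken over the
    whole trajectory (yield keeps rising in the batch continuation);
    mean STY is averaged over the fed-batch phase.  A failed member run
    is recorded per rate without aborting the sweep.
    """
    rates = np.asarray(feed_rates_l_h, dtype=float)
    if rates.size < 1:
        raise ValueError("at least one feed rate required")
    max_y = np.full(rates.size, np.nan)
    mean_s = np.full(rates.size, np.nan)
    errors: dict[int, str] = {}
    for i, F in enumerate(rates):
        try:
            grid = output_grid
            if grid is None and F > 0:
                # refine inside the fed-batch phase so the mean-STY trapezoid
                # stays accurate for fast feeds with a short phase
                t_dep_nom = min(initial.t + res.V_R / F, t_end)
                grid = np.unique(
                    np.concatenate(
                        [
                            np.linspace(initial.t, t_end, 301),
                            np.linspace(initial.t, t_dep_nom, 201),
                        ]
                    )
                )
            traj = simulate(initial, res, FeedPolicy.constant(F), params, t_end, grid)
            k = kpi_series(traj)
            max_y[i], mean_s[i] = k.max_yield, k.mean_sty
        except Exception as exc:  # per-rate failure reporting
            errors[i] = f"{type(exc).__name__}: {exc}"
    return ParetoResult(feed_rates_l_h=rates, max_yield=max_y, mean_sty=mean_s, errors=errors)
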
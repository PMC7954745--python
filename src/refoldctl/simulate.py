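"""Fed-batch / batch trajectory integration.

Integrates the refolding ODE system through the fed-batch phase, locates
reservoir depletion as a terminal integrator event, and continues the run
in batch mode (zero feed) to the requested end time.  The integrated
state vector is (V_L, c_DL, c_SL, c_NL, c_AL, V_fed) where V_fed is the
cumulative fed volume used for depletion detection and for the total
protein soft sensor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import (
    FeedPolicy,
    KineticParameters,
    ReservoirSpec,
    VesselState,
    rate_constants,
    total_protein,
)

__all__ = ["Trajectory", "simulate", "analytic_batch_solution", "SimulationError"]

#: CSV schema shared by writers/readers (units embedded in column names).
TRAJECTORY_COLUMNS = [
    "t_h",
    "V_L_L",
    "c_SL_g_L",
    "c_NL_g_L",
    "c_AL_g_L",
    "c_DL_mol_L",
    "c_PL_g_L",
    "k_r",
    "k_a",
    "phase",
]


class SimulationError(RuntimeError):
    """Integrator failure; carries the last valid state reached."""

    def __init__(self, message: str, last_state: VesselState | None = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass
class Trajectory:
    """Dense simulated trajectory on a strictly increasing time grid.

    Arrays are aligned with ``t``; ``phase`` is "fed_batch" before the
    depletion time and "batch" afterwards.  Reported concentrations are
    clamped at zero (floating-point undershoot only); the raw integrator
    state is not modified during the run.
    """

    t: np.ndarray
    V_L: np.ndarray
    c_DL: np.ndarray
    c_SL: np.ndarray
    c_NL: np.ndarray
    c_AL: np.ndarray
    V_fed: np.ndarray
    c_PL: np.ndarray
    k_r: np.ndarray
    k_a: np.ndarray
    phase: np.ndarray
    t_dep: float | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def state_at(self, i: int) -> VesselState:
        return VesselState(
            t=float(self.t[i]),
            V_L=float(self.V_L[i]),
            c_SL=float(self.c_SL[i]),
            c_NL=float(self.c_NL[i]),
            c_AL=float(self.c_AL[i]),
            c_DL=float(self.c_DL[i]),
        )

    @property
    def final_state(self) -> VesselState:
        return self.state_at(len(self.t) - 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_h": self.t,
                "V_L_L": self.V_L,
                "c_SL_g_L": self.c_SL,
                "c_NL_g_L": self.c_NL,
                "c_AL_g_L": self.c_AL,
                "c_DL_mol_L": self.c_DL,
                "c_PL_g_L": self.c_PL,
                "k_r": self.k_r,
                "k_a": self.k_a,
                "phase": self.phase,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\r\n")


def _rhs(t, y, params, res, F_nominal):
    V_L, c_DL, c_SL, c_NL, c_AL, _ = y
    k_r, k_a = rate_constants(params, max(c_DL, 0.0))
    s = max(c_SL, 0.0)
    r_fold = k_r * s
    r_agg = k_a * s**params.n_agg
    D = F_nominal / V_L
    return [
        F_nominal,
        D * (res.c_DR - c_DL),
        -(r_fold + r_agg) + D * (res.c_SR - c_SL),
        r_fold - D * c_NL,
        r_agg - D * c_AL,
        F_nominal,
    ]


def simulate(
    initial: VesselState,
    res: ReservoirSpec,
    feed: FeedPolicy,
    params: KineticParameters,
    t_end: float,
    output_grid: float | np.ndarray | None = None,
    *,
    V_max: float | None = None,
    method: str = "LSODA",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Simulate fed-batch refolding followed by batch continuation.

    Parameters
    ----------
    initial:
        Vessel state at the start of the run.
    res, feed, params:
        Reservoir, feed policy and kinetic parameters.
    t_end:
        Final process time [h]; must exceed ``initial.t``.  The run always
        continues to ``t_end`` even after reservoir depletion.
    output_grid:
        Either a uniform output step [h], an explicit strictly increasing
        grid, or None for 500 uniform points.
    V_max:
        Optional vessel volume limit; a configuration in which the initial
        volume plus the whole reservoir exceeds it is rejected up front.

    Returns
    -------
    Trajectory
        Dense trajectory with total-protein soft sensor, evaluated rate
        constants and phase labels; ``t_dep`` is the depletion time
        located by the integrator event (absent if the reservoir never
        empties).
    """
    if t_end <= initial.t:
        raise ValueError(f"t_end ({t_end}) must exceed initial time ({initial.t})")
    if V_max is not None and initial.V_L + res.V_R > V_max + 1e-12:
        raise ValueError(
            f"infeasible configuration: V0 + V_R = {initial.V_L + res.V_R:.6g} L "
            f"exceeds vessel maximum {V_max:.6g} L"
        )

    if output_grid is None:
        grid = np.linspace(initial.t, t_end, 501)
    elif np.isscalar(output_grid):
        n = int(np.ceil((t_end - initial.t) / float(output_grid)))
        grid = initial.t + np.arange(n + 1) * float(output_grid)
        grid = grid[grid <= t_end + 1e-12]
        if grid[-1] < t_end - 1e-12:
            grid = np.append(grid, t_end)
    else:
        grid = np.asarray(output_grid, dtype=float)
        if grid[0] < initial.t - 1e-12 or grid[-1] > t_end + 1e-9:
            raise ValueError("explicit output grid must lie within [t0, t_end]")

    y = np.array([initial.V_L, initial.c_DL, initial.c_SL, initial.c_NL, initial.c_AL, 0.0])
    t_dep: float | None = None
    if res.V_R <= 0:
        t_dep = initial.t

    # Piecewise integration over feed-policy breakpoints; within each piece
    # the nominal rate is constant and depletion is a terminal event.
    pieces: list[tuple[float, float, object]] = []  # (t_lo, t_hi, dense solution)
    bps = feed.breakpoints(initial.t, t_end)
    i = 0
    t_cur = initial.t
    while t_cur < t_end - 1e-13:
        while i < len(bps) - 1 and bps[i + 1] <= t_cur + 1e-13:
            i += 1
        t_next = bps[i + 1] if i + 1 < len(bps) else t_end
        F_nom = feed.rate_at(0.5 * (t_cur + min(t_next, t_end)))
        depleted = t_dep is not None and t_cur >= t_dep - 1e-13
        F_eff = 0.0 if depleted else F_nom

        events = None
        if F_eff > 0 and t_dep is None:

            def depletion(t, yy, *args):
                return yy[5] - res.V_R

            depletion.terminal = True
            depletion.direction = 1
            events = depletion

        sol = solve_ivp(
            _rhs,
            (t_cur, t_next),
            y,
            args=(params, res, F_eff),
            method=method,
            rtol=rtol,
            atol=atol,
            dense_output=True,
            events=events,
        )
        if not sol.success:
            last = VesselState(
                t=float(sol.t[-1]),
                V_L=max(float(sol.y[0, -1]), 1e-12),
                c_SL=max(float(sol.y[2, -1]), 0.0),
                c_NL=max(float(sol.y[3, -1]), 0.0),
                c_AL=max(float(sol.y[4, -1]), 0.0),
                c_DL=max(float(sol.y[1, -1]), 0.0),
            )
            raise SimulationError(f"integrator failed: {sol.message}", last_state=last)

        t_reached = float(sol.t[-1])
        pieces.append((t_cur, t_reached, sol.sol))
        y = sol.y[:, -1].copy()
        if events is not None and sol.t_events[0].size:
            t_dep = float(sol.t_events[0][0])
            y[5] = res.V_R  # exact depletion, no overshoot
        t_cur = t_reached

    # Evaluate every piece on the output grid.
    Y = np.empty((6, len(grid)))
    Y[:, 0] = np.array(
        [initial.V_L, initial.c_DL, initial.c_SL, initial.c_NL, initial.c_AL, 0.0]
    )
    for j, tg in enumerate(grid):
        if j == 0 and abs(tg - initial.t) < 1e-13:
            continue
        for t_lo, t_hi, dense in pieces:
            if t_lo - 1e-12 <= tg <= t_hi + 1e-12:
                Y[:, j] = dense(np.clip(tg, t_lo, t_hi))
                break
        else:  # grid point at the very end, guard rounding
            Y[:, j] = pieces[-1][2](pieces[-1][1])

    V_L, c_DL, c_SL, c_NL, c_AL, V_fed = Y
    # clamp floating-point undershoot in reported output only
    c_DL = np.maximum(c_DL, 0.0)
    c_SL = np.maximum(c_SL, 0.0)
    c_NL = np.maximum(c_NL, 0.0)
    c_AL = np.maximum(c_AL, 0.0)
    V_fed = np.clip(V_fed, 0.0, res.V_R)

    k_r = np.empty_like(V_L)
    k_a = np.empty_like(V_L)
    for j in range(len(grid)):
        k_r[j], k_a[j] = rate_constants(params, c_DL[j])

    M0 = initial.protein_mass
    c_PL = total_protein(V_fed, res, V_L, initial_protein_mass=M0)

    if t_dep is not None:
        phase = np.where(grid < t_dep, "fed_batch", "batch")
    else:
        phase = np.array(
            ["fed_batch" if feed.rate_at(tg) > 0 else "batch" for tg in grid]
        )

    return Trajectory(
        t=grid,
        V_L=V_L,
        c_DL=c_DL,
        c_SL=c_SL,
        c_NL=c_NL,
        c_AL=c_AL,
        V_fed=V_fed,
        c_PL=c_PL,
        k_r=k_r,
        k_a=k_a,
        phase=phase,
        t_dep=t_dep,
    )


def analytic_batch_solution(
    c0: float,
    k_r: float,
    k_a: float,
    t: float | np.ndarray,
    n_agg: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form batch solution for second-order aggregation.

    The solubilized-protein balance dc/dt = -(k_r c + k_a c^2) is a
    Bernoulli equation with solution

        c_SL(t) = k_r c0 e^{-k_r t} / (k_r + k_a c0 (1 - e^{-k_r t}))
        c_NL(t) = (k_r / k_a) ln(1 + (k_a c0 / k_r)(1 - e^{-k_r t}))

    and c_AL = c0 - c_SL - c_NL, so protein mass is conserved exactly.
    Used as the independent oracle for the numerical integrator.
    """
    if n_agg != 2:
        raise ValueError(f"closed form implemented for n_agg=2 only, got {n_agg}")
    if k_r <= 0:
        raise ValueError("closed form requires k_r > 0")
    t = np.asarray(t, dtype=float)
    e = np.exp(-k_r * t)
    if k_a == 0:
        c_S = c0 * e
        c_N = c0 * (1.0 - e)
    else:
        denom = k_r + k_a * c0 * (1.0 - e)
        c_S = k_r * c0 * e / denom
        c_N = (k_r / k_a) * np.log1p((k_a * c0 / k_r) * (1.0 - e))
    c_A = c0 - c_S - c_N
    return c_S, c_N, np.maximum(c_A, 0.0)
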
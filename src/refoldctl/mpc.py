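"""Model-predictive control of the refolding feed rate.

At each control step the current state estimate seeds a prediction of
the vessel over a finite horizon for a candidate piecewise-constant feed
sequence; the quadratic cost

    J = sum_k [ w_Y (Y_ref - Y_k)^2 + w_STY (STY_ref - STY_k)^2 ]

penalises deviation of the predicted refolding yield and space-time-
yield from their references at the end of each step.  The optimiser
respects pump bounds, a slew limit on the step-to-step feed change, the
vessel volume limit and reservoir non-negativity, and applies only the
first move (receding horizon).  A brute-force grid solver over feed
levels is shipped as the optimisation oracle for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize

from .kinetics import FeedPolicy, KineticParameters, ReservoirSpec, VesselState, rate_constants
from .kpi import kpi_series
from .observer import ObserverConfig, RefoldingObserver, StateEstimate, estimates_to_frame
from .pat import SensorSpec, generate_measurements
from .simulate import Trajectory, simulate

__all__ = [
    "ControlObjective",
    "ClosedLoopResult",
    "MpcInfeasible",
    "predict_kpis",
    "mpc_step",
    "mpc_step_grid",
    "run_closed_loop",
]


class MpcInfeasible(RuntimeError):
    """Constraint set admits no feed sequence; names the binding constraint."""


@dataclass(frozen=True)
class ControlObjective:
    """MPC references, weights and constraints.

    ``Y_ref`` is a running yield target in [0, 1]; ``STY_ref`` a running
    space-time-yield target [g/(L h)] evaluated in global process time.
    ``dF_max`` limits the feed change per control step; ``V_max`` caps
    the vessel volume.
    """

    w_Y: float = 1.0
    w_STY: float = 0.0
    Y_ref: float = 1.0
    STY_ref: float = 0.0
    F_min: float = 0.0
    F_max: float = 0.1
    dF_max: float = np.inf
    V_max: float = np.inf
    horizon: int = 10
    dt_c: float = 0.1

    def __post_init__(self) -> None:
        if self.F_min > self.F_max:
            raise ValueError("F_min must not exceed F_max")
        if self.dF_max < 0 or self.w_Y < 0 or self.w_STY < 0:
            raise ValueError("weights and dF_max must be >= 0")
        if self.w_Y + self.w_STY <= 0:
            raise ValueError("at least one KPI weight must be positive")
        if self.horizon < 1 or self.dt_c <= 0:
            raise ValueError("horizon >= 1 and dt_c > 0 required")


def _predict_states(
    x0: np.ndarray,
    t0: float,
    feeds: np.ndarray,
    dt_c: float,
    params: KineticParameters,
    res: ReservoirSpec,
    v_fed0: float,
    m0: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate the internal model over the horizon for one feed sequence.

    Returns arrays of (yield, STY, V_L) at the end of each control step.
    Feeds are cut off at reservoir depletion inside each step.
    """
    x = x0.copy()
    v_fed = v_fed0
    t = t0
    Y = np.empty(len(feeds))
    STY = np.empty(len(feeds))
    V = np.empty(len(feeds))
    for k, F in enumerate(feeds):
        remaining = max(res.V_R - v_fed, 0.0)
        t_feed_end = t + (remaining / F if F > 0 else np.inf)

        def rhs(tt, y, Fk=F, cut=t_feed_end):
            Fe = Fk if tt < cut else 0.0
            Vl = max(y[0], 1e-9)
            k_r, k_a = rate_constants(params, max(y[1], 0.0))
            s = max(y[2], 0.0)
            rf, ra = k_r * s, k_a * s**params.n_agg
            D = Fe / Vl
            return [Fe, D * (res.c_DR - y[1]), -(rf + ra) + D * (res.c_SR - y[2]),
                    rf - D * y[3], ra - D * y[4]]

        sol = solve_ivp(rhs, (t, t + dt_c), x, method="RK45", rtol=1e-6, atol=1e-8)
        x = sol.y[:, -1]
        fed = min(F * dt_c, remaining)
        v_fed += fed
        t += dt_c
        m_tot = m0 + res.c_SR * v_fed
        c_PL = m_tot / max(x[0], 1e-9)
        Y[k] = x[3] / c_PL if c_PL > 0 else 0.0
        STY[k] = x[3] / t if t > 0 else 0.0
        V[k] = x[0]
    return Y, STY, V


def _cost_and_feasibility(Y, STY, V, obj: ControlObjective):
    cost = float(np.sum(obj.w_Y * (obj.Y_ref - Y) ** 2 + obj.w_STY * (obj.STY_ref - STY) ** 2))
    feasible = bool(np.all(V <= obj.V_max + 1e-9))
    return cost, feasible


def _admissible(feeds: np.ndarray, obj: ControlObjective, F_prev: float | None) -> bool:
    if np.any(feeds < obj.F_min - 1e-12) or np.any(feeds > obj.F_max + 1e-12):
        return False
    seq = feeds if F_prev is None else np.concatenate([[F_prev], feeds])
    return bool(np.all(np.abs(np.diff(seq)) <= obj.dF_max + 1e-12))


def mpc_step_grid(
    current: StateEstimate,
    obj: ControlObjective,
    params: KineticParameters,
    res: ReservoirSpec,
    n_levels: int = 5,
    F_prev: float | None = None,
    v_fed: float = 0.0,
    protein_mass: float | None = None,
) -> tuple[np.ndarray, float, float]:
    """Exhaustive grid-search MPC solve (test oracle).

    Enumerates all sequences over ``n_levels`` equispaced feed levels in
    [F_min, F_max] that satisfy the slew constraint, and returns the
    cheapest feasible one.
    """
    levels = np.linspace(obj.F_min, obj.F_max, n_levels)
    m0 = protein_mass if protein_mass is not None else float(
        current.mean[0] * (current.mean[2] + current.mean[3] + current.mean[4])
    ) - res.c_SR * v_fed
    best = None
    for seq in product(levels, repeat=obj.horizon):
        feeds = np.array(seq)
        if not _admissible(feeds, obj, F_prev):
            continue
        Y, STY, V = _predict_states(current.mean, current.t, feeds, obj.dt_c, params, res, v_fed, m0)
        cost, feasible = _cost_and_feasibility(Y, STY, V, obj)
        if feasible and (best is None or cost < best[1]):
            best = (feeds, cost)
    if best is None:
        raise MpcInfeasible("no admissible feed sequence on the grid (volume or slew constraint)")
    return best[0], float(best[0][0]), best[1]


def mpc_step(
    current: StateEstimate,
    obj: ControlObjective,
    params: KineticParameters,
    res: ReservoirSpec,
    F_prev: float | None = None,
    v_fed: float = 0.0,
    warm_start: np.ndarray | None = None,
    protein_mass: float | None = None,
) -> tuple[np.ndarray, float, float]:
    """One receding-horizon solve from the current state estimate.

    Returns ``(feed_sequence, first_move, predicted_cost)``.  The solver
    is SLSQP over the feed sequence with linear bound/slew/volume
    constraints, multi-started from the warm start (shifted previous
    solution), from F_min and from F_max.
    """
    H = obj.horizon
    # infeasibility screen: even the minimum feed may violate the volume cap
    V_lower = current.mean[0] + obj.F_min * obj.dt_c * np.arange(1, H + 1)
    V_lower = np.minimum(V_lower, current.mean[0] + max(res.V_R - v_fed, 0.0))
    if np.any(V_lower > obj.V_max + 1e-9):
        raise MpcInfeasible(
            f"F_min={obj.F_min} forces V_L beyond V_max={obj.V_max} within the horizon"
        )
    m0 = protein_mass if protein_mass is not None else float(
        current.mean[0] * (current.mean[2] + current.mean[3] + current.mean[4])
    ) - res.c_SR * v_fed

    def cost(feeds):
        Y, STY, V = _predict_states(current.mean, current.t, feeds, obj.dt_c, params, res, v_fed, m0)
        c, _ = _cost_and_feasibility(Y, STY, V, obj)
        # volume violation handled as explicit linear constraints below
        return c

    bounds = [(obj.F_min, obj.F_max)] * H
    cons = []
    if np.isfinite(obj.dF_max):
        for k in range(H - 1):
            cons.append({"type": "ineq", "fun": lambda f, k=k: obj.dF_max - abs(f[k + 1] - f[k])})
        if F_prev is not None:
            cons.append({"type": "ineq", "fun": lambda f: obj.dF_max - abs(f[0] - F_prev)})
    if np.isfinite(obj.V_max):
        # V_L at step k is linear in the feeds (before depletion): V0 + dt*sum(F)
        for k in range(H):
            cons.append(
                {"type": "ineq",
                 "fun": lambda f, k=k: obj.V_max - (current.mean[0] + obj.dt_c * np.sum(f[: k + 1]))}
            )

    starts = []
    if warm_start is not None and len(warm_start) == H:
        starts.append(np.clip(warm_start, obj.F_min, obj.F_max))
    starts.append(np.full(H, obj.F_min))
    starts.append(np.full(H, obj.F_max))
    starts.append(np.full(H, 0.5 * (obj.F_min + obj.F_max)))

    best = None
    for s0 in starts:
        if not _admissible(s0, obj, F_prev):
            if F_prev is not None and np.isfinite(obj.dF_max):
                s0 = np.clip(s0, F_prev - obj.dF_max * np.arange(1, H + 1),
                             F_prev + obj.dF_max * np.arange(1, H + 1))
                s0 = np.clip(s0, obj.F_min, obj.F_max)
        sol = minimize(cost, s0, method="SLSQP", bounds=bounds, constraints=cons,
                       options={"maxiter": 80, "ftol": 1e-12})
        feeds = np.clip(sol.x, obj.F_min, obj.F_max)
        if not _admissible(feeds, obj, F_prev):
            continue
        c = cost(feeds)
        if best is None or c < best[1]:
            best = (feeds, c)
    if best is None:
        raise MpcInfeasible("optimizer produced no admissible sequence (slew constraint)")
    return best[0], float(best[0][0]), best[1]


@dataclass
class ClosedLoopResult:
    """Outcome of a closed-loop run: plant truth, estimates, controls."""

    plant: Trajectory
    estimates: list[StateEstimate]
    applied_feeds: np.ndarray
    control_times: np.ndarray
    step_costs: np.ndarray
    realized_yield: np.ndarray
    realized_sty: np.ndarray

    def controls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_h": self.control_times, "F_R_L_h": self.applied_feeds,
             "predicted_cost": self.step_costs, "yield": self.realized_yield,
             "sty_g_L_h": self.realized_sty}
        )

    def estimates_frame(self) -> pd.DataFrame:
        return estimates_to_frame(self.estimates)


def run_closed_loop(
    initial: VesselState,
    res: ReservoirSpec,
    plant_params: KineticParameters,
    sensors: list[SensorSpec],
    obs_cfg: ObserverConfig,
    obj: ControlObjective,
    t_end: float,
    seed: int,
    model_params: KineticParameters | None = None,
    use_grid_solver: bool = False,
) -> ClosedLoopResult:
    """Simulate the full control loop: plant -> sensors -> observer -> MPC.

    The plant evolves under ``plant_params``; the observer and controller
    use ``model_params`` (defaults to the plant's — set differently for a
    plant-model mismatch study).  At every control step the loop emulates
    newly available measurements, updates the state estimate, solves the
    MPC problem and applies the first move until ``t_end``.  Feeding
    ceases at reservoir depletion.  Reproducible for a fixed seed.
    """
    model_params = model_params or plant_params
    n_steps = int(round((t_end - initial.t) / obj.dt_c))
    if n_steps < 1:
        raise ValueError("t_end must allow at least one control step")

    # plant truth is simulated step by step under the applied feeds
    state = initial
    v_fed = 0.0
    m0 = initial.protein_mass
    obs = RefoldingObserver(obs_cfg, model_params, res, sensors, t0=initial.t)
    est = StateEstimate(t=initial.t, mean=obs.kf.x.copy(), cov=obs.kf.P.copy())

    feeds, times, costs, ys, stys = [], [], [], [], []
    estimates = [est]
    plant_pieces: list[Trajectory] = []
    F_prev: float | None = None
    plan: np.ndarray | None = None
    delivered = 0.0

    for k in range(n_steps):
        t_k = initial.t + k * obj.dt_c
        solver = mpc_step_grid if use_grid_solver else mpc_step
        kw = {} if use_grid_solver else {"warm_start": None if plan is None else np.append(plan[1:], plan[-1])}
        seq, F_apply, cost = solver(est, obj, model_params, res, F_prev=F_prev,
                                    v_fed=v_fed, protein_mass=m0, **kw)
        plan = seq
        remaining = max(res.V_R - v_fed, 0.0)
        if remaining <= 1e-12:
            F_apply = 0.0  # reservoir empty: feeding ceases
        F_cap = remaining / obj.dt_c
        F_eff = min(F_apply, F_cap)

        piece = simulate(state, res.__class__(c_SR=res.c_SR, c_DR=res.c_DR, V_R=remaining),
                         FeedPolicy.constant(F_eff, t_start=t_k, t_end=t_k + obj.dt_c),
                         plant_params, t_k + obj.dt_c,
                         output_grid=np.linspace(t_k, t_k + obj.dt_c, 11))
        plant_pieces.append(piece)
        v_fed += float(piece.V_fed[-1])
        state = piece.final_state

        # measurements that became available during this step
        full_meas = _loop_measurements(plant_pieces, sensors, seed, initial.t)
        win = full_meas.records[
            (full_meas.records["t_available_h"] > t_k + 1e-12)
            & (full_meas.records["t_available_h"] <= t_k + obj.dt_c + 1e-12)
        ]
        est = obs.step(t_k + obj.dt_c, F_eff, win)
        estimates.append(est)

        m_tot = m0 + res.c_SR * v_fed
        c_PL = m_tot / state.V_L if state.V_L > 0 else 0.0
        feeds.append(F_eff)
        times.append(t_k)
        costs.append(cost)
        ys.append(state.c_NL / c_PL if c_PL > 0 else np.nan)
        stys.append(state.c_NL / state.t if state.t > 0 else 0.0)
        F_prev = F_eff

    plant = _concat_pieces(plant_pieces)
    if plant.t_dep is None and v_fed >= res.V_R - 1e-9:
        # reservoir emptied exactly at a step boundary: locate the first
        # grid time at which the cumulative fed volume reaches V_R
        idx = int(np.argmax(plant.V_fed >= res.V_R - 1e-9))
        plant.t_dep = float(plant.t[idx])
        plant.phase = np.where(plant.t < plant.t_dep, "fed_batch", "batch")
    return ClosedLoopResult(
        plant=plant,
        estimates=estimates,
        applied_feeds=np.array(feeds),
        control_times=np.array(times),
        step_costs=np.array(costs),
        realized_yield=np.array(ys),
        realized_sty=np.array(stys),
    )


def _loop_measurements(pieces, sensors, seed, t0):
    traj = _concat_pieces(pieces)
    return generate_measurements(traj, sensors, seed)


def _concat_pieces(pieces: list[Trajectory]) -> Trajectory:
    t, V, cD, cS, cN, cA, vf, cP, kr, ka, ph = [], [], [], [], [], [], [], [], [], [], []
    v_fed_off = 0.0
    t_dep = None
    for i, p in enumerate(pieces):
        sl = slice(0 if i == 0 else 1, None)
        t.append(p.t[sl]); V.append(p.V_L[sl]); cD.append(p.c_DL[sl])
        cS.append(p.c_SL[sl]); cN.append(p.c_NL[sl]); cA.append(p.c_AL[sl])
        vf.append(p.V_fed[sl] + v_fed_off); cP.append(p.c_PL[sl])
        kr.append(p.k_r[sl]); ka.append(p.k_a[sl]); ph.append(p.phase[sl])
        v_fed_off += float(p.V_fed[-1])
        if t_dep is None and p.t_dep is not None:
            t_dep = p.t_dep
    return Trajectory(
        t=np.concatenate(t), V_L=np.concatenate(V), c_DL=np.concatenate(cD),
        c_SL=np.concatenate(cS), c_NL=np.concatenate(cN), c_AL=np.concatenate(cA),
        V_fed=np.concatenate(vf), c_PL=np.concatenate(cP), k_r=np.concatenate(kr),
        k_a=np.concatenate(ka), phase=np.concatenate(ph), t_dep=t_dep,
    )
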
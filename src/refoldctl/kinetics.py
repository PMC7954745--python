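"""Core kinetic model of dilution refolding.

The refolding reaction network is the off-pathway scheme: solubilized
protein S either folds to native protein N (first order, rate constant
``k_r``) or aggregates irreversibly (order ``n_agg``, default 2, rate
coefficient ``k_a``).  In fed-batch operation solubilizate is fed from a
finite reservoir, which adds dilution terms to every species balance and
makes vessel volume and denaturant concentration dynamic.

Units: time in h, volume in L, protein concentrations in g/L, denaturant
in mol/L.  Both vessel and reservoir denaturant concentrations are mol/L.
When rate constants depend on the denaturant concentration they follow

    k_i = a_i * (1 + c_DL)^b_i ,   i in {r, a},

with c_DL the numeric value of the denaturant concentration in mol/L
(i.e. relative to a 1 mol/L reference, so the base of the power is
dimensionless).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "RateMode",
    "KineticParameters",
    "VesselState",
    "ReservoirSpec",
    "FeedPolicy",
    "rate_constants",
    "batch_derivatives",
    "fedbatch_derivatives",
    "total_protein",
]


class RateMode(str, Enum):
    """Whether rate constants are fixed or denaturant-dependent."""

    CONSTANT = "constant"
    DENATURANT_DEPENDENT = "denaturant_dependent"


@dataclass(frozen=True)
class KineticParameters:
    """Rate-law parameters of the off-pathway refolding model.

    Parameters
    ----------
    mode:
        ``constant`` uses ``k_r``/``k_a`` directly; ``denaturant_dependent``
        evaluates ``k_i = a_i * (1 + c_DL)**b_i``.
    k_r:
        Refolding rate constant [1/h] (``constant`` mode).
    k_a:
        Aggregation rate coefficient [L^(n-1) g^(1-n) / h] (``constant`` mode).
    a_r, a_a:
        Pre-factors of the denaturant law, same units as ``k_r``/``k_a``.
    b_r, b_a:
        Dimensionless exponents of the denaturant law (typically negative:
        denaturant slows both reactions, aggregation more strongly).
    n_agg:
        Aggregation reaction order, integer >= 1.  Second order is the
        standard choice; first order applies at low protein concentration.
    """

    mode: RateMode = RateMode.CONSTANT
    k_r: float = 1.0
    k_a: float = 1.0
    a_r: float = 1.0
    a_a: float = 1.0
    b_r: float = 0.0
    b_a: float = 0.0
    n_agg: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", RateMode(self.mode))
        for name in ("k_r", "k_a", "a_r", "a_a"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not (isinstance(self.n_agg, (int, np.integer)) and self.n_agg >= 1):
            raise ValueError(f"n_agg must be an integer >= 1, got {self.n_agg!r}")

    def replace(self, **kwargs) -> "KineticParameters":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass
class VesselState:
    """Instantaneous state of the refolding vessel.

    Fields: process time ``t`` [h], liquid volume ``V_L`` [L], solubilized
    ``c_SL``, native ``c_NL`` and aggregated ``c_AL`` protein [g/L], and
    denaturant ``c_DL`` [mol/L].
    """

    t: float = 0.0
    V_L: float = 1.0
    c_SL: float = 0.0
    c_NL: float = 0.0
    c_AL: float = 0.0
    c_DL: float = 0.0

    def __post_init__(self) -> None:
        if self.V_L <= 0:
            raise ValueError(f"V_L must be > 0, got {self.V_L}")
        if self.t < 0:
            raise ValueError(f"t must be >= 0, got {self.t}")
        for name in ("c_SL", "c_NL", "c_AL", "c_DL"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    @property
    def protein_mass(self) -> float:
        """Total protein mass in the vessel [g]."""
        return self.V_L * (self.c_SL + self.c_NL + self.c_AL)

    def as_vector(self) -> np.ndarray:
        """State vector (V_L, c_DL, c_SL, c_NL, c_AL) used by the integrator."""
        return np.array([self.V_L, self.c_DL, self.c_SL, self.c_NL, self.c_AL])


@dataclass(frozen=True)
class ReservoirSpec:
    """Finite feed reservoir holding solubilizate only.

    The reservoir contains solubilized protein at ``c_SR`` [g/L] and
    denaturant at ``c_DR`` [mol/L] in an initial volume ``V_R`` [L]; no
    native or aggregated protein enters with the feed.
    """

    c_SR: float = 40.0
    c_DR: float = 6.0
    V_R: float = 0.1

    def __post_init__(self) -> None:
        for name in ("c_SR", "c_DR", "V_R"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class FeedPolicy:
    """Piecewise-constant feed-rate profile.

    ``segments`` is an ordered tuple of ``(t_start, t_end, F_R)`` with
    F_R in L/h.  Outside every segment the feed rate is 0.  The simulator
    additionally forces the effective rate to 0 once the cumulative fed
    volume reaches the reservoir volume.
    """

    segments: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        segs = tuple(tuple(float(x) for x in s) for s in self.segments)
        object.__setattr__(self, "segments", segs)
        prev_end = -np.inf
        for t0, t1, f in segs:
            if t1 <= t0:
                raise ValueError(f"segment ({t0}, {t1}) has non-positive duration")
            if f < 0:
                raise ValueError(f"feed rate must be >= 0, got {f}")
            if t0 < prev_end - 1e-12:
                raise ValueError("feed segments must be non-overlapping and time-ordered")
            prev_end = t1

    @classmethod
    def constant(cls, F_R: float, t_start: float = 0.0, t_end: float = np.inf) -> "FeedPolicy":
        """Constant feed at ``F_R`` L/h from ``t_start`` until ``t_end``."""
        return cls(segments=((t_start, t_end, F_R),))

    @classmethod
    def pulsed(
        cls,
        F_R: float,
        pulse_duration: float,
        period: float,
        n_pulses: int,
        t_start: float = 0.0,
    ) -> "FeedPolicy":
        """``n_pulses`` pulses of rate ``F_R`` and length ``pulse_duration``
        repeated every ``period`` hours."""
        if pulse_duration > period:
            raise ValueError("pulse_duration must not exceed period")
        segs = tuple(
            (t_start + k * period, t_start + k * period + pulse_duration, F_R)
            for k in range(n_pulses)
        )
        return cls(segments=segs)

    def rate_at(self, t: float) -> float:
        """Nominal feed rate at time ``t`` (ignores reservoir depletion)."""
        for t0, t1, f in self.segments:
            if t0 <= t < t1:
                return f
        return 0.0

    def breakpoints(self, t0: float, t1: float) -> np.ndarray:
        """Sorted segment boundaries inside [t0, t1], including endpoints."""
        pts = {t0, t1}
        for a, b, _ in self.segments:
            for p in (a, b):
                if t0 < p < t1 and np.isfinite(p):
                    pts.add(float(p))
        return np.array(sorted(pts))


def rate_constants(params: KineticParameters, c_DL: float) -> tuple[float, float]:
    """Evaluate (k_r, k_a) at denaturant concentration ``c_DL`` [mol/L].

    In ``constant`` mode the stored constants are returned unchanged; in
    ``denaturant_dependent`` mode ``k_i = a_i * (1 + c_DL)**b_i``.
    """
    if c_DL < 0:
        raise ValueError(f"denaturant concentration must be >= 0, got {c_DL}")
    if params.mode is RateMode.CONSTANT:
        return params.k_r, params.k_a
    base = 1.0 + c_DL
    return params.a_r * base**params.b_r, params.a_a * base**params.b_a


def batch_derivatives(
    state: VesselState, params: KineticParameters
) -> tuple[float, float, float]:
    """Species balances of closed-vessel (batch) refolding.

    Returns (dc_SL/dt, dc_NL/dt, dc_AL/dt); the three sum to zero because
    the batch system conserves protein mass.
    """
    k_r, k_a = rate_constants(params, state.c_DL)
    r_fold = k_r * state.c_SL
    r_agg = k_a * state.c_SL**params.n_agg
    return (-(r_fold + r_agg), r_fold, r_agg)


def fedbatch_derivatives(
    state: VesselState,
    params: KineticParameters,
    F_R: float,
    res: ReservoirSpec,
) -> tuple[float, float, float, float, float]:
    """Fed-batch balances: (dV_L/dt, dc_DL/dt, dc_SL/dt, dc_NL/dt, dc_AL/dt).

    The feed carries solubilized protein at ``res.c_SR`` and denaturant at
    ``res.c_DR``; every vessel concentration gains a dilution term
    ``(F_R/V_L) * (c_in - c)`` with ``c_in = 0`` for native and aggregate.
    """
    if state.V_L <= 0:
        raise ValueError(f"singular state: V_L = {state.V_L}")
    if F_R < 0:
        raise ValueError(f"feed rate must be >= 0, got {F_R}")
    dS, dN, dA = batch_derivatives(state, params)
    D = F_R / state.V_L  # dilution rate [1/h]
    return (
        F_R,
        D * (res.c_DR - state.c_DL),
        dS + D * (res.c_SR - state.c_SL),
        dN - D * state.c_NL,
        dA - D * state.c_AL,
    )


def total_protein(
    fed_volume: Sequence[float] | np.ndarray,
    res: ReservoirSpec,
    V_L: Sequence[float] | np.ndarray,
    initial_protein_mass: float = 0.0,
) -> np.ndarray:
    """Total protein concentration series from the cumulative feed balance.

    c_PL(t) = (M0 + c_SR * V_fed(t)) / V_L(t).  For a constant feed, no
    initial protein and no depletion this is the classical soft-sensor
    expression c_PL = F_R * t * c_SR / V_L.
    """
    V_fed = np.asarray(fed_volume, dtype=float)
    V = np.asarray(V_L, dtype=float)
    if np.any(np.diff(V_fed) < -1e-12):
        raise ValueError("cumulative fed volume must be non-decreasing")
    if np.any(V_fed > res.V_R + 1e-9):
        raise ValueError("cumulative fed volume exceeds reservoir volume")
    if np.any(V <= 0):
        raise ValueError("singular state: V_L <= 0")
    if initial_protein_mass < 0:
        raise ValueError("initial protein mass must be >= 0")
    return (initial_protein_mass + res.c_SR * V_fed) / V
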
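"""Scenario configuration: YAML loading, validation, fixture registry.

A scenario file is a single YAML document with sections mirroring the
domain types (vessel, reservoir, kinetics, feed, sensors, observer,
objective, simulation).  Loading re-validates every type invariant and
rejects unknown keys by name; load -> dump -> load is idempotent.

The kinetic parameter values shipped with the registry scenarios are
documented synthetic defaults for testing and demonstration — published
refolding studies fit them per protein and buffer system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .kinetics import FeedPolicy, KineticParameters, ReservoirSpec, VesselState
from .mpc import ControlObjective
from .observer import ObserverConfig
from .pat import SENSOR_PRESETS, SensorSpec

__all__ = ["ScenarioConfig", "load_scenario", "dump_scenario", "SCENARIOS", "get_scenario"]

_SECTIONS = {"vessel", "reservoir", "kinetics", "feed", "sensors", "observer", "objective", "simulation"}


@dataclass
class ScenarioConfig:
    """Fully validated scenario: every section is a constructed domain object."""

    vessel: VesselState
    reservoir: ReservoirSpec
    kinetics: KineticParameters
    feed: FeedPolicy
    sensors: tuple[SensorSpec, ...] = ()
    observer: ObserverConfig | None = None
    objective: ControlObjective | None = None
    t_end: float = 10.0
    output_step: float | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        d: dict = {
            "vessel": {"t": self.vessel.t, "V_L": self.vessel.V_L, "c_SL": self.vessel.c_SL,
                       "c_NL": self.vessel.c_NL, "c_AL": self.vessel.c_AL, "c_DL": self.vessel.c_DL},
            "reservoir": {"c_SR": self.reservoir.c_SR, "c_DR": self.reservoir.c_DR,
                          "V_R": self.reservoir.V_R},
            "kinetics": {"mode": self.kinetics.mode.value, "k_r": self.kinetics.k_r,
                         "k_a": self.kinetics.k_a, "a_r": self.kinetics.a_r,
                         "a_a": self.kinetics.a_a, "b_r": self.kinetics.b_r,
                         "b_a": self.kinetics.b_a, "n_agg": self.kinetics.n_agg},
            "feed": {"segments": [list(s) for s in self.feed.segments]},
            "simulation": {"t_end": self.t_end},
        }
        if self.output_step is not None:
            d["simulation"]["output_step"] = self.output_step
        if self.seed is not None:
            d["simulation"]["seed"] = self.seed
        if self.sensors:
            d["sensors"] = [
                {"quantity": s.quantity, "sampling_period": s.sampling_period,
                 "feedback_delay": s.feedback_delay, "noise_sd_abs": s.noise_sd_abs,
                 "noise_sd_rel": s.noise_sd_rel, "loq": s.loq}
                for s in self.sensors
            ]
        if self.observer is not None:
            o = self.observer
            d["observer"] = {"filter_family": o.filter_family,
                             "process_noise": [float(x) for x in o.process_noise],
                             "update_step": o.update_step}
            if o.initial_mean is not None:
                d["observer"]["initial_mean"] = [float(x) for x in o.initial_mean]
            if o.initial_cov is not None:
                d["observer"]["initial_cov"] = np.asarray(o.initial_cov).tolist()
        if self.objective is not None:
            ob = self.objective
            d["objective"] = {"w_Y": ob.w_Y, "w_STY": ob.w_STY, "Y_ref": ob.Y_ref,
                              "STY_ref": ob.STY_ref, "F_min": ob.F_min, "F_max": ob.F_max,
                              "dF_max": ob.dF_max if np.isfinite(ob.dF_max) else "inf",
                              "V_max": ob.V_max if np.isfinite(ob.V_max) else "inf",
                              "horizon": ob.horizon, "dt_c": ob.dt_c}
        return d


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in section '{section}': {sorted(unknown)}")


def _build(raw: dict, source: str) -> ScenarioConfig:
    if not isinstance(raw, dict):
        raise ValueError(f"{source}: top level must be a mapping")
    _check_keys("<top>", raw, _SECTIONS)
    for required in ("vessel", "reservoir", "kinetics", "feed", "simulation"):
        if required not in raw:
            raise ValueError(f"{source}: missing required section '{required}'")

    v = raw["vessel"]
    _check_keys("vessel", v, {"t", "V_L", "c_SL", "c_NL", "c_AL", "c_DL"})
    vessel = VesselState(**v)

    r = raw["reservoir"]
    _check_keys("reservoir", r, {"c_SR", "c_DR", "V_R"})
    reservoir = ReservoirSpec(**r)

    k = raw["kinetics"]
    _check_keys("kinetics", k, {"mode", "k_r", "k_a", "a_r", "a_a", "b_r", "b_a", "n_agg"})
    kinetics = KineticParameters(**k)

    f = raw["feed"]
    _check_keys("feed", f, {"segments", "constant", "t_start", "t_end"})
    if "constant" in f:
        feed = FeedPolicy.constant(f["constant"], f.get("t_start", 0.0), f.get("t_end", np.inf))
    else:
        feed = FeedPolicy(segments=tuple(tuple(s) for s in f.get("segments", [])))

    sensors: list[SensorSpec] = []
    for i, s in enumerate(raw.get("sensors", []) or []):
        if isinstance(s, str):
            if s not in SENSOR_PRESETS:
                raise ValueError(f"unknown sensor preset {s!r}; available: {sorted(SENSOR_PRESETS)}")
            sensors.append(SENSOR_PRESETS[s])
        else:
            _check_keys(f"sensors[{i}]", s,
                        {"quantity", "sampling_period", "feedback_delay",
                         "noise_sd_abs", "noise_sd_rel", "loq"})
            sensors.append(SensorSpec(**s))

    observer = None
    if "observer" in raw:
        o = dict(raw["observer"])
        _check_keys("observer", o, {"filter_family", "process_noise", "initial_mean",
                                    "initial_cov", "update_step", "alpha", "beta", "kappa"})
        for key in ("process_noise", "initial_mean", "initial_cov"):
            if key in o and o[key] is not None:
                o[key] = np.asarray(o[key], dtype=float)
        observer = ObserverConfig(**o)

    objective = None
    if "objective" in raw:
        ob = dict(raw["objective"])
        _check_keys("objective", ob, {"w_Y", "w_STY", "Y_ref", "STY_ref", "F_min", "F_max",
                                      "dF_max", "V_max", "horizon", "dt_c"})
        for key in ("dF_max", "V_max"):
            if ob.get(key) == "inf":
                ob[key] = np.inf
        try:
            objective = ControlObjective(**ob)
        except ValueError as exc:
            raise ValueError(f"objective: {exc}") from exc

    sim = raw["simulation"]
    _check_keys("simulation", sim, {"t_end", "output_step", "seed"})
    if sim["t_end"] <= vessel.t:
        raise ValueError("simulation.t_end must exceed vessel.t")

    return ScenarioConfig(
        vessel=vessel, reservoir=reservoir, kinetics=kinetics, feed=feed,
        sensors=tuple(sensors), observer=observer, objective=objective,
        t_end=float(sim["t_end"]), output_step=sim.get("output_step"),
        seed=sim.get("seed"),
    )


def load_scenario(path) -> ScenarioConfig:
    """Load and fully validate a YAML scenario file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"{path}: YAML parse error: {exc}") from exc
    try:
        return _build(raw, str(path))
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: {exc}") from exc


def dump_scenario(cfg: ScenarioConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# fixture scenario registry (synthetic defaults, documented in docs/methods.md)

def _baseline() -> ScenarioConfig:
    """Fed-batch run with denaturant-dependent kinetics; depletion at 5 h."""
    return ScenarioConfig(
        vessel=VesselState(t=0.0, V_L=1.0, c_DL=0.5),
        reservoir=ReservoirSpec(c_SR=40.0, c_DR=6.0, V_R=0.1),
        kinetics=KineticParameters(mode="denaturant_dependent",
                                   a_r=2.0, b_r=-1.0, a_a=2.0, b_a=-2.0, n_agg=2),
        feed=FeedPolicy.constant(0.02),
        sensors=(SENSOR_PRESETS["hplc_solubilized"], SENSOR_PRESETS["hplc_native"],
                 SENSOR_PRESETS["dls_aggregate"]),
        t_end=10.0,
        seed=0,
    )


def _pareto_base() -> ScenarioConfig:
    """Constant-rate kinetics for feed-rate sweeps (rates set per run).

    Folding on a minutes timescale (k_r = 10/h) against strong
    second-order aggregation (k_a = 10 L/(g h)) — a regime in which the
    swept rate range spans the whole yield/productivity tradeoff.
    """
    return ScenarioConfig(
        vessel=VesselState(t=0.0, V_L=1.0, c_DL=0.0),
        reservoir=ReservoirSpec(c_SR=40.0, c_DR=0.0, V_R=0.1),
        kinetics=KineticParameters(mode="constant", k_r=10.0, k_a=10.0, n_agg=2),
        feed=FeedPolicy.constant(0.02),
        t_end=130.0,
        seed=0,
    )


def _control_demo() -> ScenarioConfig:
    """Short closed-loop demonstration scenario."""
    mean0 = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    cov0 = np.diag([1e-6, 1e-6, 1e-4, 1e-4, 1e-4])
    return ScenarioConfig(
        vessel=VesselState(t=0.0, V_L=1.0, c_DL=0.0),
        reservoir=ReservoirSpec(c_SR=40.0, c_DR=0.0, V_R=0.1),
        kinetics=KineticParameters(mode="constant", k_r=1.0, k_a=1.0, n_agg=2),
        feed=FeedPolicy.constant(0.02),
        sensors=(SENSOR_PRESETS["ftir_native"], SENSOR_PRESETS["total_protein"],
                 SENSOR_PRESETS["dls_aggregate"]),
        observer=ObserverConfig(initial_mean=mean0, initial_cov=cov0, update_step=0.1),
        objective=ControlObjective(w_Y=1.0, w_STY=0.0, Y_ref=0.9, STY_ref=0.0,
                                   F_min=0.0, F_max=0.1, dF_max=0.05, V_max=1.2,
                                   horizon=5, dt_c=0.1),
        t_end=2.0,
        seed=0,
    )


SCENARIOS = {"baseline": _baseline, "pareto_base": _pareto_base, "control_demo": _control_demo}


def get_scenario(name: str) -> ScenarioConfig:
    """Fetch a registry scenario by name (fresh object per call)."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}")
    return SCENARIOS[name]()
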
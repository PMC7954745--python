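"""Synthetic PAT measurement emulation.

Turns a ground-truth trajectory into the measurement streams a process
analytical technology (PAT) suite would deliver: each sensor samples one
quantity on its own period, reports after a feedback delay, adds Gaussian
noise (absolute and/or relative standard deviation) and censors values
whose true concentration lies below the limit of quantification (LOQ).

The presets mimic the character of common refolding analytics —
fast inline FTIR for native protein, slower RP-HPLC with an LOQ of
0.01 g/L for species resolution, and light-scattering for aggregates
with a larger relative error.  Apart from the HPLC LOQ the preset
numbers are this package's own defaults, not instrument datasheet
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .simulate import Trajectory

__all__ = ["SensorSpec", "MeasurementSet", "generate_measurements", "SENSOR_PRESETS"]

#: Quantities a sensor may observe (c_PL is the total-protein soft signal).
OBSERVABLE_QUANTITIES = ("c_SL", "c_NL", "c_AL", "c_DL", "c_PL")


@dataclass(frozen=True)
class SensorSpec:
    """One sensor channel.

    Parameters
    ----------
    quantity:
        Which vessel quantity is observed (one of c_SL, c_NL, c_AL,
        c_DL, c_PL).
    sampling_period:
        Time between samples [h].
    feedback_delay:
        Delay between sampling and result availability [h]; consumers
        (observer, MPC) may only use a record once its availability time
        has passed.
    noise_sd_abs, noise_sd_rel:
        Absolute [same units as the quantity] and relative [fraction of
        truth] noise standard deviations; the total sd is their sum
        sd = abs + rel * truth.
    loq:
        Limit of quantification; a true value below it is reported as a
        censored record carrying the LOQ itself, never a fabricated value.
    """

    quantity: str
    sampling_period: float
    feedback_delay: float = 0.0
    noise_sd_abs: float = 0.0
    noise_sd_rel: float = 0.0
    loq: float = 0.0

    def __post_init__(self) -> None:
        if self.quantity not in OBSERVABLE_QUANTITIES:
            raise ValueError(
                f"unknown quantity {self.quantity!r}; expected one of {OBSERVABLE_QUANTITIES}"
            )
        if self.sampling_period <= 0:
            raise ValueError("sampling_period must be > 0")
        for name in ("feedback_delay", "noise_sd_abs", "noise_sd_rel", "loq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def sd_at(self, truth: float) -> float:
        return self.noise_sd_abs + self.noise_sd_rel * abs(truth)

    def with_(self, **kw) -> "SensorSpec":
        return replace(self, **kw)


#: Named presets keyed after the analytical technique they emulate.
SENSOR_PRESETS: dict[str, SensorSpec] = {
    # inline FTIR on native protein: seconds-scale feedback, usable for control
    "ftir_native": SensorSpec(
        quantity="c_NL", sampling_period=0.003, feedback_delay=0.0,
        noise_sd_abs=0.02, noise_sd_rel=0.02,
    ),
    # online RP-HPLC: species-resolved but slow, LOQ 0.01 g/L
    "hplc_solubilized": SensorSpec(
        quantity="c_SL", sampling_period=0.5, feedback_delay=0.25,
        noise_sd_abs=0.005, noise_sd_rel=0.02, loq=0.01,
    ),
    "hplc_native": SensorSpec(
        quantity="c_NL", sampling_period=0.5, feedback_delay=0.25,
        noise_sd_abs=0.005, noise_sd_rel=0.02, loq=0.01,
    ),
    # DLS/MALS aggregate signal: fast but noisier, mostly relative error
    "dls_aggregate": SensorSpec(
        quantity="c_AL", sampling_period=0.02, feedback_delay=0.0,
        noise_sd_abs=0.01, noise_sd_rel=0.10,
    ),
    # total-protein soft signal from the feed balance
    "total_protein": SensorSpec(
        quantity="c_PL", sampling_period=0.05, feedback_delay=0.0,
        noise_sd_abs=0.01, noise_sd_rel=0.01,
    ),
}


@dataclass
class MeasurementSet:
    """Table of sensor records plus the generating specs and seed.

    Columns: t_sample_h, t_available_h, quantity, value_g_L, censored.
    Censored records carry the sensor LOQ in the value column.
    """

    records: pd.DataFrame
    sensors: tuple[SensorSpec, ...]
    seed: int

    COLUMNS = ["t_sample_h", "t_available_h", "quantity", "value_g_L", "censored"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"measurement table missing columns: {missing}")
        if np.any(self.records["t_available_h"] < self.records["t_sample_h"] - 1e-12):
            raise ValueError("availability time must be >= sample time")

    def available_at(self, t: float) -> pd.DataFrame:
        """Records whose availability time has passed by process time ``t``."""
        return self.records[self.records["t_available_h"] <= t + 1e-12]

    def for_quantity(self, quantity: str) -> pd.DataFrame:
        return self.records[self.records["quantity"] == quantity]

    def to_csv(self, path) -> None:
        self.records[self.COLUMNS].to_csv(path, index=False, lineterminator="\r\n")

    @classmethod
    def from_csv(cls, path, sensors: tuple[SensorSpec, ...] = (), seed: int = 0) -> "MeasurementSet":
        df = pd.read_csv(path)
        missing = [c for c in cls.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"measurement CSV missing mandatory columns: {missing}")
        df["censored"] = df["censored"].astype(bool)
        return cls(records=df, sensors=tuple(sensors), seed=seed)


def generate_measurements(
    traj: Trajectory,
    sensors,
    seed: int,
) -> MeasurementSet:
    """Emulate every sensor channel against a ground-truth trajectory.

    Sample times are laid on each sensor's period starting at the
    trajectory start; truth is linearly interpolated from the dense
    trajectory.  Identical seed and inputs reproduce the output exactly.
    """
    sensors = tuple(sensors)
    t0, t1 = float(traj.t[0]), float(traj.t[-1])
    rows = []
    for si, spec in enumerate(sensors):
        # one stream per sensor channel: the j-th sample of a channel gets
        # the same noise draw regardless of how far the trajectory extends,
        # so incremental emulation in a closed loop is self-consistent
        rng = np.random.default_rng([int(seed), si])
        n = int(np.floor((t1 - t0) / spec.sampling_period + 1e-9))
        t_samples = t0 + spec.sampling_period * np.arange(1, n + 1)
        if t_samples.size and (t_samples[0] < t0 - 1e-9 or t_samples[-1] > t1 + 1e-9):
            raise ValueError("sample time outside trajectory span")
        truth = np.interp(t_samples, traj.t, getattr(traj, spec.quantity))
        sd = spec.noise_sd_abs + spec.noise_sd_rel * np.abs(truth)
        noise = rng.standard_normal(t_samples.size) * sd
        censored = truth < spec.loq
        # uncensored readings are floored at the LOQ (an instrument never
        # reports a quantified value below its quantification limit)
        value = np.where(censored, spec.loq, np.maximum(truth + noise, spec.loq))
        for ts, v, c in zip(t_samples, value, censored):
            rows.append(
                (float(ts), float(ts + spec.feedback_delay), spec.quantity, float(v), bool(c))
            )
    df = pd.DataFrame(rows, columns=MeasurementSet.COLUMNS)
    df = df.sort_values(["t_available_h", "t_sample_h", "quantity"], kind="stable").reset_index(
        drop=True
    )
    return MeasurementSet(records=df, sensors=sensors, seed=seed)
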
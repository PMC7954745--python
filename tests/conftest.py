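import numpy as np
import pytest

from refoldctl import (
    FeedPolicy,
    KineticParameters,
    ReservoirSpec,
    SensorSpec,
    VesselState,
    simulate,
)


@pytest.fixture
def constant_params():
    """Second-order aggregation, constant rates k_r = k_a = 1."""
    return KineticParameters(mode="constant", k_r=1.0, k_a=1.0, n_agg=2)


@pytest.fixture
def denaturant_params():
    return KineticParameters(
        mode="denaturant_dependent", a_r=2.0, b_r=-1.0, a_a=2.0, b_a=-2.0, n_agg=2
    )


@pytest.fixture
def empty_vessel():
    return VesselState(t=0.0, V_L=1.0, c_DL=0.0)


@pytest.fixture
def reservoir():
    return ReservoirSpec(c_SR=40.0, c_DR=6.0, V_R=0.1)


@pytest.fixture
def fedbatch_traj(empty_vessel, reservoir, constant_params):
    """Reference fed-batch run: depletion at 5 h, batch continuation to 12 h."""
    return simulate(
        empty_vessel, reservoir, FeedPolicy.constant(0.02), constant_params, t_end=12.0
    )


@pytest.fixture
def species_sensors():
    """Noiseless species sensors on a 50-point grid over 24 h."""
    return [
        SensorSpec(quantity=q, sampling_period=24.0 / 50) for q in ("c_SL", "c_NL", "c_AL")
    ]


def random_scenario(rng):
    """Draw a random but well-posed fed-batch scenario for property tests."""
    initial = VesselState(
        t=0.0,
        V_L=float(rng.uniform(0.5, 2.0)),
        c_SL=float(rng.uniform(0.0, 2.0)),
        c_NL=float(rng.uniform(0.0, 1.0)),
        c_AL=float(rng.uniform(0.0, 1.0)),
        c_DL=float(rng.uniform(0.0, 2.0)),
    )
    res = ReservoirSpec(
        c_SR=float(rng.uniform(10.0, 80.0)),
        c_DR=float(rng.uniform(0.0, 8.0)),
        V_R=float(rng.uniform(0.02, 0.3)),
    )
    params = KineticParameters(
        mode="constant",
        k_r=float(rng.uniform(0.2, 3.0)),
        k_a=float(rng.uniform(0.0, 3.0)),
        n_agg=int(rng.integers(1, 3)),
    )
    F = float(rng.uniform(0.005, 0.1))
    return initial, res, params, FeedPolicy.constant(F)
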
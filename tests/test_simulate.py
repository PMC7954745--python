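import numpy as np
import pytest

from refoldctl import (
    FeedPolicy,
    KineticParameters,
    ReservoirSpec,
    VesselState,
    analytic_batch_solution,
    simulate,
)
from conftest import random_scenario


def batch(c0, k_r, k_a, t_end, n_agg=2, **kw):
    init = VesselState(t=0.0, V_L=1.0, c_SL=c0)
    res = ReservoirSpec(c_SR=0.0, c_DR=0.0, V_R=0.0)
    p = KineticParameters(mode="constant", k_r=k_r, k_a=k_a, n_agg=n_agg)
    return simulate(init, res, FeedPolicy(), p, t_end, **kw)


class TestAnalyticBatchSolution:
    def test_initial_condition(self):
        cS, cN, cA = analytic_batch_solution(1.5, 1.0, 1.0, 0.0)
        assert (cS, cN, cA) == pytest.approx((1.5, 0.0, 0.0), abs=1e-14)

    def test_aggregation_free_exponential(self):
        t = np.linspace(0, 5, 50)
        cS, cN, _ = analytic_batch_solution(2.0, 0.7, 0.0, t)
        assert cS == pytest.approx(2.0 * np.exp(-0.7 * t), rel=1e-12)
        assert cN == pytest.approx(2.0 * (1 - np.exp(-0.7 * t)), rel=1e-12)

    def test_asymptotic_yield_ln2(self):
        # c0 = k_r = k_a = 1: native fraction tends to ln 2
        _, cN, _ = analytic_batch_solution(1.0, 1.0, 1.0, 200.0)
        assert cN == pytest.approx(np.log(2.0), rel=1e-9)

    def test_mass_conserved_exactly(self):
        t = np.linspace(0, 10, 101)
        cS, cN, cA = analytic_batch_solution(3.0, 1.2, 0.4, t)
        assert cS + cN + cA == pytest.approx(np.full_like(t, 3.0), rel=1e-12)

    def test_unsupported_order_rejected(self):
        with pytest.raises(ValueError, match="n_agg=2"):
            analytic_batch_solution(1.0, 1.0, 1.0, 1.0, n_agg=3)


class TestBatchSimulation:
    def test_aggregation_free_limit(self):
        traj = batch(1.0, 1.0, 0.0, 15.0)
        expected = 1.0 * (1 - np.exp(-traj.t))
        assert np.max(np.abs(traj.c_NL - expected)) < 1e-7
        assert traj.c_NL[-1] / traj.c_PL[-1] == pytest.approx(1.0, abs=1e-6)

    def test_matches_closed_form_over_random_parameters(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            c0 = rng.uniform(0.2, 5.0)
            k_r = rng.uniform(0.2, 3.0)
            k_a = rng.uniform(0.0, 3.0)
            traj = batch(c0, k_r, k_a, 8.0)
            cS, cN, cA = analytic_batch_solution(c0, k_r, k_a, traj.t)
            for sim, ana in ((traj.c_SL, cS), (traj.c_NL, cN), (traj.c_AL, cA)):
                # relative to the pointwise magnitude, floored at 0.1% of the
                # trajectory scale so integrator roundoff on near-zero values
                # is judged on an absolute basis
                rel = np.abs(sim - ana) / np.maximum(np.abs(ana), 1e-3 * c0)
                assert np.max(rel) < 1e-6

    def test_batch_conservation(self):
        traj = batch(2.0, 1.0, 0.5, 10.0)
        total = traj.c_SL + traj.c_NL + traj.c_AL
        assert np.max(np.abs(total - 2.0)) / 2.0 < 1e-8


class TestFedBatchSimulation:
    def test_depletion_time_and_phase_semantics(self, empty_vessel, constant_params):
        res = ReservoirSpec(c_SR=40.0, c_DR=6.0, V_R=0.5)
        traj = simulate(empty_vessel, res, FeedPolicy.constant(0.1), constant_params, 10.0)
        assert traj.t_dep == pytest.approx(5.0, abs=1e-6)
        after = traj.t >= traj.t_dep
        assert np.all(traj.phase[after] == "batch")
        assert np.all(traj.phase[~after] == "fed_batch")
        # volume frozen and feed terms gone after depletion
        assert np.max(np.abs(traj.V_L[after] - traj.V_L[after][0])) < 1e-9

    def test_mass_and_denaturant_balances_randomized(self):
        rng = np.random.default_rng(77)
        for _ in range(8):
            initial, res, params, feed = random_scenario(rng)
            traj = simulate(initial, res, feed, params, 6.0)
            mass = traj.V_L * (traj.c_SL + traj.c_NL + traj.c_AL)
            expect = initial.protein_mass + res.c_SR * traj.V_fed
            scale = max(np.max(np.abs(expect)), 1e-6)
            assert np.max(np.abs(mass - expect)) / scale < 1e-6
            den = traj.V_L * traj.c_DL
            expect_d = initial.V_L * initial.c_DL + res.c_DR * traj.V_fed
            scale_d = max(np.max(np.abs(expect_d)), 1e-6)
            assert np.max(np.abs(den - expect_d)) / scale_d < 1e-6

    def test_total_protein_equals_species_sum(self, fedbatch_traj):
        assert np.max(np.abs(fedbatch_traj.c_PL - (fedbatch_traj.c_SL + fedbatch_traj.c_NL + fedbatch_traj.c_AL))) < 1e-6

    def test_phase_switch_continuity(self, empty_vessel, reservoir, constant_params):
        traj = simulate(empty_vessel, reservoir, FeedPolicy.constant(0.02),
                        constant_params, 12.0)
        t_dep = traj.t_dep
        eps = 1e-7
        lo = simulate(empty_vessel, reservoir, FeedPolicy.constant(0.02), constant_params,
                      12.0, output_grid=np.array([0.0, t_dep - eps]))
        hi = simulate(empty_vessel, reservoir, FeedPolicy.constant(0.02), constant_params,
                      12.0, output_grid=np.array([0.0, t_dep + eps]))
        for attr in ("V_L", "c_DL", "c_SL", "c_NL", "c_AL"):
            jump = abs(getattr(lo, attr)[-1] - getattr(hi, attr)[-1])
            assert jump < 1e-6  # continuous across the located event

    def test_grid_invariance(self, empty_vessel, reservoir, constant_params):
        t_common = np.linspace(0.0, 12.0, 25)
        a = simulate(empty_vessel, reservoir, FeedPolicy.constant(0.02), constant_params,
                     12.0, output_grid=0.5)
        b = simulate(empty_vessel, reservoir, FeedPolicy.constant(0.02), constant_params,
                     12.0, output_grid=0.25)
        for attr in ("c_SL", "c_NL", "c_AL", "c_DL", "V_L"):
            ya = np.interp(t_common, a.t, getattr(a, attr))
            yb = np.interp(t_common, b.t, getattr(b, attr))
            assert np.max(np.abs(ya - yb)) < 1e-5

    def test_non_negativity(self, fedbatch_traj):
        for attr in ("c_SL", "c_NL", "c_AL", "c_DL", "V_L"):
            assert np.min(getattr(fedbatch_traj, attr)) >= 0.0

    def test_monotone_denaturant_dilution(self, constant_params):
        # feeding low-denaturant solution into a high-denaturant vessel
        init = VesselState(V_L=1.0, c_DL=4.0, c_SL=1.0)
        res = ReservoirSpec(c_SR=20.0, c_DR=0.5, V_R=0.2)
        traj = simulate(init, res, FeedPolicy.constant(0.05), constant_params, 6.0)
        feeding = traj.t < traj.t_dep
        assert np.all(np.diff(traj.c_DL[feeding]) <= 1e-12)

    def test_infeasible_volume_config_rejected(self, empty_vessel, reservoir, constant_params):
        with pytest.raises(ValueError, match="exceeds vessel maximum"):
            simulate(empty_vessel, reservoir, FeedPolicy.constant(0.02), constant_params,
                     5.0, V_max=1.05)

    def test_t_end_must_exceed_start(self, empty_vessel, reservoir, constant_params):
        with pytest.raises(ValueError, match="t_end"):
            simulate(empty_vessel, reservoir, FeedPolicy(), constant_params, 0.0)

    def test_csv_round_trip_schema(self, fedbatch_traj, tmp_path):
        import pandas as pd

        path = tmp_path / "traj.csv"
        fedbatch_traj.to_csv(path)
        df = pd.read_csv(path)
        from refoldctl.simulate import TRAJECTORY_COLUMNS

        assert list(df.columns) == TRAJECTORY_COLUMNS
        assert df["t_h"].is_monotonic_increasing
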
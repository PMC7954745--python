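import numpy as np
import pytest

from refoldctl import (
    ExtendedKalmanFilter,
    FeedPolicy,
    ObserverConfig,
    RefoldingObserver,
    SensorSpec,
    UnscentedKalmanFilter,
    generate_measurements,
    simulate,
)


def scalar_kalman_reference(a, q, r, p0, zs):
    """Closed-form scalar Kalman recursion (the textbook oracle)."""
    p = p0
    x = 0.0
    gains, means = [], []
    for z in zs:
        x = a * x
        p = a * a * p + q
        k = p / (p + r)
        x = x + k * (z - x)
        p = (1 - k) * p
        gains.append(k)
        means.append(x)
    return np.array(gains), np.array(means)


@pytest.mark.parametrize("cls", [UnscentedKalmanFilter, ExtendedKalmanFilter])
def test_scalar_linear_gain_matches_closed_form(cls):
    a, q, r, p0 = 0.9, 0.05, 0.2, 1.0
    rng = np.random.default_rng(0)
    zs = rng.standard_normal(40)
    ref_gains, ref_means = scalar_kalman_reference(a, q, r, p0, zs)

    kf = cls(np.array([0.0]), np.array([[p0]]))
    gains, means = [], []
    for z in zs:
        kf.predict(lambda x, dt: a * x, 1.0, np.array([[q]]))
        kf.update(np.array([z]), lambda x: x, np.array([[r]]))
        gains.append(float(kf.last_innovation["gain"][0, 0]))
        means.append(float(kf.x[0]))
    assert np.max(np.abs(np.array(gains) - ref_gains)) < 1e-10
    assert np.max(np.abs(np.array(means) - ref_means)) < 1e-10


def test_innovation_consistency_on_matched_linear_system():
    # normalized innovation squared should sit inside the chi-square 95%
    # band in the vast majority of steps when filter noise matches truth
    a, q, r = 0.95, 0.02, 0.1
    rng = np.random.default_rng(12)
    x_true = 0.0
    kf = UnscentedKalmanFilter(np.array([0.0]), np.array([[1.0]]))
    inside = 0
    n = 300
    for _ in range(n):
        x_true = a * x_true + rng.normal(scale=np.sqrt(q))
        z = x_true + rng.normal(scale=np.sqrt(r))
        kf.predict(lambda x, dt: a * x, 1.0, np.array([[q]]))
        kf.update(np.array([z]), lambda x: x, np.array([[r]]))
        innov = kf.last_innovation["innovation"]
        S = kf.last_innovation["S"]
        nis = float(innov @ np.linalg.solve(S, innov))
        if nis <= 3.841:  # chi2(1) 95% quantile
            inside += 1
    assert inside / n >= 0.80


class TestRefoldingObserver:
    def make_setup(self, noise_rel=0.0, noise_abs=0.0, delay=0.0, filter_family="unscented_kalman",
                   process_noise=None):
        from refoldctl import KineticParameters, ReservoirSpec, VesselState

        vessel = VesselState(t=0.0, V_L=1.0)
        res = ReservoirSpec(c_SR=40.0, c_DR=6.0, V_R=0.1)
        params = KineticParameters(mode="constant", k_r=1.0, k_a=1.0, n_agg=2)
        feed = FeedPolicy.constant(0.02)
        traj = simulate(vessel, res, feed, params, 6.0, output_grid=0.005)
        sensors = [
            SensorSpec(quantity="c_NL", sampling_period=0.1, noise_sd_rel=noise_rel,
                       noise_sd_abs=noise_abs, feedback_delay=delay),
            SensorSpec(quantity="c_PL", sampling_period=0.1, noise_sd_rel=noise_rel,
                       noise_sd_abs=noise_abs),
        ]
        pn = process_noise if process_noise is not None else np.zeros(5)
        cfg = ObserverConfig(
            filter_family=filter_family,
            initial_mean=np.array([1.0, 0.0, 0.0, 0.0, 0.0]),
            initial_cov=np.diag([1e-8, 1e-8, 1e-8, 1e-8, 1e-8]),
            process_noise=pn,
        )
        return vessel, res, params, feed, traj, sensors, cfg

    def run_observer(self, traj, sensors, cfg, params, res, feed, seed, t_end=6.0, step=0.1):
        meas = generate_measurements(traj, sensors, seed)
        obs = RefoldingObserver(cfg, params, res, sensors)
        t = 0.0
        out = []
        while t < t_end - 1e-9:
            t_next = round(t + step, 10)
            win = meas.records[
                (meas.records["t_available_h"] > t + 1e-12)
                & (meas.records["t_available_h"] <= t_next + 1e-12)
            ]
            F = feed.rate_at(0.5 * (t + t_next))
            if F * t_next > res.V_R:
                F = max(0.0, (res.V_R - F * t) / step)
            out.append(obs.step(t_next, F, win))
            t = t_next
        return out, meas

    @pytest.mark.parametrize("family", ["unscented_kalman", "extended_kalman"])
    def test_noiseless_exact_init_tracks_truth(self, family):
        vessel, res, params, feed, traj, sensors, cfg = self.make_setup(filter_family=family)
        ests, _ = self.run_observer(traj, sensors, cfg, params, res, feed, seed=0)
        for e in ests:
            truth = [np.interp(e.t, traj.t, g)
                     for g in (traj.V_L, traj.c_DL, traj.c_SL, traj.c_NL, traj.c_AL)]
            assert np.max(np.abs(e.mean - truth)) < 1e-4

    def test_prediction_only_follows_model_and_grows_covariance(self):
        vessel, res, params, feed, traj, sensors, cfg = self.make_setup(
            process_noise=np.full(5, 1e-6))
        obs = RefoldingObserver(cfg, params, res, sensors)
        traces = []
        for k in range(5):
            e = obs.step(0.2 * (k + 1), 0.02, None)
            traces.append(np.trace(e.cov))
            truth = [np.interp(e.t, traj.t, g)
                     for g in (traj.V_L, traj.c_DL, traj.c_SL, traj.c_NL, traj.c_AL)]
            assert np.max(np.abs(e.mean - truth)) < 1e-4
        assert np.all(np.diff(traces) > 0)

    def test_covariance_stays_numerically_psd(self):
        vessel, res, params, feed, traj, sensors, cfg = self.make_setup(
            noise_abs=0.02, process_noise=np.array([1e-8, 1e-6, 1e-4, 1e-4, 1e-4]))
        ests, _ = self.run_observer(traj, sensors, cfg, params, res, feed, seed=5)
        for e in ests:
            assert np.linalg.eigvalsh(e.cov).min() >= -1e-10

    def test_filtering_beats_raw_measurements(self):
        wins = 0
        n_rep = 5
        for seed in range(n_rep):
            vessel, res, params, feed, traj, sensors, cfg = self.make_setup(
                noise_abs=0.05, process_noise=np.array([1e-9, 1e-8, 1e-5, 1e-5, 1e-5]))
            ests, meas = self.run_observer(traj, sensors, cfg, params, res, feed, seed=seed)
            t_est = np.array([e.t for e in ests])
            truth_N = np.interp(t_est, traj.t, traj.c_NL)
            filt_N = np.array([e.mean[3] for e in ests])
            obs_N = meas.for_quantity("c_NL")
            raw_N = np.interp(t_est, obs_N["t_sample_h"], obs_N["value_g_L"])
            if np.sqrt(np.mean((filt_N - truth_N) ** 2)) < np.sqrt(np.mean((raw_N - truth_N) ** 2)):
                wins += 1
        assert wins == n_rep

    def test_unmeasured_aggregate_estimated_with_finite_error(self):
        # only c_NL and c_PL are sensed; c_AL must come from the model
        vessel, res, params, feed, traj, sensors, cfg = self.make_setup(
            noise_abs=0.02, process_noise=np.array([1e-9, 1e-8, 1e-5, 1e-5, 1e-5]))
        ests, _ = self.run_observer(traj, sensors, cfg, params, res, feed, seed=2)
        final = ests[-1]
        truth_A = np.interp(final.t, traj.t, traj.c_AL)
        assert truth_A > 0.05
        assert abs(final.mean[4] - truth_A) / truth_A < 0.25

    def test_delayed_records_are_refiltered(self):
        vessel, res, params, feed, traj, sensors, cfg = self.make_setup(
            noise_abs=0.02, delay=0.25,
            process_noise=np.array([1e-9, 1e-8, 1e-5, 1e-5, 1e-5]))
        ests, _ = self.run_observer(traj, sensors, cfg, params, res, feed, seed=3)
        final = ests[-1]
        truth = [np.interp(final.t, traj.t, g)
                 for g in (traj.V_L, traj.c_DL, traj.c_SL, traj.c_NL, traj.c_AL)]
        assert np.max(np.abs(final.mean - truth)) < 0.1

    def test_time_must_be_nondecreasing(self):
        vessel, res, params, feed, traj, sensors, cfg = self.make_setup()
        obs = RefoldingObserver(cfg, params, res, sensors)
        obs.step(0.5, 0.02, None)
        with pytest.raises(ValueError, match="non-decreasing"):
            obs.step(0.2, 0.02, None)


def test_observer_config_validation():
    with pytest.raises(ValueError, match="filter family"):
        ObserverConfig(filter_family="particle")
    with pytest.raises(ValueError):
        ObserverConfig(update_step=0.0)
    with pytest.raises(ValueError, match="symmetric PSD"):
        ObserverConfig(initial_mean=np.zeros(5), initial_cov=np.array([[1.0, 2.0], [0.0, 1.0]]))
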
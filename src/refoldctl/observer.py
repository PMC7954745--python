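"""Nonlinear Bayesian state estimation for the refolding vessel.

The observer reconstructs the full vessel state
(V_L, c_DL, c_SL, c_NL, c_AL) from sparse, noisy, possibly delayed
sensor records by recursive filtering against the fed-batch process
model — a "digital twin" of the vessel.  Two filter families are
provided: an unscented Kalman filter (default; no Jacobians of the
kinetics needed) and an extended Kalman filter with finite-difference
Jacobians.  Both are generic and are validated against the closed-form
scalar Kalman recursion.

Delayed measurements (availability time > sample time) are handled by
re-filtering: when a record becomes available the filter rewinds to its
stored estimate at the sample time, applies the update there, and
replays every later measurement and prediction up to the present.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import KineticParameters, ReservoirSpec, rate_constants
from .pat import SensorSpec

__all__ = [
    "ObserverConfig",
    "StateEstimate",
    "UnscentedKalmanFilter",
    "ExtendedKalmanFilter",
    "RefoldingObserver",
    "ObserverDivergence",
]

STATE_NAMES = ("V_L", "c_DL", "c_SL", "c_NL", "c_AL")


class ObserverDivergence(RuntimeError):
    pass


def _ensure_psd(P: np.ndarray, jitter: float = 1e-12) -> np.ndarray:
    """Symmetrise and, if needed, jitter a covariance back to numerical PSD."""
    P = 0.5 * (P + P.T)
    w = np.linalg.eigvalsh(P)
    if w.min() < -1e-10:
        warnings.warn("covariance lost positive semidefiniteness; re-conditioning")
        P = P + (abs(w.min()) + jitter) * np.eye(P.shape[0])
    elif w.min() < 0:
        P = P + jitter * np.eye(P.shape[0])
    return P


@dataclass
class StateEstimate:
    """Filtered state at one time: mean, covariance, last innovation."""

    t: float
    mean: np.ndarray
    cov: np.ndarray
    innovation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = _ensure_psd(np.asarray(self.cov, dtype=float))

    def std(self) -> np.ndarray:
        return np.sqrt(np.maximum(np.diag(self.cov), 0.0))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(STATE_NAMES, self.mean))


@dataclass
class ObserverConfig:
    """Observer tuning.

    ``process_noise`` is a per-state diagonal intensity (variance per
    hour); the discrete step covariance is ``diag(process_noise) * dt``.
    Measurement variances come from the sensor specs.  All defaults are
    this package's own tuning — there is no published observer tuning
    for refolding to inherit.
    """

    filter_family: str = "unscented_kalman"
    process_noise: np.ndarray = field(
        default_factory=lambda: np.array([1e-8, 1e-6, 1e-4, 1e-4, 1e-4])
    )
    initial_mean: np.ndarray | None = None
    initial_cov: np.ndarray | None = None
    update_step: float = 0.05
    alpha: float = 0.5
    beta: float = 2.0
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if self.filter_family not in ("unscented_kalman", "extended_kalman"):
            raise ValueError(f"unknown filter family {self.filter_family!r}")
        if self.update_step <= 0:
            raise ValueError("update_step must be > 0")
        self.process_noise = np.asarray(self.process_noise, dtype=float)
        if np.any(self.process_noise < 0):
            raise ValueError("process noise variances must be >= 0")
        if self.initial_cov is not None:
            P = np.asarray(self.initial_cov, dtype=float)
            if not np.allclose(P, P.T) or np.linalg.eigvalsh(P).min() < -1e-10:
                raise ValueError("initial covariance must be symmetric PSD")


class UnscentedKalmanFilter:
    """Generic UKF with Merwe scaled sigma points.

    ``f(x, dt)`` propagates a state over ``dt``; ``h(x)`` maps a state to
    the measurement space.  For linear systems the sigma-point transform
    is exact, so the filter reproduces the classical Kalman recursion.
    """

    def __init__(self, x0, P0, alpha=0.5, beta=2.0, kappa=0.0):
        self.x = np.atleast_1d(np.asarray(x0, dtype=float))
        self.P = _ensure_psd(np.atleast_2d(np.asarray(P0, dtype=float)))
        n = self.x.size
        self._lambda = alpha**2 * (n + kappa) - n
        c = n + self._lambda
        self.Wm = np.full(2 * n + 1, 1.0 / (2 * c))
        self.Wc = self.Wm.copy()
        self.Wm[0] = self._lambda / c
        self.Wc[0] = self._lambda / c + (1 - alpha**2 + beta)
        self.last_innovation: dict = {}

    def _sigma_points(self) -> np.ndarray:
        n = self.x.size
        try:
            S = np.linalg.cholesky((n + self._lambda) * self.P)
        except np.linalg.LinAlgError:
            S = np.linalg.cholesky((n + self._lambda) * _ensure_psd(self.P, 1e-9))
        pts = np.empty((2 * n + 1, n))
        pts[0] = self.x
        for i in range(n):
            pts[1 + i] = self.x + S[:, i]
            pts[1 + n + i] = self.x - S[:, i]
        return pts

    def predict(self, f, dt: float, Q: np.ndarray) -> None:
        pts = self._sigma_points()
        prop = np.array([np.atleast_1d(f(p, dt)) for p in pts])
        self.x = self.Wm @ prop
        d = prop - self.x
        self.P = _ensure_psd(d.T @ (self.Wc[:, None] * d) + np.atleast_2d(Q))

    def update(self, z, h, R: np.ndarray) -> None:
        z = np.atleast_1d(np.asarray(z, dtype=float))
        pts = self._sigma_points()
        Z = np.array([np.atleast_1d(h(p)) for p in pts])
        z_pred = self.Wm @ Z
        dz = Z - z_pred
        dx = pts - self.x
        S = dz.T @ (self.Wc[:, None] * dz) + np.atleast_2d(R)
        C = dx.T @ (self.Wc[:, None] * dz)
        K = np.linalg.solve(S.T, C.T).T
        innov = z - z_pred
        self.x = self.x + K @ innov
        self.P = _ensure_psd(self.P - K @ S @ K.T)
        self.last_innovation = {"z": z, "z_pred": z_pred, "innovation": innov, "S": S, "gain": K}


class ExtendedKalmanFilter:
    """EKF with central finite-difference Jacobians of ``f`` and ``h``."""

    def __init__(self, x0, P0, fd_eps: float = 1e-6):
        self.x = np.atleast_1d(np.asarray(x0, dtype=float))
        self.P = _ensure_psd(np.atleast_2d(np.asarray(P0, dtype=float)))
        self.fd_eps = fd_eps
        self.last_innovation: dict = {}

    def _jac(self, fn, x, out_dim):
        n = x.size
        J = np.empty((out_dim, n))
        for i in range(n):
            e = max(self.fd_eps * max(abs(x[i]), 1.0), 1e-12)
            xp, xm = x.copy(), x.copy()
            xp[i] += e
            xm[i] -= e
            J[:, i] = (np.atleast_1d(fn(xp)) - np.atleast_1d(fn(xm))) / (2 * e)
        return J

    def predict(self, f, dt: float, Q: np.ndarray) -> None:
        F = self._jac(lambda x: f(x, dt), self.x, self.x.size)
        self.x = np.atleast_1d(f(self.x, dt))
        self.P = _ensure_psd(F @ self.P @ F.T + np.atleast_2d(Q))

    def update(self, z, h, R: np.ndarray) -> None:
        z = np.atleast_1d(np.asarray(z, dtype=float))
        z_pred = np.atleast_1d(h(self.x))
        H = self._jac(h, self.x, z_pred.size)
        S = H @ self.P @ H.T + np.atleast_2d(R)
        K = np.linalg.solve(S.T, (self.P @ H.T).T).T
        innov = z - z_pred
        self.x = self.x + K @ innov
        I_KH = np.eye(self.x.size) - K @ H
        self.P = _ensure_psd(I_KH @ self.P @ I_KH.T + K @ np.atleast_2d(R) @ K.T)
        self.last_innovation = {"z": z, "z_pred": z_pred, "innovation": innov, "S": S, "gain": K}


def _quantity_fn(quantity: str):
    """Measurement map for one observed quantity on the 5-dim state."""
    if quantity == "c_PL":
        return lambda x: np.array([x[2] + x[3] + x[4]])
    idx = STATE_NAMES.index(quantity)
    return lambda x, i=idx: np.array([x[i]])


class RefoldingObserver:
    """Recursive state observer for the fed-batch refolding vessel.

    Wraps a UKF or EKF around the fed-batch kinetic model.  ``step``
    advances the estimate to a new time under the feed actually applied
    and assimilates every measurement record whose availability time has
    passed; records sampled in the past trigger a rewind-and-replay over
    the delay window.  Posterior means are clipped at zero concentration
    (covariance untouched).
    """

    def __init__(
        self,
        cfg: ObserverConfig,
        params: KineticParameters,
        res: ReservoirSpec,
        sensors,
        t0: float = 0.0,
    ):
        if cfg.initial_mean is None or cfg.initial_cov is None:
            raise ValueError("observer config must provide an initial mean and covariance")
        self.cfg = cfg
        self.params = params
        self.res = res
        self.sensor_by_quantity: dict[str, SensorSpec] = {s.quantity: s for s in sensors}
        cls = UnscentedKalmanFilter if cfg.filter_family == "unscented_kalman" else ExtendedKalmanFilter
        if cls is UnscentedKalmanFilter:
            self.kf = cls(cfg.initial_mean, cfg.initial_cov, cfg.alpha, cfg.beta, cfg.kappa)
        else:
            self.kf = cls(cfg.initial_mean, cfg.initial_cov)
        self.t = float(t0)
        self._feed_segments: list[tuple[float, float, float]] = []  # applied feed history
        self._v_fed0 = 0.0
        # snapshots for delayed-measurement re-filtering: sorted by time
        self._snap_t: list[float] = [self.t]
        self._snap: list[tuple[np.ndarray, np.ndarray]] = [(self.kf.x.copy(), self.kf.P.copy())]
        self._applied: list[tuple[float, str, float]] = []  # (t_sample, quantity, value)
        self._divergence_count = 0

    # -- model propagation -------------------------------------------------
    def _feed_at(self, t: float) -> float:
        for a, b, f in self._feed_segments:
            if a <= t < b:
                return f
        return 0.0

    def _v_fed_at(self, t: float) -> float:
        v = 0.0
        for a, b, f in self._feed_segments:
            v += f * max(0.0, min(t, b) - a)
        return min(v, self.res.V_R)

    def _propagate(self, x: np.ndarray, t0: float, t1: float) -> np.ndarray:
        if t1 <= t0 + 1e-13:
            return x.copy()

        def rhs(t, y):
            F = self._feed_at(t)
            if self._v_fed_at(t) >= self.res.V_R - 1e-12:
                F = 0.0
            V = max(y[0], 1e-9)
            k_r, k_a = rate_constants(self.params, max(y[1], 0.0))
            s = max(y[2], 0.0)
            rf, ra = k_r * s, k_a * s**self.params.n_agg
            D = F / V
            return [
                F,
                D * (self.res.c_DR - y[1]),
                -(rf + ra) + D * (self.res.c_SR - y[2]),
                rf - D * y[3],
                ra - D * y[4],
            ]

        sol = solve_ivp(rhs, (t0, t1), x, method="RK45", rtol=1e-7, atol=1e-9)
        if not sol.success:
            raise ObserverDivergence(f"prediction integration failed: {sol.message}")
        return sol.y[:, -1]

    def _predict_to(self, t_new: float) -> None:
        t0 = self.t
        if t_new <= t0 + 1e-13:
            return
        dt = t_new - t0
        Q = np.diag(self.cfg.process_noise) * dt
        self.kf.predict(lambda x, _dt, a=t0, b=t_new: self._propagate(x, a, b), dt, Q)
        self.t = t_new

    def _apply_measurement(self, quantity: str, value: float) -> None:
        spec = self.sensor_by_quantity.get(quantity)
        sd = spec.sd_at(value) if spec is not None else 1e-3
        # floor at the numerical accuracy of the prediction pipeline so a
        # nominally noise-free sensor cannot produce near-singular gains
        R = np.array([[max(sd, 1e-6) ** 2]])
        try:
            self.kf.update(np.array([value]), _quantity_fn(quantity), R)
        except np.linalg.LinAlgError as exc:
            self._divergence_count += 1
            if self._divergence_count > 3:
                raise ObserverDivergence("repeated covariance failure in update") from exc
            warnings.warn(f"measurement update failed ({exc}); skipping record")
        # physical floor on the posterior mean only
        self.kf.x = np.maximum(self.kf.x, [1e-9, 0.0, 0.0, 0.0, 0.0])

    def _snapshot(self) -> None:
        i = bisect.bisect_right(self._snap_t, self.t)
        self._snap_t.insert(i, self.t)
        self._snap.insert(i, (self.kf.x.copy(), self.kf.P.copy()))

    # -- public API --------------------------------------------------------
    def step(self, t_new: float, applied_feed: float, new_records: pd.DataFrame | None = None) -> StateEstimate:
        """Advance to ``t_new`` under ``applied_feed`` [L/h] and assimilate records.

        ``new_records`` rows need columns t_sample_h, quantity, value_g_L,
        censored (censored rows are ignored); every row must satisfy
        availability time <= t_new.  With no records the step is pure
        prediction and the covariance grows by the process noise.
        """
        if t_new < self.t - 1e-12:
            raise ValueError("observer time must be non-decreasing")
        if applied_feed < 0:
            raise ValueError("applied feed must be >= 0")
        self._feed_segments.append((self.t, t_new, float(applied_feed)))

        pending: list[tuple[float, str, float]] = []
        if new_records is not None and len(new_records):
            for _, r in new_records.iterrows():
                if bool(r.get("censored", False)):
                    continue
                pending.append((float(r["t_sample_h"]), str(r["quantity"]), float(r["value_g_L"])))

        rewind_to = min((p[0] for p in pending), default=np.inf)
        if pending and rewind_to < self.t - 1e-12:
            # rewind to the stored estimate at/before the earliest sample time
            i = bisect.bisect_right(self._snap_t, rewind_to + 1e-12) - 1
            i = max(i, 0)
            x, P = self._snap[i]
            self.kf.x, self.kf.P = x.copy(), P.copy()
            self.t = self._snap_t[i]
            replay = [m for m in self._applied if m[0] > self.t + 1e-12]
            del self._snap_t[i + 1 :]
            del self._snap[i + 1 :]
            self._applied = [m for m in self._applied if m[0] <= self.t + 1e-12]
            pending = sorted(pending + replay)
        else:
            pending.sort()

        for t_s, q, v in pending:
            self._predict_to(min(max(t_s, self.t), t_new))
            self._apply_measurement(q, v)
            self._applied.append((t_s, q, v))
            self._snapshot()
        self._predict_to(t_new)
        self._snapshot()
        # bound history to the delay horizon nobody will rewind past
        max_delay = max((s.feedback_delay for s in self.sensor_by_quantity.values()), default=0.0)
        cut = self.t - max_delay - 1e-9
        while len(self._snap_t) > 2 and self._snap_t[1] < cut:
            del self._snap_t[0], self._snap[0]
        self._applied = [m for m in self._applied if m[0] >= cut]

        return StateEstimate(
            t=self.t, mean=self.kf.x.copy(), cov=self.kf.P.copy(),
            innovation=dict(self.kf.last_innovation),
        )


def estimates_to_frame(estimates: list[StateEstimate]) -> pd.DataFrame:
    """Estimated-trajectory table mirroring the trajectory schema plus stds."""
    rows = []
    for e in estimates:
        d = {"t_h": e.t, "V_L_L": e.mean[0], "c_DL_mol_L": e.mean[1],
             "c_SL_g_L": e.mean[2], "c_NL_g_L": e.mean[3], "c_AL_g_L": e.mean[4]}
        s = e.std()
        for name, val in zip(("sd_V_L", "sd_c_DL", "sd_c_SL", "sd_c_NL", "sd_c_AL"), s):
            d[name] = val
        rows.append(d)
    return pd.DataFrame(rows)
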
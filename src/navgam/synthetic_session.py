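"""Synthetic firefly-task sessions with known encoding ground truth.

Generates complete sessions — steering behavior, gaze, LFP band phases and
spiking — so that every stage of the pipeline can be validated against a
known generative model without any recorded data:

* behavior: targets uniform over 1-4 m and +/-40 deg; joystick-like
  trajectories from a proportional steering controller honoring the 2 m/s and
  90 deg/s caps; endpoints follow a multiplicative-gain model (default gains
  0.89 radial / 0.79 angular, i.e. mild undershooting) plus noise; inter-trial
  intervals truncated-exponential (0.2-2.0 s, mean 0.5 s); reward within 0.6 m
  of the true target; configurable fractions of near-origin-stop and no-stop
  trials.
* gaze: the perfect-fixation prediction mixed with slow drift noise scaled so
  the expected target-tracking index matches ``tracking_quality``.
* spiking: per-bin Poisson draws from the same log-additive rate model the
  encoding analysis assumes — spline-like tuning to continuous covariates,
  periodic phase tuning to LFP bands, causal event kernels, and sequentially
  applied spike-history and partner-coupling kernels — with the complete
  ground truth returned alongside the session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior as _behavior
from .core_data import (
    AREAS,
    BinnedSession,
    LFP_BANDS,
    TrialRecord,
    bin_session,
    default_unit_meta,
    wrap_angle,
)

#: center frequency (Hz) used for the band-phase oscillators
BAND_CENTER_HZ = {"theta": 6.0, "alpha": 10.0, "beta": 21.0}


@dataclass
class SessionConfig:
    """Study conditions of the synthetic firefly task."""

    n_trials: int = 300
    dt: float = 0.006            # model bin width, s
    dt_acq: float = 0.002        # behavioural/LFP sampling, s (500 Hz)
    gain_radial: float = 0.89
    gain_angular: float = 0.79
    endpoint_noise_r: float = 30.0      # cm
    endpoint_noise_theta: float = 4.0   # deg
    target_r_range: tuple = (100.0, 400.0)
    target_theta_range: tuple = (-40.0, 40.0)
    v_max: float = 200.0         # cm/s
    w_max: float = 90.0          # deg/s
    accel_max: float = 400.0     # cm/s^2
    target_visible_s: float = 0.3
    reward_radius: float = 60.0  # cm
    max_duration: float = 7.0    # s
    iti_min: float = 0.2
    iti_max: float = 2.0
    iti_mean: float = 0.5
    frac_near_origin: float = 0.05
    frac_no_stop: float = 0.13
    tracking_quality: float = 0.73
    n_units: int = 30
    area_counts: dict = field(default_factory=lambda: {"MSTd": 10, "7a": 10, "dlPFC": 10})
    baseline_rate_hz: tuple = (5.0, 20.0)   # per-unit uniform range
    max_rate_hz: float = 200.0              # generation safety cap


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def _truncated_exp(rng, lo, hi, mean):
    scale = mean - lo
    for _ in range(100):
        v = lo + rng.exponential(scale)
        if v <= hi:
            return v
    return hi


def _steer_trial(rng, cfg: SessionConfig, goal_xy, no_stop: bool):
    """Proportional steering toward a goal; returns trajectory arrays."""
    dt = cfg.dt_acq
    n_max = int(cfg.max_duration / dt)
    x = y = 0.0
    heading = 0.0  # deg from +y, rightward positive
    v = w = 0.0
    t_move = 0.2 + 0.2 * rng.random()  # movement-start delay
    xs, ys, hs, vs, ws = [], [], [], [], []
    stopped_at = None
    for i in range(n_max):
        t = i * dt
        xs.append(x); ys.append(y); hs.append(heading); vs.append(v); ws.append(w)
        dx, dy = goal_xy[0] - x, goal_xy[1] - y
        d = np.hypot(dx, dy)
        if t < t_move:
            v_des = w_des = 0.0
        elif no_stop:
            v_des = 0.7 * cfg.v_max
            w_des = 20.0 * np.sin(0.5 * t + rng.random())  # wandering
        elif d < 3.0 or stopped_at is not None:
            v_des = w_des = 0.0
            if stopped_at is None and abs(v) < 1.0 and abs(w) < 1.0:
                stopped_at = t
            if stopped_at is not None and t - stopped_at > 0.6:
                xs_arr = np.array(xs)
                break
        else:
            bearing = np.rad2deg(np.arctan2(dx, dy))
            ang_err = (bearing - heading + 180.0) % 360.0 - 180.0
            w_des = np.clip(4.0 * ang_err, -cfg.w_max, cfg.w_max)
            v_des = np.clip(2.2 * d + 10.0, 0.0, cfg.v_max)
            # slow down while turning hard
            v_des *= np.clip(1.0 - abs(ang_err) / 120.0, 0.2, 1.0)
        dv = np.clip(v_des - v, -cfg.accel_max * dt, cfg.accel_max * dt)
        v = float(np.clip(v + dv, 0.0, cfg.v_max))
        w = float(np.clip(w + np.clip(w_des - w, -720.0 * dt, 720.0 * dt), -cfg.w_max, cfg.w_max))
        heading += w * dt
        rad = np.deg2rad(heading)
        x += v * np.sin(rad) * dt
        y += v * np.cos(rad) * dt
    tarr = np.arange(len(xs)) * dt
    traj = pd.DataFrame(
        {"t": tarr, "x": xs, "y": ys, "heading": hs, "lin_vel": vs, "ang_vel": ws}
    )
    return traj, stopped_at, t_move


def generate_behavior(config: SessionConfig | None = None, seed: int = 0) -> list[TrialRecord]:
    """Simulate the steering behavior of one session."""
    cfg = config or SessionConfig()
    if cfg.gain_radial * cfg.target_r_range[1] / cfg.max_duration > cfg.v_max:
        raise ValueError("infeasible gains: goals unreachable within speed caps")
    rng = np.random.default_rng(seed)
    trials = []
    t_clock = _truncated_exp(rng, cfg.iti_min, cfg.iti_max, cfg.iti_mean)
    for k in range(cfg.n_trials):
        r = rng.uniform(*cfg.target_r_range)
        th = rng.uniform(*cfg.target_theta_range)
        u = rng.random()
        no_stop = u < cfg.frac_no_stop
        near_origin = (not no_stop) and (u < cfg.frac_no_stop + cfg.frac_near_origin)
        if near_origin:
            goal_r = rng.uniform(10.0, 45.0)
            goal_th = th
        else:
            goal_r = np.clip(cfg.gain_radial * r + rng.normal(0, cfg.endpoint_noise_r), 20.0, 520.0)
            goal_th = cfg.gain_angular * th + rng.normal(0, cfg.endpoint_noise_theta)
        grad = np.deg2rad(goal_th)
        goal_xy = (goal_r * np.sin(grad), goal_r * np.cos(grad))
        traj, stopped_at, t_move = _steer_trial(rng, cfg, goal_xy, no_stop)
        t_on = 0.05
        tr = TrialRecord(
            trial_id=k,
            t_start=t_clock,
            target_r=r,
            target_theta=th,
            t_target_on=t_on,
            t_target_off=t_on + cfg.target_visible_s,
            trajectory=traj,
        )
        moving = np.abs(traj["lin_vel"].to_numpy()) > 1.0
        if moving.any():
            tr.t_move_on = float(traj["t"].to_numpy()[np.argmax(moving)])
        if stopped_at is not None:
            tr.t_move_off = stopped_at
            i = int(np.searchsorted(traj["t"].to_numpy(), stopped_at))
            ex, ey = float(traj["x"].iloc[i]), float(traj["y"].iloc[i])
            tr.endpoint_r = float(np.hypot(ex, ey))
            tr.endpoint_theta = float(np.rad2deg(np.arctan2(ex, ey)))
            tx, ty = tr.target_xy
            if np.hypot(ex - tx, ey - ty) <= cfg.reward_radius:
                tr.rewarded = True
                tr.t_reward = stopped_at + _truncated_exp(rng, 0.1, 0.6, 0.25)
        trials.append(tr)
        t_clock += tr.duration + _truncated_exp(rng, cfg.iti_min, cfg.iti_max, cfg.iti_mean)
    return trials


def generate_gaze(
    trials: list[TrialRecord], tracking_quality: float, seed: int = 0
) -> list[TrialRecord]:
    """Attach gaze traces mixing the fixation prediction with drift noise.

    The slow (AR(1)) noise is scaled per trial and component so the expected
    tracking index equals ``tracking_quality``; at 1 gaze sits exactly on the
    prediction, at 0 it is unrelated drift with matched variance.
    """
    if not 0.0 <= tracking_quality <= 1.0:
        raise ValueError("tracking_quality must lie in [0, 1]")
    q = tracking_quality
    rng = np.random.default_rng(seed)
    rho = 0.995
    for tr in trials:
        traj = tr.trajectory
        pred = _behavior.predict_gaze(
            np.column_stack([traj["x"], traj["y"]]),
            traj["heading"].to_numpy(),
            tr.target_xy,
        )
        n = len(traj)
        gaze = {"t": traj["t"].to_numpy()}
        for col in ("left_h", "left_v", "right_h", "right_v"):
            p = pred[col].to_numpy()
            if np.isnan(p).any():  # target behind: hold last valid prediction
                ok = ~np.isnan(p)
                p = np.interp(np.arange(n), np.flatnonzero(ok), p[ok]) if ok.any() else np.zeros(n)
            var_p = max(p.var(), 1e-6)
            if q >= 1.0:
                gaze[col] = p
                continue
            e = rng.standard_normal(n)
            ar = np.empty(n)
            ar[0] = e[0]
            for i in range(1, n):
                ar[i] = rho * ar[i - 1] + e[i]
            ar -= ar.mean()
            sd_ar = ar.std() or 1.0
            if q <= 0.0:
                gaze[col] = p.mean() + ar / sd_ar * np.sqrt(var_p)
            else:
                var_n = var_p * (1.0 - q * q) / (q * q)
                gaze[col] = p + ar / sd_ar * np.sqrt(var_n)
        tr.gaze = pd.DataFrame(gaze)
    return trials


# ---------------------------------------------------------------------------
# ground truth for spiking
# ---------------------------------------------------------------------------

@dataclass
class UnitGroundTruth:
    """Generative parameters of one unit (log-rate contributions)."""

    unit_id: int
    area: str
    baseline_hz: float
    tunings: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    phase_tuning: dict[str, tuple[float, float]] = field(default_factory=dict)  # band -> (pref, depth)
    event_kernels: dict[str, np.ndarray] = field(default_factory=dict)  # name -> lag kernel
    history_kernel: np.ndarray | None = None
    coupling: dict[int, np.ndarray] = field(default_factory=dict)  # sender -> lag kernel

    def tuning_value(self, var: str, x: np.ndarray) -> np.ndarray:
        g, v = self.tunings[var]
        return np.interp(np.clip(x, g[0], g[-1]), g, v)

    @property
    def tuned_variables(self) -> set:
        out = set(self.tunings) | {f"lfp_{b}" for b in self.phase_tuning} | set(self.event_kernels)
        return out


@dataclass
class GroundTruth:
    units: list[UnitGroundTruth]
    gains: tuple
    tracking_quality: float

    def unit(self, uid: int) -> UnitGroundTruth:
        return self.units[uid]


#: probability that a unit of each area is tuned to each covariate family —
#: a qualitative MSTd eye-heavy / 7a sensorimotor+LFP-heavy / dlPFC
#: latent-heavy cohort used to exercise the population analyses
AREA_TUNING_PROFILES = {
    "MSTd": {"eye": 0.8, "velocity": 0.45, "latent_origin": 0.25, "latent_target": 0.45,
             "lfp": 0.3, "events": 0.4},
    "7a": {"eye": 0.3, "velocity": 0.85, "latent_origin": 0.55, "latent_target": 0.2,
           "lfp": 0.7, "events": 0.7},
    "dlPFC": {"eye": 0.6, "velocity": 0.3, "latent_origin": 0.5, "latent_target": 0.6,
              "lfp": 0.3, "events": 0.5},
}
_FAMILIES = {
    "eye": ("eye_hor", "eye_vert"),
    "velocity": ("lin_vel", "ang_vel", "lin_acc", "ang_acc"),
    "latent_origin": ("dist_origin", "angle_origin"),
    "latent_target": ("dist_target", "angle_target"),
    "events": ("target_on", "move_on", "move_off", "reward"),
}


def _random_tuning(rng, lo, hi, amp=None):
    """Random smooth tuning shape tabulated on a grid (log-rate units)."""
    grid = np.linspace(lo, hi, 40)
    amp = amp if amp is not None else rng.uniform(0.35, 0.8)
    kind = rng.choice(["bump", "sigmoid", "ramp"])
    c = rng.uniform(lo + 0.15 * (hi - lo), hi - 0.15 * (hi - lo))
    w = (hi - lo) * rng.uniform(0.12, 0.3)
    if kind == "bump":
        v = amp * np.exp(-0.5 * ((grid - c) / w) ** 2)
    elif kind == "sigmoid":
        v = amp / (1.0 + np.exp(-(grid - c) / w))
    else:
        v = amp * (grid - lo) / (hi - lo)
    if rng.random() < 0.4:
        v = -v
    return grid, v - v.mean()


def make_ground_truth(
    cfg: SessionConfig, session: BinnedSession, seed: int = 0
) -> GroundTruth:
    """Draw per-unit tuning/coupling ground truth for a binned session."""
    rng = np.random.default_rng(seed)
    meta = session.unit_meta
    units = []
    for uid in range(session.n_units):
        area = meta["area"].iloc[uid]
        prof = AREA_TUNING_PROFILES.get(area, AREA_TUNING_PROFILES["MSTd"])
        gt = UnitGroundTruth(
            unit_id=uid,
            area=area,
            baseline_hz=rng.uniform(*cfg.baseline_rate_hz),
        )
        in_trial = session.trial_index >= 0
        for fam, prob in prof.items():
            if fam == "lfp":
                for band in session.lfp_phase:
                    if rng.random() < prob:
                        gt.phase_tuning[band] = (
                            rng.uniform(-np.pi, np.pi),
                            rng.uniform(0.2, 0.5),
                        )
                continue
            if fam == "events":
                L = int(round(0.6 / session.dt))
                lags = (np.arange(L) + 1) * session.dt
                for name in _FAMILIES["events"]:
                    if rng.random() < prob:
                        peak = rng.uniform(0.05, 0.3)
                        amp = rng.uniform(0.4, 0.9) * rng.choice([-1.0, 1.0])
                        gt.event_kernels[name] = amp * np.exp(
                            -0.5 * ((lags - peak) / 0.07) ** 2
                        )
                continue
            for name in _FAMILIES[fam]:
                if rng.random() < prob:
                    x = session.continuous[name].to_numpy()[in_trial]
                    lo, hi = np.quantile(x, [0.02, 0.98])
                    if hi - lo < 1e-9:
                        continue
                    gt.tunings[name] = _random_tuning(rng, lo, hi)
        # refractory-ish spike history (36 ms)
        Lh = int(round(0.036 / session.dt))
        gt.history_kernel = np.concatenate(([-1.5], -0.3 * np.exp(-np.arange(Lh - 1))))
        units.append(gt)
    # couplings: distance-dependent within areas, MSTd<->dlPFC biased across
    ex = meta[["elec_x", "elec_y"]].to_numpy()
    Lw = int(round(0.036 / cfg.dt))
    La = int(round(0.6 / cfg.dt))
    for r, gt in enumerate(units):
        for s in range(session.n_units):
            if s == r:
                continue
            a_s, a_r = units[s].area, gt.area
            if a_s == a_r:
                d = np.hypot(*(ex[s] - ex[r]))
                p = 0.3 * np.exp(-d / 400.0)
                if rng.random() < p:
                    amp = rng.uniform(0.3, 0.7) * rng.choice([-1.0, 1.0])
                    gt.coupling[s] = amp * np.exp(-np.arange(Lw) / 2.0)
            else:
                pair = {a_s, a_r}
                p = 0.10 if pair == {"MSTd", "dlPFC"} else 0.03
                if rng.random() < p:
                    lags = (np.arange(La) + 1) * cfg.dt
                    amp = rng.uniform(0.25, 0.5) * rng.choice([-1.0, 1.0])
                    gt.coupling[s] = amp * np.exp(-lags / 0.2)
    return GroundTruth(
        units=units,
        gains=(cfg.gain_radial, cfg.gain_angular),
        tracking_quality=cfg.tracking_quality,
    )


def generate_lfp_phases(
    duration: float, n_channels: int, dt_acq: float, seed: int = 0,
    bands: tuple = LFP_BANDS, diffusion: float = 2.0,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Band-limited oscillator phases advancing at the band center frequency
    with phase diffusion; returns ({band: (channels, n)}, sample times)."""
    rng = np.random.default_rng(seed)
    n = int(np.ceil(duration / dt_acq)) + 1
    t = np.arange(n) * dt_acq
    out = {}
    for band in bands:
        fc = BAND_CENTER_HZ[band]
        steps = 2 * np.pi * fc * dt_acq + diffusion * np.sqrt(dt_acq) * rng.standard_normal(
            (n_channels, n)
        )
        steps[:, 0] = rng.uniform(-np.pi, np.pi, n_channels)
        out[band] = wrap_angle(np.cumsum(steps, axis=1))
    return out, t


def generate_spikes(
    session: BinnedSession, ground_truth: GroundTruth, seed: int = 0
) -> np.ndarray:
    """Per-bin Poisson spike counts from the ground-truth rate model.

    The stimulus part (tunings, phase tuning, event kernels) is evaluated
    vectorially; spike-history and coupling contributions are applied
    sequentially in time so the generated process is causal and the fitted
    causal filters have a well-defined truth.
    """
    rng = np.random.default_rng(seed)
    U, T = session.n_units, session.n_bins
    dt = session.dt
    cap = np.log(1e3)  # absolute cap on log expected count (safety)
    eta0 = np.empty((U, T))
    any_dyn = False
    for gt in ground_truth.units:
        e = np.full(T, np.log(gt.baseline_hz * dt))
        for var, _ in gt.tunings.items():
            e += gt.tuning_value(var, session.continuous[var].to_numpy())
        for band, (pref, depth) in gt.phase_tuning.items():
            e += depth * np.cos(session.lfp_phase[band][gt.unit_id] - pref)
        for name, kern in gt.event_kernels.items():
            z = session.events[name].to_numpy().astype(float)
            full = np.concatenate(([0.0], kern))
            e += np.convolve(z, full)[:T]
        eta0[gt.unit_id] = e
        if gt.history_kernel is not None or gt.coupling:
            any_dyn = True
    max_mu = 1e3 * dt  # cap expected counts per bin at a 1 kHz-equivalent rate
    counts = np.zeros((U, T), dtype=np.int64)
    if np.any(eta0 > np.log(max_mu) + 5):
        bad = np.unique(np.where(eta0 > np.log(max_mu) + 5)[0])
        raise ValueError(f"rate overflow in spike generation for units {bad.tolist()}")
    if not any_dyn:
        return rng.poisson(np.minimum(np.exp(np.minimum(eta0, cap)), max_mu)).astype(np.int64)
    dyn = np.zeros((U, T + int(0.7 / dt) + 4))
    hist = {gt.unit_id: gt.history_kernel for gt in ground_truth.units}
    # sender -> [(receiver, kernel)] for causal scatter updates
    outgoing: dict[int, list] = {u: [] for u in range(U)}
    for gt in ground_truth.units:
        for s, k in gt.coupling.items():
            outgoing[s].append((gt.unit_id, k))
    for t in range(T):
        mu = np.minimum(np.exp(np.minimum(eta0[:, t] + dyn[:, t], cap)), max_mu)
        yt = rng.poisson(mu)
        counts[:, t] = yt
        for s in np.flatnonzero(yt):
            ys = yt[s]
            h = hist[s]
            if h is not None:
                dyn[s, t + 1 : t + 1 + len(h)] += ys * h
            for r, k in outgoing[s]:
                dyn[r, t + 1 : t + 1 + len(k)] += ys * k
    return counts


def spike_times_from_counts(counts: np.ndarray, dt: float, seed: int = 0) -> list[np.ndarray]:
    """Jitter per-bin counts into sorted spike times (for QC-style analyses)."""
    rng = np.random.default_rng(seed)
    out = []
    for u in range(counts.shape[0]):
        times = []
        nz = np.flatnonzero(counts[u])
        for b in nz:
            times.append(b * dt + dt * rng.random(counts[u, b]))
        st = np.sort(np.concatenate(times)) if times else np.array([])
        out.append(st)
    return out


# ---------------------------------------------------------------------------
# full session
# ---------------------------------------------------------------------------

def make_session(
    config: SessionConfig | None = None, seed: int = 0
) -> tuple[BinnedSession, list[TrialRecord], GroundTruth]:
    """Generate a complete synthetic session: behavior, gaze, LFP, spikes."""
    cfg = config or SessionConfig()
    trials = generate_behavior(cfg, seed=seed)
    trials = generate_gaze(trials, cfg.tracking_quality, seed=seed + 1)
    duration = max(tr.t_start + tr.duration for tr in trials) + 1.0
    n_units = sum(cfg.area_counts.values()) if cfg.area_counts else cfg.n_units
    phases, lfp_t = generate_lfp_phases(duration, n_units, cfg.dt_acq, seed=seed + 2)
    meta_rows = []
    uid = 0
    rng = np.random.default_rng(seed + 3)
    for area, cnt in cfg.area_counts.items():
        for j in range(cnt):
            meta_rows.append(
                {
                    "unit_id": uid,
                    "area": area,
                    "channel": uid,
                    "elec_x": float(400.0 * (j % 6) + rng.normal(0, 20)),
                    "elec_y": float(400.0 * (j // 6) + rng.normal(0, 20)),
                }
            )
            uid += 1
    unit_meta = pd.DataFrame(meta_rows)
    session = bin_session(
        trials,
        spikes=[np.array([]) for _ in range(n_units)],
        lfp=phases,
        lfp_t=lfp_t,
        dt=cfg.dt,
        unit_meta=unit_meta,
    )
    gt = make_ground_truth(cfg, session, seed=seed + 4)
    session.counts = generate_spikes(session, gt, seed=seed + 5)
    return session, trials, gt
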
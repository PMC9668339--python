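"""Session data model for closed-loop navigation recordings.

A recording session is represented at two levels:

* :class:`TrialRecord` — one trial of the firefly task: the target location in
  polar coordinates (distance ``r`` in cm, signed eccentricity ``theta`` in
  degrees, rightward positive), the behavioural endpoint, event times, and the
  trajectory / gaze time series sampled at the acquisition rate.
* :class:`BinnedSession` — the time-aligned container of per-unit spike counts,
  continuous covariates, binary event trains and LFP band phases, all resampled
  on a common bin axis (default 6 ms).

Conventions: distances in cm, angles in signed degrees (rightward positive),
phases in radians wrapped to (-pi, pi], times in seconds. At trial start the
observer sits at the origin heading along +y, so a target at (r, theta) lies at
Cartesian (r sin theta, r cos theta).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# Canonical covariate/event/band names. Ten continuous covariates, four task
# events and three LFP bands make up the 17 task inputs of the encoding model.
CONTINUOUS_VARS = (
    "lin_vel",
    "ang_vel",
    "lin_acc",
    "ang_acc",
    "dist_origin",
    "angle_origin",
    "dist_target",
    "angle_target",
    "eye_hor",
    "eye_vert",
)
EVENT_VARS = ("target_on", "move_on", "move_off", "reward")
LFP_BANDS = ("theta", "alpha", "beta")
#: (low, high) edges in Hz of the LFP bands entered as phase covariates.
BAND_EDGES = {"theta": (4.0, 8.0), "alpha": (8.0, 12.0), "beta": (12.0, 30.0)}
TASK_VARIABLES = CONTINUOUS_VARS + tuple(f"lfp_{b}" for b in LFP_BANDS) + EVENT_VARS

AREAS = ("MSTd", "7a", "dlPFC")


def wrap_angle(phi: np.ndarray) -> np.ndarray:
    """Wrap phases (radians) to (-pi, pi]."""
    out = np.asarray(phi, dtype=float)
    out = -((-out + np.pi) % (2.0 * np.pi) - np.pi)
    return out


@dataclass
class TrialRecord:
    """One firefly trial.

    ``trajectory`` is a DataFrame with columns ``t`` (s from trial start),
    ``x``, ``y`` (cm), ``heading`` (deg), ``lin_vel`` (cm/s), ``ang_vel``
    (deg/s). ``gaze`` has columns ``t``, ``left_h``, ``left_v``, ``right_h``,
    ``right_v`` (deg of visual angle). ``t_start`` is the absolute session time
    of trial start, used when concatenating trials onto the session bin axis.
    """

    trial_id: int
    target_r: float
    target_theta: float
    t_target_on: float
    t_target_off: float
    trajectory: pd.DataFrame
    gaze: pd.DataFrame | None = None
    t_move_on: float | None = None
    t_move_off: float | None = None
    t_reward: float | None = None
    endpoint_r: float | None = None
    endpoint_theta: float | None = None
    rewarded: bool = False
    t_start: float = 0.0

    @property
    def duration(self) -> float:
        return float(self.trajectory["t"].iloc[-1])

    @property
    def target_xy(self) -> tuple[float, float]:
        th = np.deg2rad(self.target_theta)
        return (self.target_r * np.sin(th), self.target_r * np.cos(th))

    @property
    def endpoint_xy(self) -> tuple[float, float] | None:
        if self.endpoint_r is None:
            return None
        th = np.deg2rad(self.endpoint_theta)
        return (self.endpoint_r * np.sin(th), self.endpoint_r * np.cos(th))


@dataclass
class BinnedSession:
    """Time-binned session: spike counts, covariates, events and LFP phase.

    All streams share the bin axis of length ``n_bins``. ``trial_index`` maps
    each bin to a trial id (-1 for retained inter-trial bins). ``lfp_phase``
    holds one phase trace per unit (the phase of the unit's own channel) per
    band. ``unit_meta`` carries ``unit_id``, ``area``, ``channel``, ``elec_x``,
    ``elec_y`` (electrode coordinates, micrometres).
    """

    dt: float
    counts: np.ndarray
    continuous: pd.DataFrame
    events: pd.DataFrame
    lfp_phase: dict[str, np.ndarray]
    trial_index: np.ndarray
    unit_meta: pd.DataFrame

    @property
    def n_units(self) -> int:
        return int(self.counts.shape[0])

    @property
    def n_bins(self) -> int:
        return int(self.counts.shape[1])

    @property
    def duration(self) -> float:
        return self.n_bins * self.dt

    def validate(self) -> None:
        T = self.n_bins
        if len(self.continuous) != T or len(self.events) != T or len(self.trial_index) != T:
            raise ValueError("streams do not share the bin axis")
        for band, ph in self.lfp_phase.items():
            if ph.shape != self.counts.shape:
                raise ValueError(f"lfp_phase[{band}] shape mismatch")
        ev = self.events.to_numpy()
        if not np.isin(ev, (0, 1)).all():
            raise ValueError("events must be 0/1 trains")
        if (self.counts < 0).any():
            raise ValueError("negative spike counts")

    def bins_of_trial(self, trial_id: int) -> np.ndarray:
        return np.flatnonzero(self.trial_index == trial_id)


# ---------------------------------------------------------------------------
# latent covariates
# ---------------------------------------------------------------------------

def compute_latent_covariates(trial: TrialRecord) -> pd.DataFrame:
    """Per-sample path-integration and target-vector covariates of one trial.

    Returns a DataFrame aligned with ``trial.trajectory`` holding
    ``dist_origin`` (cm travelled, the integral of linear velocity),
    ``angle_origin`` (cumulative heading change, deg), ``dist_target``
    (Euclidean distance from current position to the fixed target, cm) and
    ``angle_target`` (bearing of the target relative to current heading,
    signed deg, rightward positive). Path integration restarts at each trial
    start by construction.
    """
    if trial.target_r is None or not np.isfinite(trial.target_r):
        raise ValueError("trial has no target")
    traj = trial.trajectory
    t = traj["t"].to_numpy()
    v = traj["lin_vel"].to_numpy()
    w = traj["ang_vel"].to_numpy()
    # cumulative trapezoid integrals of the velocities
    from scipy.integrate import cumulative_trapezoid

    dist_origin = np.concatenate(([0.0], cumulative_trapezoid(v, t)))
    angle_origin = np.concatenate(([0.0], cumulative_trapezoid(w, t)))
    tx, ty = trial.target_xy
    dx = tx - traj["x"].to_numpy()
    dy = ty - traj["y"].to_numpy()
    dist_target = np.hypot(dx, dy)
    # bearing of target in world frame, then relative to heading (deg,
    # rightward positive, consistent with heading measured from +y axis)
    bearing = np.rad2deg(np.arctan2(dx, dy))
    rel = bearing - traj["heading"].to_numpy()
    angle_target = (rel + 180.0) % 360.0 - 180.0
    return pd.DataFrame(
        {
            "t": t,
            "dist_origin": dist_origin,
            "angle_origin": angle_origin,
            "dist_target": dist_target,
            "angle_target": angle_target,
        }
    )


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def _bin_average(t: np.ndarray, x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Average samples of x(t) within each bin; NaN for empty bins."""
    idx = np.digitize(t, edges) - 1
    ok = (idx >= 0) & (idx < len(edges) - 1)
    sums = np.bincount(idx[ok], weights=x[ok], minlength=len(edges) - 1)
    n = np.bincount(idx[ok], minlength=len(edges) - 1)
    with np.errstate(invalid="ignore"):
        out = sums / n
    out[n == 0] = np.nan
    return out


def bin_session(
    trials: list[TrialRecord],
    spikes: list[np.ndarray],
    lfp: dict[str, np.ndarray] | None,
    dt: float = 0.006,
    *,
    lfp_t: np.ndarray | None = None,
    unit_meta: pd.DataFrame | None = None,
    phase_at: str = "acquisition",
    max_gap_bins: int = 1,
) -> BinnedSession:
    """Bin spikes, covariates, events and LFP phases at resolution ``dt``.

    Parameters
    ----------
    trials
        Trial records with absolute ``t_start`` times; trials must not overlap.
    spikes
        Per-unit arrays of absolute spike times (s); must be non-decreasing.
    lfp
        Mapping band -> (n_units, n_samples) instantaneous phase at the
        acquisition rate (each unit's own channel), or None for no LFP terms.
    lfp_t
        Sample times of the LFP phase arrays (required when ``lfp`` given).
    phase_at
        "acquisition": phases are sampled at bin centres from the
        acquisition-rate phase (default). "bins": phases are circularly
        averaged within each bin.

    Spike counts are raw per-bin counts (no baseline correction). Continuous
    covariates are averaged within each bin; events mark the bin containing
    the event time. Inter-trial bins are retained (``trial_index == -1``) with
    velocities, accelerations and latent covariates at 0 and eye position held
    at its last value.
    """
    for u, st in enumerate(spikes):
        st = np.asarray(st, dtype=float)
        if st.size > 1 and np.any(np.diff(st) < 0):
            raise ValueError(f"non-monotonic spike times for unit {u}")
    if not trials:
        raise ValueError("no trials")
    trials = sorted(trials, key=lambda tr: tr.t_start)
    t_end = max(tr.t_start + tr.duration for tr in trials)
    if spikes:
        spike_max = max((np.max(s) if len(s) else 0.0) for s in spikes)
        t_end = max(t_end, spike_max)
    n_bins = int(np.ceil(t_end / dt + 1e-9))
    edges = np.arange(n_bins + 1) * dt
    centers = edges[:-1] + dt / 2.0

    n_units = len(spikes)
    counts = np.zeros((n_units, n_bins), dtype=np.int64)
    for u, st in enumerate(spikes):
        st = np.asarray(st, dtype=float)
        if len(st):
            counts[u] = np.histogram(st, bins=edges)[0]

    trial_index = np.full(n_bins, -1, dtype=np.int64)
    cont = pd.DataFrame(
        np.zeros((n_bins, len(CONTINUOUS_VARS))), columns=list(CONTINUOUS_VARS)
    )
    cont[["eye_hor", "eye_vert"]] = np.nan
    events = pd.DataFrame(
        np.zeros((n_bins, len(EVENT_VARS)), dtype=np.int64), columns=list(EVENT_VARS)
    )

    for tr in trials:
        t0 = tr.t_start
        lo = int(np.floor(t0 / dt))
        hi = min(int(np.ceil((t0 + tr.duration) / dt)), n_bins)
        if hi <= lo:
            continue
        trial_index[lo:hi] = tr.trial_id
        sub_edges = edges[lo : hi + 1]
        traj = tr.trajectory
        tt = traj["t"].to_numpy() + t0
        # reject long gaps in the behavioural streams
        if len(tt) > 1:
            gaps = np.diff(tt)
            if np.any(gaps > max_gap_bins * dt + 1e-9):
                raise ValueError(
                    f"trial {tr.trial_id}: covariate gap of {gaps.max():.4f}s "
                    f"exceeds {max_gap_bins} bin(s)"
                )
        lat = compute_latent_covariates(tr)
        series = {
            "lin_vel": traj["lin_vel"].to_numpy(),
            "ang_vel": traj["ang_vel"].to_numpy(),
            "dist_origin": lat["dist_origin"].to_numpy(),
            "angle_origin": lat["angle_origin"].to_numpy(),
            "dist_target": lat["dist_target"].to_numpy(),
            "angle_target": lat["angle_target"].to_numpy(),
        }
        fs = 1.0 / np.median(np.diff(tt)) if len(tt) > 1 else 1.0 / dt
        series["lin_acc"] = np.gradient(series["lin_vel"], 1.0 / fs)
        series["ang_acc"] = np.gradient(series["ang_vel"], 1.0 / fs)
        if tr.gaze is not None:
            g = tr.gaze
            series["eye_hor"] = 0.5 * (g["left_h"].to_numpy() + g["right_h"].to_numpy())
            series["eye_vert"] = 0.5 * (g["left_v"].to_numpy() + g["right_v"].to_numpy())
        for name, x in series.items():
            binned = _bin_average(tt, x, sub_edges)
            # short empty bins: interpolate from neighbours
            if np.isnan(binned).any():
                ok = ~np.isnan(binned)
                binned = np.interp(np.arange(len(binned)), np.flatnonzero(ok), binned[ok])
            cont.iloc[lo:hi, cont.columns.get_loc(name)] = binned
        for name, t_ev in (
            ("target_on", tr.t_target_on),
            ("move_on", tr.t_move_on),
            ("move_off", tr.t_move_off),
            ("reward", tr.t_reward),
        ):
            if t_ev is None:
                continue
            b = int((t0 + t_ev) / dt)
            if 0 <= b < n_bins:
                events.iloc[b, events.columns.get_loc(name)] = 1

    # eye position: hold last value through inter-trial bins
    cont[["eye_hor", "eye_vert"]] = (
        cont[["eye_hor", "eye_vert"]].ffill().bfill().fillna(0.0)
    )

    lfp_phase: dict[str, np.ndarray] = {}
    if lfp:
        if lfp_t is None:
            raise ValueError("lfp_t required with lfp phases")
        for band, ph in lfp.items():
            ph = np.atleast_2d(np.asarray(ph, dtype=float))
            out = np.empty((ph.shape[0], n_bins))
            if phase_at == "acquisition":
                idx = np.clip(np.searchsorted(lfp_t, centers), 0, ph.shape[1] - 1)
                out = ph[:, idx]
            elif phase_at == "bins":
                for c in range(ph.shape[0]):
                    s = _bin_average(lfp_t, np.sin(ph[c]), edges)
                    co = _bin_average(lfp_t, np.cos(ph[c]), edges)
                    s = np.nan_to_num(s)
                    co = np.where(np.isnan(co), 1.0, co)
                    out[c] = np.arctan2(s, co)
            else:
                raise ValueError("phase_at must be 'acquisition' or 'bins'")
            lfp_phase[band] = wrap_angle(out)

    if unit_meta is None:
        unit_meta = default_unit_meta(n_units)

    sess = BinnedSession(
        dt=dt,
        counts=counts,
        continuous=cont,
        events=events,
        lfp_phase=lfp_phase,
        trial_index=trial_index,
        unit_meta=unit_meta,
    )
    sess.validate()
    return sess


def default_unit_meta(n_units: int, area: str = "MSTd") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit_id": np.arange(n_units),
            "area": [area] * n_units,
            "channel": np.arange(n_units),
            "elec_x": 100.0 * np.arange(n_units),
            "elec_y": np.zeros(n_units),
        }
    )


# ---------------------------------------------------------------------------
# unit quality control
# ---------------------------------------------------------------------------

def unit_qc(
    spike_times: np.ndarray,
    session_duration: float,
    *,
    isi_threshold: float = 0.001,
    max_isi_violation: float = 0.20,
    min_presence_rate: float = 0.90,
) -> dict:
    """Single-unit quality metrics: ISI violations and presence rate.

    ``isi_violation_fraction`` is the fraction of spikes occurring within 1 ms
    of the previous spike; ``presence_rate`` is 1 minus the fraction of 1-min
    bins with no spike. A unit passes with ISIv < 0.20 and PR > 0.90.
    """
    st = np.sort(np.asarray(spike_times, dtype=float))
    if st.size == 0:
        return {"isi_violation_fraction": np.nan, "presence_rate": 0.0, "pass": False}
    if st.size < 2:
        isiv = 0.0
    else:
        # fraction of *spikes* within 1 ms of the previous spike (the first
        # spike has no predecessor and cannot violate)
        isiv = float(np.sum(np.diff(st) < isi_threshold) / st.size)
    n_min_bins = max(1, int(np.ceil(session_duration / 60.0)))
    occupied = np.unique(np.clip((st / 60.0).astype(int), 0, n_min_bins - 1))
    pr = float(len(occupied) / n_min_bins)
    return {
        "isi_violation_fraction": isiv,
        "presence_rate": pr,
        "pass": bool(isiv < max_isi_violation and pr > min_presence_rate),
    }


# ---------------------------------------------------------------------------
# session directory serialization
# ---------------------------------------------------------------------------

def save_session(
    session: BinnedSession,
    path: str | Path,
    trials: list[TrialRecord] | None = None,
) -> None:
    """Write a session directory: JSON manifest, CSV tables, .npy streams."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "dt": session.dt,
        "continuous": list(session.continuous.columns),
        "events": list(session.events.columns),
        "bands": list(session.lfp_phase.keys()),
        "band_edges_hz": {b: BAND_EDGES.get(b) for b in session.lfp_phase},
        "n_units": session.n_units,
        "n_bins": session.n_bins,
    }
    (path / "session.json").write_text(json.dumps(manifest, indent=1))
    session.unit_meta.to_csv(path / "units.csv", index=False)
    np.save(path / "counts.npy", session.counts)
    np.save(path / "trial_index.npy", session.trial_index)
    np.save(path / "continuous.npy", session.continuous.to_numpy())
    np.save(path / "events.npy", session.events.to_numpy())
    for band, ph in session.lfp_phase.items():
        np.save(path / f"lfp_{band}.npy", ph)
    if trials is not None:
        rows = []
        arrays = {}
        for tr in trials:
            rows.append(
                {
                    "trial_id": tr.trial_id,
                    "t_start": tr.t_start,
                    "target_r": tr.target_r,
                    "target_theta": tr.target_theta,
                    "t_target_on": tr.t_target_on,
                    "t_target_off": tr.t_target_off,
                    "t_move_on": tr.t_move_on,
                    "t_move_off": tr.t_move_off,
                    "t_reward": tr.t_reward,
                    "endpoint_r": tr.endpoint_r,
                    "endpoint_theta": tr.endpoint_theta,
                    "rewarded": tr.rewarded,
                }
            )
            arrays[f"traj_{tr.trial_id}"] = tr.trajectory.to_numpy()
            if tr.gaze is not None:
                arrays[f"gaze_{tr.trial_id}"] = tr.gaze.to_numpy()
        pd.DataFrame(rows).to_csv(path / "trials.csv", index=False)
        np.savez(path / "trial_arrays.npz", **arrays)


def load_session(path: str | Path) -> tuple[BinnedSession, list[TrialRecord]]:
    """Read a session directory written by :func:`save_session`."""
    path = Path(path)
    man_file = path / "session.json"
    if not man_file.exists():
        raise FileNotFoundError(f"not a session directory (missing session.json): {path}")
    manifest = json.loads(man_file.read_text())
    for stream in ("counts", "trial_index", "continuous", "events"):
        if not (path / f"{stream}.npy").exists():
            raise FileNotFoundError(f"session directory missing stream: {stream}")
    session = BinnedSession(
        dt=manifest["dt"],
        counts=np.load(path / "counts.npy"),
        continuous=pd.DataFrame(
            np.load(path / "continuous.npy"), columns=manifest["continuous"]
        ),
        events=pd.DataFrame(
            np.load(path / "events.npy").astype(np.int64), columns=manifest["events"]
        ),
        lfp_phase={b: np.load(path / f"lfp_{b}.npy") for b in manifest["bands"]},
        trial_index=np.load(path / "trial_index.npy"),
        unit_meta=pd.read_csv(path / "units.csv"),
    )
    session.validate()
    trials: list[TrialRecord] = []
    if (path / "trials.csv").exists():
        tab = pd.read_csv(path / "trials.csv")
        arrays = np.load(path / "trial_arrays.npz") if (path / "trial_arrays.npz").exists() else {}
        traj_cols = ["t", "x", "y", "heading", "lin_vel", "ang_vel"]
        gaze_cols = ["t", "left_h", "left_v", "right_h", "right_v"]
        for _, row in tab.iterrows():
            tid = int(row["trial_id"])
            traj = pd.DataFrame(arrays[f"traj_{tid}"], columns=traj_cols)
            gkey = f"gaze_{tid}"
            gaze = pd.DataFrame(arrays[gkey], columns=gaze_cols) if gkey in arrays else None

            def _opt(v):
                return None if pd.isna(v) else float(v)

            trials.append(
                TrialRecord(
                    trial_id=tid,
                    t_start=float(row["t_start"]),
                    target_r=float(row["target_r"]),
                    target_theta=float(row["target_theta"]),
                    t_target_on=float(row["t_target_on"]),
                    t_target_off=float(row["t_target_off"]),
                    t_move_on=_opt(row["t_move_on"]),
                    t_move_off=_opt(row["t_move_off"]),
                    t_reward=_opt(row["t_reward"]),
                    endpoint_r=_opt(row["endpoint_r"]),
                    endpoint_theta=_opt(row["endpoint_theta"]),
                    rewarded=bool(row["rewarded"]),
                    trajectory=traj,
                    gaze=gaze,
                )
            )
    return session, trials
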
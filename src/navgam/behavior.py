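"""Behavioral quantification for the firefly task.

Targets and trajectory endpoints are expressed in polar coordinates (radial
distance r in cm, eccentricity theta in signed degrees). Steering accuracy is
summarized by the slope of a no-intercept regression of response on target
(multiplicative gain): slope 1 means unbiased, < 1 undershooting. Gaze is
summarized by the target-tracking index — the square root of the fraction of
variance in observed eye position explained by the prediction of perfect
fixation on the (hidden) target center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import TrialRecord

#: height of the virtual camera above the ground plane, cm
EYE_HEIGHT_CM = 10.0
#: interocular distance for the binocular projection, cm (only affects
#: vergence, which is near-negligible at task distances)
INTEROCULAR_CM = 3.5


@dataclass
class BehaviorSummary:
    session_id: str
    slope_radial: float
    slope_angular: float
    r2_radial: float
    r2_angular: float
    fraction_excluded_near_origin: float
    fraction_no_stop: float
    fraction_rewarded: float
    tracking_index_first_second: float
    tracking_index_whole_trial: float
    n_trials: int


# ---------------------------------------------------------------------------
# stop detection and trial exclusion
# ---------------------------------------------------------------------------

def find_stop(
    trial: TrialRecord,
    lin_thresh: float = 1.0,
    ang_thresh: float = 1.0,
    min_duration: float = 0.2,
) -> float | None:
    """First time (s from trial start) both speeds stay below threshold for
    ``min_duration``; None if the trial never stops."""
    traj = trial.trajectory
    t = traj["t"].to_numpy()
    slow = (np.abs(traj["lin_vel"].to_numpy()) < lin_thresh) & (
        np.abs(traj["ang_vel"].to_numpy()) < ang_thresh
    )
    # require motion before a stop counts (ignore the pre-movement rest)
    moved = np.maximum.accumulate(~slow)
    cand = slow & moved
    if not cand.any():
        return None
    # first run of length >= min_duration
    idx = np.flatnonzero(cand)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in runs:
        if t[run[-1]] - t[run[0]] >= min_duration or run[-1] == len(t) - 1:
            return float(t[run[0]])
    return None


def exclude_trials(
    trials: list[TrialRecord],
    min_endpoint_r: float = 50.0,
    max_duration: float = 7.0,
) -> tuple[list[TrialRecord], dict]:
    """Drop trials stopping within 0.5 m of the origin or never stopping
    within the maximum trial duration; report per-category fractions."""
    kept, near_origin, no_stop = [], 0, 0
    for tr in trials:
        if tr.endpoint_r is None:
            no_stop += 1
        elif tr.endpoint_r < min_endpoint_r:
            near_origin += 1
        else:
            kept.append(tr)
    n = max(len(trials), 1)
    report = {
        "n_total": len(trials),
        "n_kept": len(kept),
        "fraction_near_origin": near_origin / n,
        "fraction_no_stop": no_stop / n,
        "max_duration": max_duration,
    }
    return kept, report


# ---------------------------------------------------------------------------
# bias slopes
# ---------------------------------------------------------------------------

def bias_slopes(targets: np.ndarray, endpoints: np.ndarray) -> tuple[float, float]:
    """Multiplicative-gain regression of endpoints on targets (no intercept).

    Returns (slope, R^2). Slope 1 is unbiased; < 1 is undershooting.
    """
    x = np.asarray(targets, dtype=float)
    y = np.asarray(endpoints, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 trials")
    sxx = float(x @ x)
    if sxx <= 0 or np.ptp(x) == 0:
        raise ValueError("degenerate target spread")
    slope = float(x @ y) / sxx
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return slope, r2


# ---------------------------------------------------------------------------
# gaze prediction and target-tracking index
# ---------------------------------------------------------------------------

def predict_gaze(
    position_xy: np.ndarray,
    heading_deg: np.ndarray,
    target_xy: tuple[float, float],
    eye_height: float = EYE_HEIGHT_CM,
    interocular: float = INTEROCULAR_CM,
    near_clip: float = 5.0,
) -> pd.DataFrame:
    """Binocular eye position (deg) predicted by fixation on the target center.

    Perspective projection of the ground-plane target into eye-centered
    angles, for eyes ``eye_height`` cm above the ground separated laterally by
    ``interocular`` cm. Azimuth is signed (rightward positive); elevation is
    negative for a target below the horizon, growing more negative — and the
    azimuth less eccentric — as the target is approached. Samples with the
    target behind the observer (or inside the near clipping plane) are NaN
    and flagged invalid.
    """
    pos = np.atleast_2d(np.asarray(position_xy, dtype=float))
    hd = np.deg2rad(np.atleast_1d(np.asarray(heading_deg, dtype=float)))
    dx = target_xy[0] - pos[:, 0]
    dy = target_xy[1] - pos[:, 1]
    # rotate into the head frame: forward = along heading, lateral = rightward
    fwd = dx * np.sin(hd) + dy * np.cos(hd)
    lat = dx * np.cos(hd) - dy * np.sin(hd)
    valid = fwd > near_clip
    out = {}
    for label, off in (("left", -interocular / 2.0), ("right", interocular / 2.0)):
        lat_e = lat - off
        az = np.rad2deg(np.arctan2(lat_e, fwd))
        ground = np.hypot(lat_e, fwd)
        el = -np.rad2deg(np.arctan2(eye_height, ground))
        az[~valid] = np.nan
        el[~valid] = np.nan
        out[f"{label}_h"] = az
        out[f"{label}_v"] = el
    out["valid"] = valid
    return pd.DataFrame(out)


def tracking_index(observed: np.ndarray, predicted: np.ndarray) -> float:
    """sqrt of the fraction of variance in observed gaze explained by the
    fixation prediction, pooled over gaze components.

    Both inputs are (n, k) arrays of matching gaze components (e.g. columns
    horizontal and vertical, eyes averaged). The explained fraction is
    computed against the prediction directly — no free gain or offset — and
    rectified at 0 before the square root: 1 means gaze sat on the target
    center throughout, 0 means no correspondence.
    """
    o = np.atleast_2d(np.asarray(observed, dtype=float))
    p = np.atleast_2d(np.asarray(predicted, dtype=float))
    if o.shape != p.shape:
        raise ValueError("observed and predicted must have matching shapes")
    ok = np.isfinite(o).all(axis=1) & np.isfinite(p).all(axis=1)
    o, p = o[ok], p[ok]
    ss_tot = float(np.sum((o - o.mean(axis=0)) ** 2))
    if ss_tot <= 0:
        return float("nan")  # constant observed gaze: undefined
    ss_res = float(np.sum((o - p) ** 2))
    return float(np.sqrt(max(0.0, 1.0 - ss_res / ss_tot)))


def tracking_index_gain_fit(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Variant with a free per-component gain/offset regression (flagged
    alternative to the direct-prediction definition)."""
    o = np.atleast_2d(np.asarray(observed, dtype=float))
    p = np.atleast_2d(np.asarray(predicted, dtype=float))
    ok = np.isfinite(o).all(axis=1) & np.isfinite(p).all(axis=1)
    o, p = o[ok], p[ok]
    ss_tot = float(np.sum((o - o.mean(axis=0)) ** 2))
    if ss_tot <= 0:
        return float("nan")
    ss_res = 0.0
    for j in range(o.shape[1]):
        A = np.column_stack([p[:, j], np.ones(len(p))])
        coef, *_ = np.linalg.lstsq(A, o[:, j], rcond=None)
        ss_res += float(np.sum((o[:, j] - A @ coef) ** 2))
    return float(np.sqrt(max(0.0, 1.0 - ss_res / ss_tot)))


def trial_tracking_index(trial: TrialRecord, window: float | None = None) -> float:
    """Tracking index of one trial (components pooled, eyes averaged).

    ``window`` restricts to the first ``window`` seconds after target onset
    (the "first second" variant uses window=1.0); None uses the whole trial.
    """
    if trial.gaze is None:
        return float("nan")
    g = trial.gaze
    traj = trial.trajectory
    pred = predict_gaze(
        np.column_stack([traj["x"], traj["y"]]),
        traj["heading"].to_numpy(),
        trial.target_xy,
    )
    t = traj["t"].to_numpy()
    mask = np.ones(len(t), dtype=bool)
    if window is not None:
        mask &= (t >= trial.t_target_on) & (t <= trial.t_target_on + window)
    obs = np.column_stack(
        [
            0.5 * (g["left_h"].to_numpy() + g["right_h"].to_numpy()),
            0.5 * (g["left_v"].to_numpy() + g["right_v"].to_numpy()),
        ]
    )[mask]
    prd = np.column_stack(
        [
            0.5 * (pred["left_h"].to_numpy() + pred["right_h"].to_numpy()),
            0.5 * (pred["left_v"].to_numpy() + pred["right_v"].to_numpy()),
        ]
    )[mask]
    return tracking_index(obs, prd)


# ---------------------------------------------------------------------------
# bimodality coefficient
# ---------------------------------------------------------------------------

def bimodality_coefficient(samples: np.ndarray) -> float:
    """Sarle's bimodality coefficient with finite-sample correction.

        b = (g1^2 + 1) / (g2 + 3 (n-1)^2 / ((n-2)(n-3)))

    with g1 the bias-corrected sample skewness and g2 the bias-corrected
    excess kurtosis. The uniform distribution gives 5/9 ~ 0.556 (the null
    reference for preferred-angle distributions); larger values suggest
    bimodality, a Gaussian gives ~1/3.
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 samples")
    if np.ptp(x) == 0:
        return float("nan")
    g1 = stats.skew(x, bias=False)
    g2 = stats.kurtosis(x, fisher=True, bias=False)
    return float((g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


# ---------------------------------------------------------------------------
# session summary
# ---------------------------------------------------------------------------

def summarize_session(trials: list[TrialRecord], session_id: str = "session") -> BehaviorSummary:
    """Exclusion, bias slopes, reward rate and tracking indices of one session."""
    kept, report = exclude_trials(trials)
    tr_r = np.array([t.target_r for t in kept])
    tr_th = np.array([t.target_theta for t in kept])
    ep_r = np.array([t.endpoint_r for t in kept])
    ep_th = np.array([t.endpoint_theta for t in kept])
    slope_r, r2_r = bias_slopes(tr_r, ep_r)
    slope_th, r2_th = bias_slopes(tr_th, ep_th)
    ti_1 = [trial_tracking_index(t, window=1.0) for t in kept]
    ti_all = [trial_tracking_index(t) for t in kept]
    return BehaviorSummary(
        session_id=session_id,
        slope_radial=slope_r,
        slope_angular=slope_th,
        r2_radial=r2_r,
        r2_angular=r2_th,
        fraction_excluded_near_origin=report["fraction_near_origin"],
        fraction_no_stop=report["fraction_no_stop"],
        fraction_rewarded=float(np.mean([t.rewarded for t in kept])) if kept else np.nan,
        tracking_index_first_second=float(np.nanmean(ti_1)) if kept else np.nan,
        tracking_index_whole_trial=float(np.nanmean(ti_all)) if kept else np.nan,
        n_trials=len(trials),
    )
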
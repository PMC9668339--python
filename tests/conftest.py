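"""Shared fixtures: small synthetic sessions and helper builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter1d

from navgam import synthetic_session as synth
from navgam.core_data import BinnedSession, default_unit_meta


@pytest.fixture(scope="session")
def small_session():
    """A small but complete synthetic session (behavior, gaze, LFP, spikes)."""
    cfg = synth.SessionConfig(
        n_trials=30, area_counts={"MSTd": 3, "7a": 3, "dlPFC": 3}
    )
    session, trials, gt = synth.make_session(cfg, seed=11)
    return session, trials, gt


@pytest.fixture(scope="session")
def behavior_session():
    """A behavior-only session with enough trials for regression statistics."""
    cfg = synth.SessionConfig(n_trials=250, frac_near_origin=0.05, frac_no_stop=0.13)
    trials = synth.generate_behavior(cfg, seed=5)
    trials = synth.generate_gaze(trials, cfg.tracking_quality, seed=6)
    return cfg, trials


def make_covariate_session(
    seed: int,
    n_bins: int = 30000,
    names=("lin_vel", "ang_vel", "lin_acc", "ang_acc", "dist_origin", "eye_hor"),
    tuned: dict | None = None,
    baseline_hz: float = 10.0,
    dt: float = 0.006,
    trial_len: int = 500,
):
    """Session with smooth artificial covariates and one unit whose rate is
    exp(log(baseline*dt) + sum of the given tuning functions). Returns
    (session, counts, truth dict)."""
    rng = np.random.default_rng(seed)
    xs = {}
    for name in names:
        x = gaussian_filter1d(rng.standard_normal(n_bins), 20)
        xs[name] = x / x.std()
    eta = np.full(n_bins, np.log(baseline_hz * dt))
    tuned = tuned or {}
    for name, f in tuned.items():
        eta += f(xs[name])
    y = rng.poisson(np.exp(eta))
    session = BinnedSession(
        dt=dt,
        counts=y[None, :],
        continuous=pd.DataFrame(xs),
        events=pd.DataFrame(index=range(n_bins)),
        lfp_phase={},
        trial_index=np.repeat(np.arange(int(np.ceil(n_bins / trial_len))), trial_len)[:n_bins],
        unit_meta=default_unit_meta(1),
    )
    return session, y, tuned
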
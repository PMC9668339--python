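"""Pipeline orchestration: simulate -> fit -> behavior -> population/coupling.

A single YAML (or dict) config drives all stages; every stage writes
plain-text outputs (CSV/JSON) into the run directory and records status,
wall time and output paths in ``manifest.json``. Re-running a config resumes
from the first incomplete stage; deterministic stages reproduce identical
outputs for the same config and seed. Logs are line-delimited JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bh
from . import coupling_network as cn
from . import encoding_metrics as em
from . import pgam
from . import population_structure as ps
from . import synthetic_session as synth
from .core_data import load_session, save_session

STAGES = ("simulate", "fit", "behavior", "population", "coupling")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "navgam_run",
    "simulate": {"n_trials": 60, "area_counts": {"MSTd": 6, "7a": 6, "dlPFC": 6}},
    "fit": {
        "enabled": True,
        "n_knots": 8,
        "phase_knots": 7,
        "coupling": True,
        "spike_history": True,
        "lambda_strategy": "cv_first",  # CV on the first unit, reuse after
        "alpha": 0.01,
    },
    "behavior": {"enabled": True},
    "population": {"enabled": True, "k": 7, "n_grid": 40},
    "coupling": {"enabled": True},
}


class _JsonFormatter(logging.Formatter):
    def format(self, record):
        return json.dumps(
            {
                "t": round(record.created, 3),
                "level": record.levelname,
                "stage": getattr(record, "stage", None),
                "msg": record.getMessage(),
            }
        )


log = logging.getLogger("navgam")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(_JsonFormatter())
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    out_dir: str
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, status: str, wall_time: float, outputs: list[str]):
        self.stages[stage] = {
            "status": status,
            "wall_time_s": round(wall_time, 3),
            "outputs": outputs,
        }

    def save(self, path: Path):
        path.write_text(json.dumps(self.__dict__, indent=1, default=str))

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        d = json.loads(path.read_text())
        return cls(**d)

    def done(self, stage: str) -> bool:
        st = self.stages.get(stage)
        return bool(st and st["status"] == "done" and all(Path(p).exists() for p in st["outputs"]))


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(config: dict | str | Path | None) -> dict:
    if config is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    return _merge(DEFAULT_CONFIG, config)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: dict, out: Path, seed: int) -> list[str]:
    sim_kwargs = {k: v for k, v in cfg["simulate"].items()}
    scfg = synth.SessionConfig(**sim_kwargs)
    session, trials, gt = synth.make_session(scfg, seed=seed)
    sdir = out / "session"
    save_session(session, sdir, trials)
    gt_json = {
        "gains": list(gt.gains),
        "tracking_quality": gt.tracking_quality,
        "units": [
            {
                "unit_id": u.unit_id,
                "area": u.area,
                "baseline_hz": u.baseline_hz,
                "tuned_variables": sorted(u.tuned_variables),
                "tunings": {k: [v[0].tolist(), v[1].tolist()] for k, v in u.tunings.items()},
                "phase_tuning": {k: list(v) for k, v in u.phase_tuning.items()},
                "coupled_senders": sorted(u.coupling),
            }
            for u in gt.units
        ],
    }
    (out / "ground_truth.json").write_text(json.dumps(gt_json))
    return [str(sdir / "session.json"), str(out / "ground_truth.json")]


def stage_fit(cfg: dict, out: Path, seed: int) -> list[str]:
    session, _trials = load_session(out / "session")
    fcfg = cfg["fit"]
    spec = pgam.ModelConfig(
        n_knots=fcfg["n_knots"],
        phase_knots=fcfg["phase_knots"],
        coupling=fcfg["coupling"],
        spike_history=fcfg["spike_history"],
        alpha=fcfg["alpha"],
    )
    strategy = fcfg.get("lambda_strategy", "cv_first")
    fixed = None
    if isinstance(strategy, (int, float)):
        fixed = float(strategy)
    summary_rows, tuning_rows = [], []
    fits_meta = {}
    n_grid = cfg["population"]["n_grid"]
    for uid in range(session.n_units):
        design = pgam.assemble_design(session, uid, spec)
        full = pgam.fit_pgam(
            design, session.counts[uid], seed=seed, fixed_lambda=fixed, alpha=spec.alpha
        )
        if fixed is None and strategy == "cv_first":
            fixed = next(iter(full.lambdas.values()))
        red = pgam.reduce_and_refit(design, full, session.counts[uid], alpha=spec.alpha, seed=seed)
        area = session.unit_meta["area"].iloc[uid]
        fits_meta[uid] = {
            "term_pvalues": full.term_pvalues,
            "pseudo_r2_test": full.pseudo_r2_test,
            "reduced_terms": red.term_names,
        }
        for name, p in full.term_pvalues.items():
            summary_rows.append(
                {
                    "unit_id": uid,
                    "area": area,
                    "term": name,
                    "kind": full.term_kind[name],
                    "p_value": p,
                    "edf": full.edf[name],
                    "pseudo_r2_train": full.pseudo_r2_train,
                    "pseudo_r2_test": full.pseudo_r2_test,
                    "pseudo_r2_test_reduced": red.pseudo_r2_test,
                }
            )
        for name, kind in full.term_kind.items():
            if kind not in ("task", "lfp"):
                continue
            tf = em.extract_tuning(full, name, n_grid=n_grid)
            for gx, r in zip(tf.grid, tf.response):
                tuning_rows.append(
                    {"unit_id": uid, "area": area, "variable": name, "x": gx, "rate_hz": r,
                     "p_value": tf.p_value}
                )
        log.info("fitted unit %d (%s)", uid, area, extra={"stage": "fit"})
    pd.DataFrame(summary_rows).to_csv(out / "fit_summary.csv", index=False)
    pd.DataFrame(tuning_rows).to_csv(out / "tuning_curves.csv", index=False)
    return [str(out / "fit_summary.csv"), str(out / "tuning_curves.csv")]


def stage_behavior(cfg: dict, out: Path, seed: int) -> list[str]:
    _session, trials = load_session(out / "session")
    summ = bh.summarize_session(trials, session_id=_config_hash(cfg))
    pd.DataFrame([summ.__dict__]).to_csv(out / "behavior_summary.csv", index=False)
    rows = []
    for tr in trials:
        rows.append(
            {
                "trial_id": tr.trial_id,
                "target_r": tr.target_r,
                "target_theta": tr.target_theta,
                "endpoint_r": tr.endpoint_r,
                "endpoint_theta": tr.endpoint_theta,
                "rewarded": tr.rewarded,
                "tracking_index": bh.trial_tracking_index(tr),
            }
        )
    pd.DataFrame(rows).to_csv(out / "behavior_trials.csv", index=False)
    return [str(out / "behavior_summary.csv"), str(out / "behavior_trials.csv")]


def stage_population(cfg: dict, out: Path, seed: int) -> list[str]:
    summary = pd.read_csv(out / "fit_summary.csv")
    task = summary[summary["kind"].isin(["task", "lfp", "event"])]
    alpha = cfg["fit"]["alpha"]
    # tuned fractions per area and variable (the population selectivity map)
    rows = []
    for (area, term), grp in task.groupby(["area", "term"]):
        fr = ps.fraction_tuned(grp["p_value"] < alpha)
        rows.append({"area": area, "term": term, **fr})
    pd.DataFrame(rows).to_csv(out / "tuned_fractions.csv", index=False)
    # binary profiles -> jaccard spectral clusters
    pivot = (task.assign(tuned=task["p_value"] < alpha)
             .pivot_table(index="unit_id", columns="term", values="tuned", aggfunc="first")
             .fillna(False).astype(bool))
    areas = summary.groupby("unit_id")["area"].first().loc[pivot.index].to_numpy()
    k = min(cfg["population"]["k"], max(2, len(np.unique(pivot.to_numpy(), axis=0)) - 1))
    try:
        ca = ps.jaccard_spectral_cluster(pivot.to_numpy(), k=k, seed=seed)
        labels = ca.labels
    except ValueError:
        labels = np.zeros(len(pivot), dtype=int)
    lab_df = pd.DataFrame({"unit_id": pivot.index, "area": areas, "cluster": labels})
    lab_df.to_csv(out / "cluster_labels.csv", index=False)
    # stacked tuning shapes -> embedding + density clusters
    tun = pd.read_csv(out / "tuning_curves.csv")
    mat = tun.pivot_table(index="unit_id", columns=["variable", "x"], values="rate_hz")
    X = mat.to_numpy()
    # z-score each variable's curve block
    for var in tun["variable"].unique():
        cols = [j for j, c in enumerate(mat.columns) if c[0] == var]
        blk = X[:, cols]
        sd = blk.std()
        X[:, cols] = (blk - blk.mean()) / (sd if sd > 0 else 1.0)
    outputs = [str(out / "tuned_fractions.csv"), str(out / "cluster_labels.csv")]
    if len(X) >= 10:
        emb = ps.shape_embed_cluster(X, seed=seed)
        pd.DataFrame(
            {
                "unit_id": mat.index,
                "x": emb.embedding_2d[:, 0],
                "y": emb.embedding_2d[:, 1],
                "cluster": emb.labels,
            }
        ).to_csv(out / "embedding.csv", index=False)
        outputs.append(str(out / "embedding.csv"))
    return outputs


def stage_coupling(cfg: dict, out: Path, seed: int) -> list[str]:
    summary = pd.read_csv(out / "fit_summary.csv")
    session, _ = load_session(out / "session")
    coup = summary[summary["kind"] == "coupling"].copy()
    outputs = []
    alpha = cfg["fit"]["alpha"]
    if not coup.empty:
        meta = session.unit_meta.set_index("unit_id")
        coup["sender"] = coup["term"].str.split("_").str[1].astype(int)
        coup["sender_area"] = meta.loc[coup["sender"], "area"].to_numpy()
        coup["receiver_area"] = meta.loc[coup["unit_id"], "area"].to_numpy()
        coup["significant"] = coup["p_value"] < alpha
        coup.rename(columns={"unit_id": "receiver"}).to_csv(out / "coupling_edges.csv", index=False)
        grid = (
            coup.groupby(["sender_area", "receiver_area"])
            .apply(lambda g: g.groupby("sender")["significant"].any().mean(),
                   include_groups=False)
            .unstack()
        )
        grid.to_csv(out / "coupling_grid.csv")
        outputs += [str(out / "coupling_edges.csv"), str(out / "coupling_grid.csv")]
    return outputs


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "fit": stage_fit,
    "behavior": stage_behavior,
    "population": stage_population,
    "coupling": stage_coupling,
}

_STAGE_DEPS = {
    "simulate": (),
    "fit": ("simulate",),
    "behavior": ("simulate",),
    "population": ("fit",),
    "coupling": ("fit",),
}


def run_pipeline(config: dict | str | Path | None = None, force: bool = False) -> RunManifest:
    """Execute all enabled stages in dependency order; resume if possible."""
    cfg = load_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    mpath = out / "manifest.json"
    if mpath.exists() and not force:
        manifest = RunManifest.load(mpath)
        if manifest.config_hash != _config_hash(cfg):
            manifest = RunManifest(_config_hash(cfg), seed, str(out))
    else:
        manifest = RunManifest(_config_hash(cfg), seed, str(out))
    failed = set()
    for stage in STAGES:
        enabled = cfg.get(stage, {}).get("enabled", True) if stage != "simulate" else True
        if not enabled:
            manifest.record(stage, "skipped", 0.0, [])
            continue
        if any(d in failed or cfg.get(d, {}).get("enabled", True) is False
               for d in _STAGE_DEPS[stage]):
            manifest.record(stage, "skipped_missing_dependency", 0.0, [])
            continue
        if manifest.done(stage) and not force:
            log.info("stage %s already complete", stage, extra={"stage": stage})
            continue
        t0 = time.time()
        try:
            outputs = _STAGE_FUNCS[stage](cfg, out, seed)
            manifest.record(stage, "done", time.time() - t0, outputs)
            log.info("stage %s done", stage, extra={"stage": stage})
        except Exception as exc:  # record and halt downstream stages
            manifest.record(stage, f"failed: {exc}", time.time() - t0, [])
            log.error("stage %s failed: %s", stage, exc, extra={"stage": stage})
            failed.add(stage)
        manifest.save(mpath)
    manifest.save(mpath)
    return manifest
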
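"""End-to-end reproducible runs: synth -> train -> calibrate -> sessions ->
symmetry index -> outcomes.

A single master seed fans out deterministically to per-stage child seeds;
the configuration, seed and a content hash are written to a manifest in the
artifact directory, so re-running an identical configuration reproduces
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bsi as _bsi
from . import control as _control
from . import online as _online
from . import outcomes as _outcomes
from .model import BCIModel, SearchGrid, CVScheme, model_search
from .synth import (ERDSimConfig, simulate_force_trace, simulate_imagery_stream,
                    simulate_rest_stream, simulate_session)
from .io import save_decisions, save_schedule


@dataclass
class RunConfig:
    """Parameters of one end-to-end run."""

    seed: int = 0
    n_runs: int = 5
    n_cues: int = 20
    sim: dict = field(default_factory=dict)          # ERDSimConfig overrides
    grid: dict = field(default_factory=dict)         # SearchGrid overrides
    session_levels: tuple = ("L1", "L2", "L3")
    days_per_level: int = 3
    trials_per_session: int = 8
    subject_engagement: float = 0.9
    subject_force_compliance: float = 0.9
    bsi_band_hz: tuple = (6.0, 32.0)

    def to_dict(self) -> dict:
        return asdict(self)


class ModelDrivenSubject:
    """Simulated trainee that drives the fitted decoder with synthetic EEG.

    Per checkpoint, the subject engages in imagery with probability
    ``engagement`` (producing an ERD-modulated stream scored by the actual
    online chain) and moves the forearm compliantly with probability
    ``q_force``.
    """

    def __init__(self, model: BCIModel, sim_config: ERDSimConfig,
                 engagement: float = 0.9, q_force: float = 0.9,
                 timeout_s: float = _control.DEFAULT_TIMEOUT_S):
        self.model = model
        self.sim_config = sim_config
        self.engagement = engagement
        self.q_force = q_force
        self.timeout_s = timeout_s

    def checkpoint_streams(self, cp, rng: np.random.Generator):
        duration = self.timeout_s + self.model.window_len_s
        child = np.random.default_rng(rng.integers(2**31))
        if child.random() < self.engagement:
            stream = simulate_imagery_stream(self.sim_config, duration,
                                             rng=child, active_from_s=0.0)
        else:
            stream = simulate_rest_stream(self.sim_config, duration, rng=child)
        decisions = _online.stream_classify(self.model, stream)
        comply = child.random() < self.q_force
        direction = cp.required_direction if comply else (
            "flexion" if cp.required_direction == "extension" else "extension")
        latency = float(child.uniform(1.5, 3.5))
        force = simulate_force_trace(direction, latency,
                                     duration_s=self.timeout_s, rng=child)
        return decisions, force


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31, size=n)]


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute every stage and write the artifact directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    log_fh = open(outdir / "run.log", "w")

    def log(msg: str) -> None:
        stamp = datetime.now().isoformat(timespec="seconds")
        log_fh.write(f"{stamp} {msg}\n")
        log_fh.flush()

    log(f"pipeline start seed={config.seed}")

    # --- synth: stimulus-presentation runs + calibration rest stream --------
    sim = ERDSimConfig(seed=seeds[0], **config.sim)
    runs = simulate_session(sim, config.n_runs, config.n_cues)
    recordings = [r for r, _ in runs]
    schedules = [s for _, s in runs]
    for i, sched in enumerate(schedules):
        save_schedule(sched, outdir / f"schedule_run{i + 1}.csv")
    rest = simulate_rest_stream(sim, 30.0,
                                rng=np.random.default_rng(seeds[1]))
    log(f"synth: {config.n_runs} runs x {config.n_cues} cues + 30-s rest")

    # --- train: 54-candidate search ----------------------------------------
    grid = SearchGrid(**{k: (CVScheme(**v) if k == "cv_scheme" else v)
                         for k, v in config.grid.items()})
    model, leaderboard = model_search(recordings, schedules, grid,
                                      seed=seeds[2])
    leaderboard.to_csv(outdir / "leaderboard.csv", index=False)
    log(f"train: {len(leaderboard)} candidates, best "
        f"{model.feature_spec.kind}+{model.classifier_kind} "
        f"cv={model.cv_accuracy:.3f}")

    # --- calibrate ----------------------------------------------------------
    calib = _online.calibrate_threshold(model, rest)
    model.save(outdir / "model.json")
    rest_decisions = _online.stream_classify(model, rest)
    save_decisions(rest_decisions, outdir / "rest_decisions.csv")
    log(f"calibrate: max_rest={calib.max_rest:.3f} "
        f"threshold={calib.threshold:.3f}")

    # --- sessions -----------------------------------------------------------
    subject = ModelDrivenSubject(model, sim, config.subject_engagement,
                                 config.subject_force_compliance)
    weekly_rows = []
    session_rng = np.random.default_rng(seeds[3])
    for w, level in enumerate(config.session_levels, start=1):
        daily = []
        for day in range(config.days_per_level):
            slog = _control.run_session(level, config.trials_per_session,
                                        subject,
                                        seed=int(session_rng.integers(2**31)),
                                        date_index=day)
            slog.save_jsonl(outdir / f"session_{level}_day{day + 1}.jsonl")
            daily.append(_control.success_rate(slog))
        mean, sd = _control.weekly_summary(daily)
        weekly_rows.append({"week": w, "level": level, "mode": "BF",
                            "mean_success_rate": mean, "sd": sd,
                            "n_days": config.days_per_level})
    pd.DataFrame(weekly_rows).to_csv(outdir / "weekly_success.csv", index=False)
    log(f"sessions: {len(weekly_rows)} level-weeks logged")

    # --- brain symmetry index ----------------------------------------------
    hmap = _bsi.default_hemisphere_map(recordings[0].channel_labels)
    state_epochs = [(onset + _bsi.DEFAULT_T, label)
                    for onset, label in zip(schedules[0].cue_onsets,
                                            schedules[0].cue_labels)]
    series = _bsi.bsi_series(recordings[0], hmap, state_epochs,
                             band_hz=config.bsi_band_hz)
    pd.DataFrame([{"state": k, "mean_bsi": v,
                   "n_epochs": sum(1 for _, s in state_epochs if s == k)}
                  for k, v in sorted(series.items())]).to_csv(
        outdir / "bsi.csv", index=False)

    # --- outcomes ------------------------------------------------------------
    table = _outcomes.case_wmft_table()
    rows = []
    for task in table.timed_tasks():
        rows.append({"quantity": f"improvement_pct[{task}]",
                     "value": _outcomes.percent_improvement(table, task)})
    avg_base = float(np.mean([_outcomes.average_wmft_time(table, s)
                              for s in _outcomes.BASELINE_SESSIONS]))
    y = [avg_base] + [_outcomes.average_wmft_time(table, s)
                      for s in ("week_1", "week_2", "week_3", "week_4",
                                "retention")]
    fit = _outcomes.fit_log_model(y)
    rows += [{"quantity": "log_fit_r", "value": fit.r},
             {"quantity": "log_fit_p", "value": fit.p},
             {"quantity": "avg_time_baseline_s", "value": avg_base},
             {"quantity": "avg_time_retention_s",
              "value": _outcomes.average_wmft_time(table, "retention")}]
    pd.DataFrame(rows).to_csv(outdir / "outcomes.csv", index=False)

    # --- manifest ------------------------------------------------------------
    cfg = config.to_dict()
    manifest = {
        "seed": config.seed,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=list).encode()).hexdigest(),
        "best_model": {"feature": model.feature_spec.kind,
                       "classifier": model.classifier_kind,
                       "window_start_s": model.window_start_s,
                       "cv_accuracy": model.cv_accuracy,
                       "activity_threshold": model.activity_threshold},
        "calibration_max_rest": calib.max_rest,
        "n_candidates": int(len(leaderboard)),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log("pipeline complete")
    log_fh.close()
    return outdir
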
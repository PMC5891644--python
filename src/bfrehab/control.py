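"""The BF-control trial state machine and the goal-oriented protocols.

A trial is an ordered list of checkpoints.  Each checkpoint asks the user
to (a) produce a BCI trigger by motor imagery and/or (b) move the forearm
in a required direction against the force sensor, both within a 10-s
timeout.  A checkpoint that times out marks the trial unsuccessful and the
device completes the movement passively; remaining checkpoints are still
executed so the limb always receives the full movement cycle.  Functional
electrical stimulation (FES) events for hand opening are scheduled per
checkpoint: during warm-up, stimulation switches off automatically after
5 s; in the level-3 grasp phase the device waits 3 s and releases the
stimulation so the user can hold the object.

Protocol levels: warm-up session 1 (fully passive, success not applicable),
session 2 (BCI trigger only), session 3 (full BF control); level 1
(plate-cleaning: extend then flex), level 2 (bucket lift: flex then
extend), level 3 (reach-grasp-place-release: four checkpoints, FES on the
grasp and release phases).  Sessions guarantee a minimum of 10 delivered
repetitions, topping up with passive movements when needed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .online import DecisionStream
from .synth import ForceTrace

DEFAULT_TIMEOUT_S = 10.0
MIN_PASSIVE_REPS = 10
FES_HOLD_WAIT_S = 3.0
FES_AUTO_OFF_S = 5.0
FORCE_THRESHOLD_FRACTION = 0.1
FORCE_HOLD_S = 0.2

LEVELS = ("warmup1", "warmup2", "warmup3", "L1", "L2", "L3")


@dataclass
class Checkpoint:
    required_direction: str  # "extension" | "flexion"
    bci_required: bool = True
    force_required: bool = True
    timeout_s: float = DEFAULT_TIMEOUT_S
    fes_action: str = "none"  # "none" | "open_then_hold" | "open_then_release"


@dataclass
class TrialSpec:
    checkpoints: list[Checkpoint]
    level: str

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")

    @property
    def is_applicable(self) -> bool:
        """Whether success is defined (any active control requested)."""
        return any(c.bci_required or c.force_required for c in self.checkpoints)


@dataclass
class CheckpointOutcome:
    passed: bool
    latency_s: float | None
    fes_events: list[tuple[float, str]] = field(default_factory=list)


@dataclass
class TrialResult:
    checkpoint_outcomes: list[str]  # "pass" | "timeout" | "passive"
    success: bool | None            # None when not applicable (warm-up 1)
    passive_fallback_used: bool
    latencies_s: list[float | None]
    level: str = "L1"

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass
class SessionLog:
    trials: list[TrialResult]
    level: str
    mode: str = "BF"  # "BCI-only" | "BF" | "passive"
    min_passive_reps: int = MIN_PASSIVE_REPS
    date_index: int = 0

    @property
    def delivered_repetitions(self) -> int:
        return len(self.trials)

    def applicable_trials(self) -> list[TrialResult]:
        return [t for t in self.trials if t.success is not None]

    def save_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.trials:
                fh.write(t.to_json() + "\n")


def level_trial_spec(level: str) -> TrialSpec:
    """The checkpoint chain for one trial of a protocol level."""
    if level == "warmup1":
        cps = [Checkpoint("extension", False, False),
               Checkpoint("flexion", False, False)]
    elif level == "warmup2":
        cps = [Checkpoint("extension", True, False, fes_action="open_then_release"),
               Checkpoint("flexion", True, False)]
    elif level == "warmup3":
        cps = [Checkpoint("extension", True, True, fes_action="open_then_release"),
               Checkpoint("flexion", True, True)]
    elif level == "L1":  # plate cleaning: extend to wash, flex to return
        cps = [Checkpoint("extension", True, True),
               Checkpoint("flexion", True, True)]
    elif level == "L2":  # bucket lift: flex to lift, extend to place
        cps = [Checkpoint("flexion", True, True),
               Checkpoint("extension", True, True)]
    elif level == "L3":  # reach+grasp, lift, place+release, return
        cps = [Checkpoint("extension", True, True, fes_action="open_then_hold"),
               Checkpoint("flexion", True, True),
               Checkpoint("extension", True, True, fes_action="open_then_release"),
               Checkpoint("flexion", True, True)]
    else:
        raise ValueError(f"unknown level {level!r}")
    return TrialSpec(cps, level)


def first_force_crossing(force: ForceTrace, direction: str,
                         threshold: float | None = None,
                         hold_s: float = FORCE_HOLD_S) -> float | None:
    """First time the trace crosses the directional threshold, sustained.

    The default threshold is 10% of the trace's absolute range; the crossing
    must be held for ``hold_s`` seconds to count as a deliberate movement.
    """
    sign = 1.0 if direction == "extension" else -1.0
    v = sign * force.values
    if threshold is None:
        rng = np.abs(force.values).max()
        threshold = FORCE_THRESHOLD_FRACTION * rng if rng > 0 else np.inf
    above = v >= threshold
    need = max(int(round(hold_s * force.fs_hz)), 1)
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= need:
            return (i - need + 1) / force.fs_hz
    return None


def run_checkpoint(cp: Checkpoint, decisions: DecisionStream | None,
                   force: ForceTrace | None,
                   force_threshold: float | None = None) -> CheckpointOutcome:
    """Evaluate one BF-control gate.

    Pass requires every enabled modality to be satisfied within the
    timeout; the latency is the first time both are simultaneously met
    (each condition latches once achieved).
    """
    t_bci = None
    if cp.bci_required:
        if decisions is None:
            raise ValueError("checkpoint requires a BCI decision stream")
        t_bci = decisions.first_trigger_time()
    t_force = None
    if cp.force_required:
        if force is None:
            raise ValueError("checkpoint requires a force trace")
        t_force = first_force_crossing(force, cp.required_direction,
                                       force_threshold)

    needed = []
    if cp.bci_required:
        needed.append(t_bci)
    if cp.force_required:
        needed.append(t_force)
    if not needed:  # passive checkpoint: device moves the limb, no gate
        return CheckpointOutcome(True, None, _fes_schedule(cp, 0.0))
    if any(t is None for t in needed):
        return CheckpointOutcome(False, None, [])
    latency = max(needed)
    if latency > cp.timeout_s:
        return CheckpointOutcome(False, None, [])
    return CheckpointOutcome(True, float(latency), _fes_schedule(cp, float(latency)))


def _fes_schedule(cp: Checkpoint, t0: float) -> list[tuple[float, str]]:
    if cp.fes_action == "open_then_hold":
        return [(t0, "fes_on"), (t0 + FES_HOLD_WAIT_S, "fes_off")]
    if cp.fes_action == "open_then_release":
        return [(t0, "fes_on"), (t0 + FES_AUTO_OFF_S, "fes_off")]
    return []


def run_trial(spec: TrialSpec, streams) -> TrialResult:
    """Execute all checkpoints of a trial.

    ``streams`` is a sequence of (DecisionStream | None, ForceTrace | None)
    pairs, one per checkpoint.  A timed-out checkpoint triggers the passive
    fallback; the remaining checkpoints are still run.
    """
    if len(streams) != len(spec.checkpoints):
        raise ValueError("one stream pair per checkpoint required")
    outcomes, latencies = [], []
    fallback = False
    for cp, (dec, force) in zip(spec.checkpoints, streams):
        if not (cp.bci_required or cp.force_required):
            outcomes.append("passive")
            latencies.append(None)
            continue
        res = run_checkpoint(cp, dec, force)
        outcomes.append("pass" if res.passed else "timeout")
        latencies.append(res.latency_s)
        if not res.passed:
            fallback = True
    if spec.is_applicable:
        success = all(o != "timeout" for o in outcomes)
    else:
        success = None
        fallback = True  # fully passive movement delivery
    return TrialResult(outcomes, success, fallback, latencies, spec.level)


def success_rate(log: SessionLog) -> float:
    """Successful trials / applicable trials (warm-up-1 style trials excluded)."""
    applicable = log.applicable_trials()
    if not applicable:
        raise ValueError("no applicable trials in the session log")
    return sum(1 for t in applicable if t.success) / len(applicable)


def run_session(level: str, n_trials: int, subject, seed: int = 0,
                date_index: int = 0) -> SessionLog:
    """Run one training session of ``n_trials`` trials at ``level``.

    ``subject`` provides per-checkpoint streams via
    ``subject.checkpoint_streams(checkpoint, rng)``; it is ignored for
    fully passive levels.  At least ``MIN_PASSIVE_REPS`` movements are
    delivered: if fewer trials are run, passive repetitions are appended.
    """
    spec = level_trial_spec(level)
    rng = np.random.default_rng(seed)
    trials = []
    for _ in range(n_trials):
        if spec.is_applicable:
            streams = [subject.checkpoint_streams(cp, rng)
                       for cp in spec.checkpoints]
        else:
            streams = [(None, None)] * len(spec.checkpoints)
        trials.append(run_trial(spec, streams))
    while len(trials) < MIN_PASSIVE_REPS:
        trials.append(TrialResult(["passive"] * len(spec.checkpoints), None,
                                  True, [None] * len(spec.checkpoints), level))
    mode = {"warmup1": "passive", "warmup2": "BCI-only"}.get(level, "BF")
    return SessionLog(trials, level, mode=mode, date_index=date_index)


def weekly_summary(daily_rates) -> tuple[float, float]:
    """Mean and sample standard deviation of daily success rates."""
    rates = np.asarray(list(daily_rates), dtype=float)
    if rates.size == 0:
        raise ValueError("no daily rates")
    sd = float(rates.std(ddof=1)) if rates.size > 1 else 0.0
    return float(rates.mean()), sd


class ScriptedSubject:
    """Probabilistic stand-in subject for protocol-level simulation.

    Per checkpoint the subject produces a BCI trigger with probability
    ``p_bci`` (at ~3 s) and a compliant directional force with probability
    ``q_force`` (at ~2 s); failures yield an un-triggered decision stream or
    a force push in the wrong direction.  Checkpoint outcomes are mutually
    independent, so a two-checkpoint level-1 trial succeeds with
    probability (p_bci * q_force)^2.
    """

    def __init__(self, p_bci: float = 0.9, q_force: float = 0.9,
                 fs_force: float = 50.0, timeout_s: float = DEFAULT_TIMEOUT_S):
        self.p_bci = p_bci
        self.q_force = q_force
        self.fs_force = fs_force
        self.timeout_s = timeout_s

    def checkpoint_streams(self, cp: Checkpoint, rng: np.random.Generator):
        times = 2.0 + 0.5 * np.arange(int(self.timeout_s / 0.5))
        trigger = rng.random() < self.p_bci
        raw = np.full(len(times), 0.5 if trigger else 0.0)
        triggered = np.zeros(len(times), dtype=bool)
        if trigger:
            triggered[times >= 3.0] = True
        dec = DecisionStream(times, raw, raw.copy(), triggered, 0.1)
        comply = rng.random() < self.q_force
        direction = cp.required_direction if comply else (
            "flexion" if cp.required_direction == "extension" else "extension")
        n = int(self.timeout_s * self.fs_force)
        t = np.arange(n) / self.fs_force
        sign = 1.0 if direction == "extension" else -1.0
        values = sign * np.clip((t - 2.0) / 1.0, 0.0, 1.0)
        force = ForceTrace(values, self.fs_force)
        return dec, force
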
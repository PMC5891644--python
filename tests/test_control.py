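"""BF-control state machine, protocol levels and success-rate accounting."""

import copy

import numpy as np
import pytest

import bfrehab as bf
from bfrehab.control import (Checkpoint, ScriptedSubject, SessionLog,
                             TrialResult, level_trial_spec, run_checkpoint,
                             run_session, run_trial, success_rate,
                             weekly_summary)
from bfrehab.online import DecisionStream
from bfrehab.synth import ForceTrace, simulate_force_trace


def _decisions(trigger_at=None, horizon=10.0):
    times = 2.0 + 0.5 * np.arange(int(horizon / 0.5))
    raw = np.zeros(len(times))
    trig = np.zeros(len(times), dtype=bool)
    if trigger_at is not None:
        trig[times >= trigger_at] = True
        raw[times >= trigger_at] = 0.5
    return DecisionStream(times, raw, raw.copy(), trig, 0.1)


def _force(direction="extension", latency=2.0):
    return simulate_force_trace(direction, latency, noise_sd=0.0,
                                duration_s=12.0,
                                rng=np.random.default_rng(0))


def test_checkpoint_pass_latency_is_when_both_met():
    cp = Checkpoint("extension")
    res = run_checkpoint(cp, _decisions(trigger_at=3.0), _force(latency=4.0))
    assert res.passed
    assert res.latency_s == pytest.approx(4.0, abs=0.6)


def test_checkpoint_times_out_without_force():
    cp = Checkpoint("extension")
    res = run_checkpoint(cp, _decisions(trigger_at=3.0),
                         _force("flexion", latency=4.0))
    assert not res.passed and res.latency_s is None


def test_checkpoint_bci_only_mode():
    cp = Checkpoint("extension", bci_required=True, force_required=False)
    res = run_checkpoint(cp, _decisions(trigger_at=6.0), None)
    assert res.passed and res.latency_s == pytest.approx(6.0)


def test_checkpoint_late_trigger_times_out():
    cp = Checkpoint("extension", timeout_s=10.0)
    res = run_checkpoint(cp, _decisions(trigger_at=11.0, horizon=12.0),
                         _force(latency=2.0))
    assert not res.passed


def test_checkpoint_missing_required_stream_raises():
    with pytest.raises(ValueError, match="force"):
        run_checkpoint(Checkpoint("extension"), _decisions(3.0), None)
    with pytest.raises(ValueError, match="decision"):
        run_checkpoint(Checkpoint("extension"), None, _force())


def test_level_specs_checkpoint_counts():
    assert len(level_trial_spec("L1").checkpoints) == 2
    assert len(level_trial_spec("L2").checkpoints) == 2
    assert len(level_trial_spec("L3").checkpoints) == 4
    assert not level_trial_spec("warmup1").is_applicable
    with pytest.raises(ValueError):
        level_trial_spec("L4")


def test_l3_trial_with_timeout_records_all_outcomes():
    spec = level_trial_spec("L3")
    good = (_decisions(3.0), _force("extension", 2.0))
    good_flex = (_decisions(3.0), _force("flexion", 2.0))
    bad = (_decisions(None), _force("extension", 2.0))
    res = run_trial(spec, [good, good_flex, bad, good_flex])
    assert res.success is False
    assert res.passive_fallback_used
    assert len(res.checkpoint_outcomes) == 4
    assert res.checkpoint_outcomes[2] == "timeout"


def test_l3_fes_hold_and_warmup_autoff_timing():
    spec = level_trial_spec("L3")
    res = run_checkpoint(spec.checkpoints[0], _decisions(3.0),
                         _force("extension", 2.0))
    on, off = res.fes_events
    assert off[0] - on[0] == pytest.approx(3.0)  # wait, then release to hold
    w = level_trial_spec("warmup3")
    res2 = run_checkpoint(w.checkpoints[0], _decisions(3.0),
                          _force("extension", 2.0))
    on2, off2 = res2.fes_events
    assert off2[0] - on2[0] == pytest.approx(5.0)  # automatic switch-off


def test_warmup1_trials_not_applicable():
    spec = level_trial_spec("warmup1")
    res = run_trial(spec, [(None, None), (None, None)])
    assert res.success is None
    assert res.passive_fallback_used
    log = SessionLog([res] * 25, "warmup1", mode="passive")
    with pytest.raises(ValueError, match="applicable"):
        success_rate(log)


def _scripted_log(patterns, level="L3"):
    trials = []
    for pat in patterns:
        outcomes = ["pass" if p else "timeout" for p in pat]
        trials.append(TrialResult(outcomes, all(pat), not all(pat),
                                  [None] * len(pat), level))
    return SessionLog(trials, level)


def test_success_rate_enumerates_checkpoint_patterns():
    """All 2^3 outcome patterns of a 3-checkpoint trial: only TTT succeeds."""
    patterns = [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]
    log = _scripted_log(patterns)
    assert success_rate(log) == pytest.approx(1.0 / 8.0)


def test_success_rate_matches_brute_force_recount():
    rng = np.random.default_rng(17)
    patterns = [tuple(rng.random(2) < 0.6) for _ in range(57)]
    log = _scripted_log(patterns, level="L1")
    recount = sum(1 for p in patterns if all(p)) / len(patterns)
    assert success_rate(log) == pytest.approx(recount)


def test_success_rate_monotonicity():
    log = _scripted_log([(1, 1), (0, 1)], level="L1")
    base = success_rate(log)
    worse = copy.deepcopy(log)
    worse.trials.append(TrialResult(["timeout", "pass"], False, True,
                                    [None, None], "L1"))
    assert success_rate(worse) <= base
    better = copy.deepcopy(log)
    better.trials.append(TrialResult(["pass", "pass"], True, False,
                                     [None, None], "L1"))
    assert success_rate(better) >= base


def test_weekly_summary_mean_and_sd():
    mean, sd = weekly_summary([0.8, 0.9, 1.0])
    assert mean == pytest.approx(0.9)
    assert sd == pytest.approx(0.1)


def test_session_minimum_passive_repetitions():
    log = run_session("L1", 0, ScriptedSubject(), seed=0)
    assert log.delivered_repetitions == 10
    assert all(t.success is None for t in log.trials)


def test_session_determinism():
    subj = ScriptedSubject(0.7, 0.7)
    log1 = run_session("L1", 15, subj, seed=11)
    log2 = run_session("L1", 15, subj, seed=11)
    assert [t.success for t in log1.trials] == [t.success for t in log2.trials]


def test_l1_success_rate_matches_independence_closed_form():
    """With independent per-checkpoint BCI (p) and force (q) success, a
    two-checkpoint trial succeeds with probability (p*q)^2."""
    p, q = 0.8, 0.75
    subj = ScriptedSubject(p, q)
    n = 1500
    log = run_session("L1", n, subj, seed=23)
    rate = success_rate(log)
    expect = (p * q) ** 2
    se = np.sqrt(expect * (1 - expect) / n)
    assert abs(rate - expect) <= 3 * se


def test_bci_only_session_rate_reflects_p_only():
    p = 0.7
    subj = ScriptedSubject(p_bci=p, q_force=0.0)  # force never compliant
    log = run_session("warmup2", 1000, subj, seed=29)
    rate = success_rate(log)
    se = np.sqrt(p * p * (1 - p * p) / 1000)
    assert abs(rate - p * p) <= 3.5 * se
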
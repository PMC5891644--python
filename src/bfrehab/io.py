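"""Readers and writers for the package's on-disk formats.

Recordings travel as a plain numeric matrix (TSV, one row per sample, one
column per channel) with a JSON sidecar holding the sampling rate and
channel labels, or as EDF (read-only, via mne).  Cue schedules, decision
streams, feature matrices and summaries are CSV; models are JSON; session
logs are JSONL.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .online import DecisionStream
from .signal import Recording
from .synth import CueSchedule, ForceTrace


def save_recording(recording: Recording, prefix) -> tuple[Path, Path]:
    """Write ``<prefix>.tsv`` (time x channels) and ``<prefix>.json``."""
    prefix = Path(prefix)
    tsv = prefix.with_suffix(".tsv")
    meta = prefix.with_suffix(".json")
    np.savetxt(tsv, recording.samples.T, fmt="%.5f", delimiter="\t")
    sidecar = {"fs_hz": recording.fs_hz,
               "channel_labels": list(recording.channel_labels)}
    if recording.annotations:
        sidecar["annotations"] = [[float(t), str(l)]
                                  for t, l in recording.annotations]
    meta.write_text(json.dumps(sidecar, indent=2))
    return tsv, meta


def load_recording(path) -> Recording:
    """Load a recording from ``.tsv``/``.json`` pair or an ``.edf`` file."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _load_edf(path)
    prefix = path.with_suffix("")
    meta = json.loads(prefix.with_suffix(".json").read_text())
    samples = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t", ndmin=2).T
    annotations = [(float(t), str(l)) for t, l in meta.get("annotations", [])] or None
    return Recording(samples, float(meta["fs_hz"]),
                     list(meta["channel_labels"]), annotations)


def _load_edf(path: Path) -> Recording:
    import mne  # heavy import kept local

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    samples = raw.get_data() * 1e6  # volts -> microvolts
    annotations = [(float(o), str(d)) for o, d in
                   zip(raw.annotations.onset, raw.annotations.description)] or None
    return Recording(samples, float(raw.info["sfreq"]), list(raw.ch_names),
                     annotations)


def save_schedule(schedule: CueSchedule, path) -> None:
    pd.DataFrame({"onset_s": schedule.cue_onsets,
                  "label": schedule.cue_labels}).to_csv(path, index=False)


def load_schedule(path, cue_duration_s: float = 4.0) -> CueSchedule:
    df = pd.read_csv(path)
    return CueSchedule(df["onset_s"].to_numpy(), df["label"].to_numpy(),
                       cue_duration_s=cue_duration_s)


def save_features(X, labels, path) -> None:
    """Feature matrix as CSV: one row per epoch, plus a label column."""
    X = np.asarray(X)
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    df["label"] = np.asarray(labels)
    df.to_csv(path, index=False)


def load_features(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    labels = df.pop("label").to_numpy()
    return df.to_numpy(dtype=float), labels


def save_decisions(decisions: DecisionStream, path) -> None:
    pd.DataFrame({"t": decisions.times, "raw": decisions.raw_scores,
                  "smoothed": decisions.smoothed_scores,
                  "triggered": decisions.triggered}).to_csv(path, index=False)


def save_force_trace(trace: ForceTrace, path) -> None:
    pd.DataFrame({"t": trace.times, "force": trace.values}).to_csv(path,
                                                                   index=False)


def load_force_trace(path) -> ForceTrace:
    df = pd.read_csv(path)
    t = df["t"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    return ForceTrace(df["force"].to_numpy(), fs)
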
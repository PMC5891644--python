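"""Online decoding: 500-ms decision cadence, 8-point smoothing, threshold.

The streaming chain mirrors the acquisition front end: the raw stream is
causally band-pass filtered 1-45 Hz at its native rate, resampled to the
model's analysis rate, and scored once every 500 ms on the trailing 2-s
buffer.  Raw scores are smoothed with a moving average over the latest 8
decisions (undefined until 8 decisions exist); a decision triggers the
device when the smoothed score exceeds the activity threshold.

The threshold is calibrated from a 30-s eyes-open rest stream: nominally
0.1, raised to (max rest output + 0.02) whenever the classifier's rest
outputs exceed the nominal value, so that the calibration stream itself can
never trigger.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import BCIModel
from .signal import Recording, fir_bandpass, resample

DECISION_STEP_S = 0.5
SMOOTHING_WINDOW = 8
NOMINAL_THRESHOLD = 0.1
CALIBRATION_MARGIN = 0.02
HEADROOM_LIMIT = 0.98
ACQUISITION_BAND = (1.0, 45.0)


@dataclass
class DecisionStream:
    """Per-decision outputs of the online classifier."""

    times: np.ndarray
    raw_scores: np.ndarray
    smoothed_scores: np.ndarray  # NaN until SMOOTHING_WINDOW decisions exist
    triggered: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.raw_scores = np.asarray(self.raw_scores, dtype=float)
        self.smoothed_scores = np.asarray(self.smoothed_scores, dtype=float)
        self.triggered = np.asarray(self.triggered, dtype=bool)

    def __len__(self) -> int:
        return len(self.times)

    def first_trigger_time(self) -> float | None:
        idx = np.flatnonzero(self.triggered)
        return float(self.times[idx[0]]) if idx.size else None


@dataclass
class ThresholdCalibration:
    rest_outputs: np.ndarray
    max_rest: float
    threshold: float


def smooth_scores(raw: np.ndarray, window: int = SMOOTHING_WINDOW) -> np.ndarray:
    """Trailing moving average; NaN before ``window`` decisions exist."""
    raw = np.asarray(raw, dtype=float)
    out = np.full(len(raw), np.nan)
    if len(raw) >= window:
        kernel = np.ones(window) / window
        out[window - 1:] = np.convolve(raw, kernel, mode="valid")
    return out


def make_decision_stream(times, raw_scores, threshold: float,
                         window: int = SMOOTHING_WINDOW) -> DecisionStream:
    smoothed = smooth_scores(raw_scores, window)
    with np.errstate(invalid="ignore"):
        triggered = np.nan_to_num(smoothed, nan=-np.inf) > threshold
    return DecisionStream(times, raw_scores, smoothed, triggered, threshold)


def stream_classify(model: BCIModel, stream: Recording,
                    threshold: float | None = None,
                    acquisition_band: tuple = ACQUISITION_BAND,
                    step_s: float = DECISION_STEP_S) -> DecisionStream:
    """Score a continuous stream at the decision cadence.

    One raw score is produced per ``step_s`` on the trailing buffer of
    ``model.window_len_s`` seconds; no decision is emitted before a full
    buffer exists, so a stream of duration D yields
    floor((D - buffer) / step) + 1 decisions.
    """
    if threshold is None:
        threshold = (model.activity_threshold
                     if model.activity_threshold is not None
                     else NOMINAL_THRESHOLD)
    rec = fir_bandpass(stream, *acquisition_band, mode="causal")
    if rec.fs_hz > model.fs_hz:
        rec = resample(rec, model.fs_hz)
    fs = rec.fs_hz
    buf = int(round(model.window_len_s * fs))
    if rec.n_samples < buf:
        return make_decision_stream(np.empty(0), np.empty(0), threshold)
    n_dec = int(np.floor((rec.duration_s - model.window_len_s) / step_s)) + 1
    times = model.window_len_s + step_s * np.arange(n_dec)
    raw = np.empty(n_dec)
    for i, t in enumerate(times):
        i1 = int(round(t * fs))
        window = rec.samples[:, i1 - buf:i1]
        raw[i] = model.score_buffer(window, fs, rec.channel_labels)
    return make_decision_stream(times, raw, threshold)


def calibrate_threshold(model: BCIModel, rest: Recording,
                        nominal: float = NOMINAL_THRESHOLD,
                        margin: float = CALIBRATION_MARGIN) -> ThresholdCalibration:
    """Set the activity threshold from a rest stream.

    Requires enough rest signal for the buffer plus a full smoothing window.
    Raises when the rest outputs leave no headroom for imagery scores.
    """
    needed = model.window_len_s + (SMOOTHING_WINDOW - 1) * DECISION_STEP_S
    if rest.duration_s < needed:
        raise ValueError(
            f"rest stream must cover at least {needed:.1f} s "
            f"(buffer + {SMOOTHING_WINDOW} decisions), got {rest.duration_s:.1f} s")
    decisions = stream_classify(model, rest, threshold=np.inf)
    max_rest = float(decisions.raw_scores.max())
    threshold = threshold_from_max_rest(max_rest, nominal, margin)
    model.activity_threshold = threshold
    return ThresholdCalibration(decisions.raw_scores, max_rest, threshold)


def threshold_from_max_rest(max_rest: float, nominal: float = NOMINAL_THRESHOLD,
                            margin: float = CALIBRATION_MARGIN,
                            headroom: float = HEADROOM_LIMIT) -> float:
    """Nominal threshold, raised above the maximum rest output when needed."""
    if max_rest >= headroom:
        raise ValueError(
            f"max rest output {max_rest:.3f} leaves no headroom for imagery "
            f"scores; the model is unusable online")
    return max(nominal, max_rest + margin)
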
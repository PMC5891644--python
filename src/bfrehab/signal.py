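"""EEG containers and the offline/online signal chain.

The analysis chain mirrors a sensorimotor-rhythm BCI pipeline: continuous
multichannel EEG acquired at a high rate, resampled to 250 Hz, band-pass
filtered with a windowed-sinc FIR (6-35 Hz for offline feature extraction,
1-45 Hz causally for the acquisition front end), and cut into fixed-length
trial epochs at a configurable offset after each visual cue.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import signal as _sps


@dataclass
class Recording:
    """Continuous multichannel EEG (or any uniformly sampled signal block).

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs_hz : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique 10-20-style channel names (odd digit = left hemisphere,
        even = right, 'z' = midline).
    annotations : list of (onset_s, label), optional
        Event annotations.
    """

    samples: np.ndarray
    fs_hz: float
    channel_labels: list[str]
    annotations: list[tuple[float, str]] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels x time) matrix")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs_hz


@dataclass
class EpochSet:
    """Labelled trial windows cut from a recording.

    ``epochs`` has shape (n_trials, n_channels, n_samples); ``labels`` holds
    one of ``{"rest", "imagery"}`` per trial.
    """

    epochs: np.ndarray
    labels: np.ndarray
    fs_hz: float
    window_start_s: float
    window_len_s: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (trials x channels x samples)")
        if self.epochs.shape[0] != len(self.labels):
            raise ValueError("labels must match the number of trials")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    def __len__(self) -> int:
        return self.n_trials

    @staticmethod
    def concat(parts: Sequence["EpochSet"]) -> "EpochSet":
        """Stack epoch sets from several runs recorded under one montage."""
        if not parts:
            raise ValueError("nothing to concatenate")
        first = parts[0]
        for p in parts[1:]:
            if p.fs_hz != first.fs_hz or p.epochs.shape[1:] != first.epochs.shape[1:]:
                raise ValueError("incompatible epoch sets")
        return EpochSet(
            epochs=np.concatenate([p.epochs for p in parts], axis=0),
            labels=np.concatenate([p.labels for p in parts]),
            fs_hz=first.fs_hz,
            window_start_s=first.window_start_s,
            window_len_s=first.window_len_s,
            channel_labels=first.channel_labels,
        )


@lru_cache(maxsize=64)
def _cached_firwin(numtaps: int, low_hz: float, high_hz: float,
                   fs_hz: float) -> np.ndarray:
    return _sps.firwin(numtaps, [low_hz, high_hz], pass_zero=False,
                       fs=fs_hz, window="hamming")


def design_fir_bandpass(low_hz: float, high_hz: float, fs_hz: float,
                        numtaps: int | None = None) -> np.ndarray:
    """Design a Hamming-windowed sinc band-pass FIR.

    The default length is three periods of the low band edge (rounded to an
    odd tap count), which keeps the transition band narrow enough for >40 dB
    stop-band attenuation close to the design edges.
    """
    nyq = fs_hz / 2.0
    if not (0 < low_hz < high_hz):
        raise ValueError(f"band edges must satisfy 0 < low ({low_hz}) < high ({high_hz})")
    if high_hz >= nyq:
        raise ValueError(f"high edge {high_hz} Hz violates Nyquist ({nyq} Hz)")
    if numtaps is None:
        numtaps = int(round(3.0 * fs_hz / low_hz))
    if numtaps % 2 == 0:
        numtaps += 1
    return _cached_firwin(int(numtaps), float(low_hz), float(high_hz),
                          float(fs_hz))


def filter_array(x: np.ndarray, taps: np.ndarray, mode: str = "zero_phase",
                 axis: int = -1) -> np.ndarray:
    """Apply an FIR filter along ``axis``; zero-phase offline, causal online."""
    if mode == "zero_phase":
        padlen = min(3 * len(taps), x.shape[axis] - 1)
        return _sps.filtfilt(taps, [1.0], x, axis=axis, padlen=padlen)
    if mode == "causal":
        return _sps.lfilter(taps, [1.0], x, axis=axis)
    raise ValueError(f"unknown filter mode {mode!r}")


def fir_bandpass(recording: Recording, low_hz: float, high_hz: float,
                 order: int | None = None, mode: str = "zero_phase") -> Recording:
    """Band-pass filter a recording with a windowed-sinc FIR.

    ``mode='zero_phase'`` applies the filter forward-backward (offline
    analysis); ``mode='causal'`` applies it in one pass (streaming chain).
    """
    taps = design_fir_bandpass(low_hz, high_hz, recording.fs_hz, numtaps=order)
    out = filter_array(recording.samples, taps, mode=mode, axis=-1)
    return replace(recording, samples=out)


def resample(recording: Recording, target_fs_hz: float) -> Recording:
    """Polyphase anti-aliased downsampling; upsampling is refused."""
    if target_fs_hz > recording.fs_hz:
        raise ValueError(
            f"upsampling {recording.fs_hz} -> {target_fs_hz} Hz is not supported")
    if target_fs_hz == recording.fs_hz:
        return replace(recording, samples=recording.samples.copy())
    frac = Fraction(target_fs_hz / recording.fs_hz).limit_denominator(10_000)
    out = _sps.resample_poly(recording.samples, frac.numerator,
                             frac.denominator, axis=-1)
    return replace(recording, samples=out, fs_hz=target_fs_hz)


def extract_epochs(recording: Recording, schedule, window_start_s: float,
                   window_len_s: float = 2.0) -> EpochSet:
    """Cut one labelled epoch per cue at ``window_start_s`` after cue onset.

    ``schedule`` is any object exposing ``cue_onsets`` (seconds) and
    ``cue_labels``; the window is [onset + start, onset + start + len].
    """
    fs = recording.fs_hz
    n = int(round(window_len_s * fs))
    onsets = np.asarray(schedule.cue_onsets, dtype=float)
    labels = np.asarray(schedule.cue_labels)
    if onsets.size == 0:
        return EpochSet(np.empty((0, recording.n_channels, n)), labels, fs,
                        window_start_s, window_len_s, recording.channel_labels)
    out = np.empty((len(onsets), recording.n_channels, n))
    for i, onset in enumerate(onsets):
        i0 = int(round((onset + window_start_s) * fs))
        if i0 < 0 or i0 + n > recording.n_samples:
            raise ValueError(
                f"epoch window for cue {i} (onset {onset:.2f} s) falls outside "
                f"the recording")
        out[i] = recording.samples[:, i0:i0 + n]
    return EpochSet(out, labels, fs, window_start_s, window_len_s,
                    recording.channel_labels)
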
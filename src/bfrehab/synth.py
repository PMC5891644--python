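"""Synthetic EEG, rest streams and force traces.

The generator emulates the statistical structure a sensorimotor-rhythm BCI
pipeline assumes: band-limited mu (~10 Hz) and beta (~20 Hz) oscillations
shared across a 10-20 montage over a 1/f Gaussian background, with
event-related desynchronization (ERD) modelled as multiplicative amplitude
attenuation of the rhythm on a subset of (contralateral) channels during
imagery cues.  Cue schedules follow the stimulus-presentation protocol:
4-s cues, randomized 4-6-s inter-cue intervals, balanced rest/imagery labels
within each run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal import Recording

REST = "rest"
IMAGERY = "imagery"

DEFAULT_CHANNELS = ["F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2"]


@dataclass
class ERDSimConfig:
    """Parameters of the generative EEG model.

    Amplitudes are in microvolts; ``erd_depth`` is the fractional amplitude
    attenuation of the rhythm during imagery (band power is attenuated by
    (1 - erd_depth)^2 on ``erd_channels``).
    """

    n_channels: int = 8
    fs_hz: float = 1000.0
    mu_hz: float = 10.0
    beta_hz: float = 20.0
    erd_depth: float = 0.4
    noise_exponent: float = 1.0
    erd_channels: tuple[str, ...] = ("C3",)
    seed: int = 0
    channel_labels: tuple[str, ...] = ()
    mu_amp: float = 12.0
    beta_amp: float = 6.0
    noise_rms: float = 3.0
    amp_mod_depth: float = 0.15
    cue_duration_s: float = 4.0
    interval_range_s: tuple[float, float] = (4.0, 6.0)

    def __post_init__(self) -> None:
        if not self.channel_labels:
            if self.n_channels <= len(DEFAULT_CHANNELS):
                self.channel_labels = tuple(DEFAULT_CHANNELS[: self.n_channels])
            else:
                extra = [f"EEG{i}" for i in range(self.n_channels - len(DEFAULT_CHANNELS))]
                self.channel_labels = tuple(DEFAULT_CHANNELS + extra)
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels must match n_channels")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        unknown = set(self.erd_channels) - set(self.channel_labels)
        if unknown:
            raise ValueError(f"erd_channels not on the montage: {sorted(unknown)}")
        if self.fs_hz <= 2 * self.beta_hz:
            raise ValueError("fs_hz must exceed twice the beta frequency")


@dataclass
class CueSchedule:
    """Timed, labelled stimulus-presentation cues."""

    cue_onsets: np.ndarray
    cue_labels: np.ndarray
    cue_duration_s: float = 4.0
    inter_cue_interval_s: tuple[float, float] = (4.0, 6.0)

    def __post_init__(self) -> None:
        self.cue_onsets = np.asarray(self.cue_onsets, dtype=float)
        self.cue_labels = np.asarray(self.cue_labels)
        if np.any(np.diff(self.cue_onsets) <= 0):
            raise ValueError("cue onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.cue_onsets)


@dataclass
class ForceTrace:
    """1-D signed force-sensor trace (abstract units, extension positive)."""

    values: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fs_hz

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.fs_hz


def one_over_f_noise(rng: np.random.Generator, n_samples: int, fs_hz: float,
                     exponent: float, rms: float) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit-free RMS."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs_hz)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n_samples)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _slow_envelope(rng: np.random.Generator, n_samples: int, fs_hz: float,
                   depth: float) -> np.ndarray:
    """Slowly varying positive amplitude envelope (knots every 2 s)."""
    if depth <= 0:
        return np.ones(n_samples)
    n_knots = max(int(np.ceil(n_samples / fs_hz / 2.0)) + 2, 4)
    knots = 1.0 + depth * rng.standard_normal(n_knots)
    t = np.arange(n_samples) / fs_hz
    env = np.interp(t, np.linspace(0, t[-1] if n_samples > 1 else 1.0, n_knots), knots)
    return np.clip(env, 0.1, None)


def make_cue_schedule(n_cues: int, rng: np.random.Generator,
                      cue_duration_s: float = 4.0,
                      interval_range_s: tuple[float, float] = (4.0, 6.0),
                      lead_in_s: float = 5.0) -> CueSchedule:
    """Balanced shuffled rest/imagery cues with randomized intervals."""
    if n_cues % 2 != 0:
        raise ValueError(
            f"n_cues must be even for a balanced rest/imagery design, got {n_cues}")
    labels = np.array([REST, IMAGERY] * (n_cues // 2))
    rng.shuffle(labels)
    gaps = rng.uniform(*interval_range_s, size=n_cues)
    onsets = np.empty(n_cues)
    t = lead_in_s
    for i in range(n_cues):
        onsets[i] = t
        t += cue_duration_s + gaps[i]
    return CueSchedule(onsets, labels, cue_duration_s, interval_range_s)


def _render_eeg(config: ERDSimConfig, n_samples: int, rng: np.random.Generator,
                imagery_windows: list[tuple[float, float]]) -> np.ndarray:
    """Mix rhythm sources and 1/f noise into channels.

    The forward model is deliberately simple: one mu and one beta source
    project with unit gain to every channel; channels in ``erd_channels``
    additionally see their rhythm amplitude multiplied by (1 - erd_depth)
    inside imagery windows.
    """
    fs = config.fs_hz
    t = np.arange(n_samples) / fs
    gate = np.ones(n_samples)
    for t0, t1 in imagery_windows:
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        gate[i0:i1] = 1.0 - config.erd_depth

    def band_source(f_hz: float, amp: float) -> np.ndarray:
        phase = rng.uniform(0, 2 * np.pi)
        env = _slow_envelope(rng, n_samples, fs, config.amp_mod_depth)
        return amp * env * np.sin(2 * np.pi * f_hz * t + phase)

    rhythm = band_source(config.mu_hz, config.mu_amp) \
        + band_source(config.beta_hz, config.beta_amp)

    erd = set(config.erd_channels)
    samples = np.empty((config.n_channels, n_samples))
    for c, label in enumerate(config.channel_labels):
        noise = one_over_f_noise(rng, n_samples, fs, config.noise_exponent,
                                 config.noise_rms)
        g = gate if label in erd else 1.0
        samples[c] = rhythm * g + noise
    return samples


def simulate_run(config: ERDSimConfig, n_cues: int = 20,
                 rng: np.random.Generator | None = None
                 ) -> tuple[Recording, CueSchedule]:
    """One stimulus-presentation run of ``n_cues`` balanced cues.

    During imagery cues, band-limited power at the mu/beta frequencies on
    ``erd_channels`` is attenuated by (1 - erd_depth)^2.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    schedule = make_cue_schedule(n_cues, rng, config.cue_duration_s,
                                 config.interval_range_s)
    final_gap = rng.uniform(*config.interval_range_s)
    duration = schedule.cue_onsets[-1] + config.cue_duration_s + final_gap
    n_samples = int(round(duration * config.fs_hz))
    imagery_windows = [
        (onset, onset + config.cue_duration_s)
        for onset, label in zip(schedule.cue_onsets, schedule.cue_labels)
        if label == IMAGERY
    ]
    samples = _render_eeg(config, n_samples, rng, imagery_windows)
    annotations = [(float(o), str(l)) for o, l in
                   zip(schedule.cue_onsets, schedule.cue_labels)]
    rec = Recording(samples, config.fs_hz, list(config.channel_labels),
                    annotations=annotations)
    return rec, schedule


def simulate_session(config: ERDSimConfig, n_runs: int = 5, n_cues: int = 20
                     ) -> list[tuple[Recording, CueSchedule]]:
    """Several independent runs from one master seed (the acquisition day)."""
    master = np.random.default_rng(config.seed)
    out = []
    for _ in range(n_runs):
        child = np.random.default_rng(master.integers(2**31))
        out.append(simulate_run(config, n_cues, rng=child))
    return out


def simulate_rest_stream(config: ERDSimConfig, duration_s: float = 30.0,
                         rng: np.random.Generator | None = None) -> Recording:
    """Stationary eyes-open rest stream (no ERD events) for calibration."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_samples = int(round(duration_s * config.fs_hz))
    samples = _render_eeg(config, n_samples, rng, imagery_windows=[])
    return Recording(samples, config.fs_hz, list(config.channel_labels))


def simulate_imagery_stream(config: ERDSimConfig, duration_s: float,
                            rng: np.random.Generator | None = None,
                            active_from_s: float = 0.0) -> Recording:
    """Continuous stream with sustained imagery (ERD on) from a given time.

    Used to drive the online decoder during simulated training trials.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_samples = int(round(duration_s * config.fs_hz))
    windows = [(active_from_s, duration_s)]
    samples = _render_eeg(config, n_samples, rng, imagery_windows=windows)
    return Recording(samples, config.fs_hz, list(config.channel_labels))


def simulate_force_trace(direction: str, latency_s: float, noise_sd: float = 0.02,
                         duration_s: float = 10.0, fs_hz: float = 100.0,
                         peak: float = 1.0, rise_s: float = 1.0,
                         rng: np.random.Generator | None = None) -> ForceTrace:
    """Signed force trace ramping in ``direction`` after ``latency_s``.

    Extension is positive, flexion negative.  Before the latency the trace
    is zero-mean noise; afterwards it ramps linearly to ``peak`` over
    ``rise_s`` and holds.  A latency beyond ``duration_s`` yields pure noise
    (the subject never moved within the observed window).
    """
    if direction not in ("extension", "flexion"):
        raise ValueError(f"unknown direction {direction!r}")
    if rng is None:
        rng = np.random.default_rng(0)
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    sign = 1.0 if direction == "extension" else -1.0
    ramp = np.clip((t - latency_s) / rise_s, 0.0, 1.0) * peak * sign
    values = ramp + noise_sd * rng.standard_normal(n)
    return ForceTrace(values, fs_hz)
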
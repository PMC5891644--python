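"""Brain Symmetry Index (BSI) over T-second epochs.

For an epoch [t-T, t], let a_n^2(ch) be the squared magnitude of the n-th
Fourier coefficient of channel ch on the discrete frequency grid (resolution
1/T) restricted to a frequency band.  With hemisphere-averaged powers
R_n = mean over right channels of a_n^2 and L_n likewise for the left,

    BSI = (1/k) * sum_n | (R_n - L_n) / (R_n + L_n) |,

a value in [0, 1]: 0 for perfectly symmetric hemispheres, 1 for power
confined to one side.  Frequencies where R_n + L_n = 0 are skipped and k
reduced accordingly.  The default band is 6-32 Hz (the feature band of the
decoder); a classical 1-25 Hz preset is also provided.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .signal import Recording

DEFAULT_BAND = (6.0, 32.0)
VAN_PUTTEN_BAND = (1.0, 25.0)
DEFAULT_T = 4.0


@dataclass
class SpectralEpoch:
    """Per-channel spectral power on k grid frequencies for one epoch."""

    coeffs: np.ndarray  # (n_channels, k) squared Fourier magnitudes
    freqs_hz: np.ndarray
    channel_labels: list[str]
    t: float
    T: float

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if np.any(self.coeffs < 0):
            raise ValueError("spectral powers must be non-negative")

    @property
    def k(self) -> int:
        return self.coeffs.shape[1]


@dataclass
class HemisphereMap:
    """Equal-sized, disjoint left/right channel sets (midline excluded)."""

    left_channels: list[str]
    right_channels: list[str]

    def __post_init__(self) -> None:
        if len(self.left_channels) != len(self.right_channels):
            raise ValueError("hemisphere sets must have equal size")
        if not self.left_channels:
            raise ValueError("empty hemisphere set")
        if set(self.left_channels) & set(self.right_channels):
            raise ValueError("hemisphere sets must be disjoint")

    @property
    def m(self) -> int:
        return len(self.left_channels)


_LABEL_RE = re.compile(r"^([A-Za-z]+?)(\d+)$")


def default_hemisphere_map(channel_labels) -> HemisphereMap:
    """Pair homologous channels by 10-20 label parity (odd left, even right).

    A left channel with site number n is paired with the same site at n+1
    (C3 with C4, F3 with F4, ...); midline ('z') and unpaired channels are
    dropped.
    """
    by_label = set(channel_labels)
    left, right = [], []
    for lab in channel_labels:
        m = _LABEL_RE.match(lab)
        if not m:
            continue
        base, num = m.group(1), int(m.group(2))
        if num % 2 == 1:
            homolog = f"{base}{num + 1}"
            if homolog in by_label:
                left.append(lab)
                right.append(homolog)
    if not left:
        raise ValueError("no homologous left/right channel pairs on montage")
    return HemisphereMap(left, right)


def spectral_epoch(recording: Recording, t: float, T: float = DEFAULT_T,
                   band_hz: tuple = DEFAULT_BAND) -> SpectralEpoch:
    """Squared Fourier coefficient magnitudes of the window [t-T, t]."""
    fs = recording.fs_hz
    i1 = int(round(t * fs))
    i0 = i1 - int(round(T * fs))
    if i0 < 0 or i1 > recording.n_samples:
        raise ValueError(f"epoch [{t - T:.2f}, {t:.2f}] s outside the recording")
    seg = recording.samples[:, i0:i1]
    coeffs = np.abs(np.fft.rfft(seg, axis=-1)) ** 2
    freqs = np.fft.rfftfreq(seg.shape[1], 1.0 / fs)
    eps = 1e-9
    sel = (freqs >= band_hz[0] - eps) & (freqs <= band_hz[1] + eps)
    if not np.any(sel):
        raise ValueError(f"no grid frequencies inside band {band_hz}")
    return SpectralEpoch(coeffs[:, sel], freqs[sel],
                         list(recording.channel_labels), t, T)


def compute_bsi(epoch: SpectralEpoch, hmap: HemisphereMap) -> float:
    """Evaluate the symmetry index of one spectral epoch."""
    idx = {lab: i for i, lab in enumerate(epoch.channel_labels)}
    missing = [c for c in hmap.left_channels + hmap.right_channels
               if c not in idx]
    if missing:
        raise ValueError(f"mapped channels absent from epoch: {missing}")
    li = [idx[c] for c in hmap.left_channels]
    ri = [idx[c] for c in hmap.right_channels]
    L = epoch.coeffs[li].mean(axis=0)
    R = epoch.coeffs[ri].mean(axis=0)
    total = R + L
    keep = total > 0
    if not np.any(keep):
        raise ValueError("all frequency bins have zero power")
    return float(np.mean(np.abs((R[keep] - L[keep]) / total[keep])))


def bsi_series(recording: Recording, hmap: HemisphereMap, state_epochs,
               T: float = DEFAULT_T, band_hz: tuple = DEFAULT_BAND) -> dict:
    """Mean BSI per state over a list of (epoch end time, state) pairs."""
    values: dict[str, list[float]] = {}
    for t, state in state_epochs:
        ep = spectral_epoch(recording, float(t), T, band_hz)
        values.setdefault(str(state), []).append(compute_bsi(ep, hmap))
    return {state: float(np.mean(v)) for state, v in values.items()}
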
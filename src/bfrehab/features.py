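"""Feature extraction: band power (BP), CSP and filter-bank CSP (FBCSP).

CSP follows the classical two-class formulation: per-epoch trace-normalized
covariance matrices are averaged within class, and spatial filters are the
generalized eigenvectors of (C_imagery, C_imagery + C_rest).  Filters are
taken in pairs from both ends of the eigen-spectrum; the eigenvalue of a
filter is the fraction of composite variance captured for the imagery class,
so the two class-wise eigenvalues of any filter sum to one.

The filter bank applies CSP independently inside 6-15, 15-25 and 25-32 Hz
and concatenates the per-band log-variance features (3 bands x 6 filters =
18 dimensions).  Band power uses 17 equal-width sub-bands spanning 6-32 Hz,
channel-averaged, log-transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as _sla

from .signal import EpochSet, design_fir_bandpass, filter_array

BP_BAND = (6.0, 32.0)
CSP_BAND = (6.0, 32.0)
FBCSP_BANDS = ((6.0, 15.0), (15.0, 25.0), (25.0, 32.0))
BP_DIM = 17
CSP_DIM = 6


@dataclass
class SpatialFilterModel:
    """Fitted CSP projection.

    ``filters`` rows are spatial filters (n_filters x channels); the first
    half maximizes imagery-class variance, the second half rest-class
    variance.  ``eigenvalues`` are the imagery-class generalized eigenvalues
    of each filter (in [0, 1]).
    """

    filters: np.ndarray
    eigenvalues: np.ndarray
    band_hz: tuple[float, float] = CSP_BAND
    class_order: tuple[str, str] = ("imagery", "rest")

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]

    @property
    def n_channels(self) -> int:
        return self.filters.shape[1]


@dataclass
class FeatureSpec:
    """Which extractor a model candidate uses, and its settings."""

    kind: str  # "BP" | "CSP" | "FBCSP"
    band_hz: tuple = CSP_BAND
    n_filters: int = CSP_DIM
    n_bins: int = BP_DIM
    bands_hz: tuple = FBCSP_BANDS

    @property
    def dim(self) -> int:
        if self.kind == "BP":
            return self.n_bins
        if self.kind == "CSP":
            return self.n_filters
        if self.kind == "FBCSP":
            return len(self.bands_hz) * self.n_filters
        raise ValueError(f"unknown feature kind {self.kind!r}")


def epoch_covariances(epochs: np.ndarray) -> np.ndarray:
    """Per-epoch trace-normalized spatial covariances, shape (n, ch, ch)."""
    x = epochs - epochs.mean(axis=-1, keepdims=True)
    covs = np.einsum("ncs,nds->ncd", x, x)
    traces = np.trace(covs, axis1=1, axis2=2)
    if np.any(traces <= 0):
        raise ValueError("epoch with zero variance: covariance undefined")
    return covs / traces[:, None, None]


def csp_from_covariances(covs: np.ndarray, labels: np.ndarray,
                         n_filters: int = CSP_DIM,
                         reg: float = 1e-8) -> SpatialFilterModel:
    """Fit CSP from precomputed per-epoch covariances."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"CSP needs exactly two classes, got {list(classes)}")
    pos = "imagery" if "imagery" in classes else classes[0]
    neg = [c for c in classes if c != pos][0]
    c1 = covs[labels == pos].mean(axis=0)
    c2 = covs[labels == neg].mean(axis=0)
    comp = c1 + c2
    n_ch = comp.shape[0]
    lam = reg * np.trace(comp) / n_ch
    comp_r = comp + lam * np.eye(n_ch)
    if np.linalg.matrix_rank(comp) < n_ch:
        warnings.warn("rank-deficient composite covariance; regularized",
                      RuntimeWarning)
    evals, evecs = _sla.eigh(c1, comp_r)  # ascending imagery-class eigenvalues
    order = np.argsort(evals)
    evals, evecs = evals[order], evecs[:, order]
    half = n_filters // 2
    if 2 * half != n_filters:
        raise ValueError("n_filters must be even (filters are taken in pairs)")
    top = evecs[:, ::-1][:, :half].T        # maximize imagery variance
    bottom = evecs[:, :half].T              # maximize rest variance
    filters = np.vstack([top, bottom])
    eigenvalues = np.concatenate([evals[::-1][:half], evals[:half]])
    return SpatialFilterModel(filters=filters, eigenvalues=eigenvalues,
                              class_order=(str(pos), str(neg)))


def fit_csp(train: EpochSet, n_filters: int = CSP_DIM,
            reg: float = 1e-8) -> SpatialFilterModel:
    """Fit CSP on (already band-filtered) training epochs."""
    covs = epoch_covariances(train.epochs)
    model = csp_from_covariances(covs, train.labels, n_filters, reg)
    return model


def csp_features(model: SpatialFilterModel, epochs: EpochSet) -> np.ndarray:
    """Log of normalized variance of each spatially filtered signal."""
    if epochs.n_channels != model.n_channels:
        raise ValueError(
            f"model expects {model.n_channels} channels, got {epochs.n_channels}")
    return csp_features_from_covariances(model, epoch_covariances(epochs.epochs))


def csp_features_from_covariances(model: SpatialFilterModel,
                                  covs: np.ndarray) -> np.ndarray:
    w = model.filters
    var = np.einsum("fc,ncd,fd->nf", w, covs, w)
    var = np.maximum(var, 0.0)
    total = var.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("epoch with zero projected variance")
    return np.log(var / total + 1e-300)


def fit_fbcsp(train: EpochSet, bands: tuple = FBCSP_BANDS,
              n_filters_per_band: int = CSP_DIM) -> list[SpatialFilterModel]:
    """One CSP model per band-filtered copy of the training epochs."""
    if len(bands) < 1:
        raise ValueError("at least one band required")
    models = []
    for band in bands:
        taps = design_fir_bandpass(band[0], band[1], train.fs_hz)
        filtered = filter_array(train.epochs, taps, mode="zero_phase", axis=-1)
        covs = epoch_covariances(filtered)
        m = csp_from_covariances(covs, train.labels, n_filters_per_band)
        m.band_hz = tuple(band)
        models.append(m)
    return models


def fbcsp_features(models: list[SpatialFilterModel], epochs: EpochSet) -> np.ndarray:
    """Concatenated per-band CSP features (bands x n_filters columns)."""
    blocks = []
    for m in models:
        taps = design_fir_bandpass(m.band_hz[0], m.band_hz[1], epochs.fs_hz)
        filtered = filter_array(epochs.epochs, taps, mode="zero_phase", axis=-1)
        blocks.append(csp_features_from_covariances(m, epoch_covariances(filtered)))
    return np.hstack(blocks)


def bandpower_features(epochs: EpochSet, band_hz: tuple = BP_BAND,
                       n_bins: int = BP_DIM,
                       channels: list[int] | None = None) -> np.ndarray:
    """Channel-averaged log power in equal-width sub-bands of ``band_hz``."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    fs = epochs.fs_hz
    if band_hz[1] >= fs / 2:
        raise ValueError(f"band {band_hz} exceeds Nyquist ({fs / 2} Hz)")
    x = epochs.epochs if channels is None else epochs.epochs[:, channels, :]
    x = x - x.mean(axis=-1, keepdims=True)
    n = x.shape[-1]
    psd = np.abs(np.fft.rfft(x, axis=-1)) ** 2 / n
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    edges = np.linspace(band_hz[0], band_hz[1], n_bins + 1)
    feats = np.empty((x.shape[0], n_bins))
    for b in range(n_bins):
        sel = (freqs >= edges[b]) & (freqs < edges[b + 1])
        if b == n_bins - 1:
            sel = (freqs >= edges[b]) & (freqs <= edges[b + 1])
        if not np.any(sel):
            raise ValueError("sub-band without any frequency grid point; "
                             "epoch too short for this resolution")
        feats[:, b] = np.log(psd[:, :, sel].mean(axis=(1, 2)) + 1e-300)
    return feats


# --- extractor objects used by the model-search machinery -------------------

class BaseExtractor:
    spec: FeatureSpec

    def fit(self, epochs: EpochSet) -> "BaseExtractor":
        raise NotImplementedError

    def transform(self, epochs: EpochSet) -> np.ndarray:
        raise NotImplementedError


class BandPowerExtractor(BaseExtractor):
    """Stateless band-power features (no training step)."""

    def __init__(self, band_hz: tuple = BP_BAND, n_bins: int = BP_DIM):
        self.spec = FeatureSpec("BP", band_hz=tuple(band_hz), n_bins=n_bins)

    def fit(self, epochs: EpochSet) -> "BandPowerExtractor":
        return self

    def transform(self, epochs: EpochSet) -> np.ndarray:
        return bandpower_features(epochs, self.spec.band_hz, self.spec.n_bins)


class CSPExtractor(BaseExtractor):
    """Band-filtered CSP with log-variance features."""

    def __init__(self, band_hz: tuple = CSP_BAND, n_filters: int = CSP_DIM):
        self.spec = FeatureSpec("CSP", band_hz=tuple(band_hz), n_filters=n_filters)
        self.model: SpatialFilterModel | None = None

    def _filtered(self, epochs: EpochSet) -> np.ndarray:
        taps = design_fir_bandpass(*self.spec.band_hz, epochs.fs_hz)
        return filter_array(epochs.epochs, taps, mode="zero_phase", axis=-1)

    def fit(self, epochs: EpochSet) -> "CSPExtractor":
        covs = epoch_covariances(self._filtered(epochs))
        self.model = csp_from_covariances(covs, epochs.labels, self.spec.n_filters)
        self.model.band_hz = self.spec.band_hz
        return self

    def transform(self, epochs: EpochSet) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("extractor not fitted")
        covs = epoch_covariances(self._filtered(epochs))
        return csp_features_from_covariances(self.model, covs)


class FBCSPExtractor(BaseExtractor):
    """Filter-bank CSP: per-band CSP features concatenated."""

    def __init__(self, bands_hz: tuple = FBCSP_BANDS, n_filters: int = CSP_DIM):
        self.spec = FeatureSpec("FBCSP", bands_hz=tuple(tuple(b) for b in bands_hz),
                                n_filters=n_filters)
        self.models: list[SpatialFilterModel] | None = None

    def fit(self, epochs: EpochSet) -> "FBCSPExtractor":
        self.models = fit_fbcsp(epochs, self.spec.bands_hz, self.spec.n_filters)
        return self

    def transform(self, epochs: EpochSet) -> np.ndarray:
        if self.models is None:
            raise RuntimeError("extractor not fitted")
        return fbcsp_features(self.models, epochs)


def make_extractor(spec: FeatureSpec) -> BaseExtractor:
    if spec.kind == "BP":
        return BandPowerExtractor(spec.band_hz, spec.n_bins)
    if spec.kind == "CSP":
        return CSPExtractor(spec.band_hz, spec.n_filters)
    if spec.kind == "FBCSP":
        return FBCSPExtractor(spec.bands_hz, spec.n_filters)
    raise ValueError(f"unknown feature kind {spec.kind!r}")
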
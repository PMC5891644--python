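"""CSP, filter-bank CSP and band-power extractors."""

import numpy as np
import pytest
from scipy import linalg

import bfrehab as bf
from bfrehab.features import (CSP_DIM, FBCSP_BANDS, bandpower_features,
                              csp_features, epoch_covariances, fbcsp_features,
                              fit_csp, fit_fbcsp)
from bfrehab.signal import EpochSet


def _epochset(epochs, labels, fs=250.0, chans=None):
    epochs = np.asarray(epochs, float)
    chans = chans or [f"C{i}" for i in range(epochs.shape[1])]
    return EpochSet(epochs, np.asarray(labels), fs, 0.5, epochs.shape[-1] / fs,
                    chans)


def _latent_dataset(rng, n=200, n_ch=4, n_s=200, var_ratio=6.0):
    """Two classes differing only in the variance of one latent source."""
    A = rng.standard_normal((n_ch, n_ch)) + np.eye(n_ch)
    epochs = np.empty((n, n_ch, n_s))
    labels = np.array(["imagery", "rest"] * (n // 2))
    for i, lab in enumerate(labels):
        s = rng.standard_normal((n_ch, n_s))
        if lab == "imagery":
            s[0] *= np.sqrt(var_ratio)
        epochs[i] = A @ s
    return epochs, labels, A


def test_csp_recovers_latent_unmixing_direction():
    rng = np.random.default_rng(7)
    epochs, labels, A = _latent_dataset(rng)
    model = fit_csp(_epochset(epochs, labels), n_filters=2)
    w = model.filters[0]
    true_dir = np.linalg.inv(A)[0]  # unmixing row of the modulated source
    c = abs(np.dot(w, true_dir) / (np.linalg.norm(w) * np.linalg.norm(true_dir)))
    assert c >= 0.95


def test_csp_eigenvalues_near_half_without_structure():
    rng = np.random.default_rng(8)
    epochs = rng.standard_normal((500, 3, 100))
    labels = np.array(["imagery", "rest"] * 250)
    model = fit_csp(_epochset(epochs, labels), n_filters=2)
    assert np.all(np.abs(model.eigenvalues - 0.5) < 0.05)


def test_csp_single_class_rejected():
    rng = np.random.default_rng(0)
    eps = _epochset(rng.standard_normal((10, 3, 50)), ["rest"] * 10)
    with pytest.raises(ValueError, match="two classes"):
        fit_csp(eps)


def test_csp_matches_generalized_eigenproblem_oracle():
    """On small problems the filters span the same subspaces as a direct
    whitening-based solution of the generalized eigenproblem."""
    rng = np.random.default_rng(9)
    epochs, labels, _ = _latent_dataset(rng, n=100, n_ch=4)
    eps = _epochset(epochs, labels)
    model = fit_csp(eps, n_filters=4)

    covs = epoch_covariances(eps.epochs)
    c1 = covs[eps.labels == "imagery"].mean(axis=0)
    c2 = covs[eps.labels == "rest"].mean(axis=0)
    # independent route: whiten the (identically ridged) composite, then
    # eigendecompose the whitened imagery covariance
    comp = c1 + c2
    comp = comp + 1e-8 * np.trace(comp) / comp.shape[0] * np.eye(comp.shape[0])
    evals_w, U = np.linalg.eigh(comp)
    P = U @ np.diag(evals_w ** -0.5) @ U.T
    lam, V = np.linalg.eigh(P @ c1 @ P)
    W = (P @ V).T  # rows = filters, ascending imagery eigenvalue
    top_oracle = W[::-1][:2]
    bottom_oracle = W[:2]
    ang_top = linalg.subspace_angles(model.filters[:2].T, top_oracle.T).max()
    ang_bot = linalg.subspace_angles(model.filters[2:].T, bottom_oracle.T).max()
    assert ang_top < 1e-6
    assert ang_bot < 1e-6


def test_csp_classwise_eigenvalue_pairs_sum_to_one():
    rng = np.random.default_rng(10)
    epochs, labels, _ = _latent_dataset(rng, n=80, n_ch=4)
    eps = _epochset(epochs, labels)
    model = fit_csp(eps, n_filters=4)
    covs = epoch_covariances(eps.epochs)
    c1 = covs[eps.labels == "imagery"].mean(axis=0)
    c2 = covs[eps.labels == "rest"].mean(axis=0)
    comp = c1 + c2
    for i, w in enumerate(model.filters):
        lam1 = w @ c1 @ w / (w @ comp @ w)
        lam2 = w @ c2 @ w / (w @ comp @ w)
        assert abs(lam1 + lam2 - 1.0) < 1e-9
        # stored eigenvalues are taken w.r.t. the ridged composite
        assert abs(lam1 - model.eigenvalues[i]) < 1e-4


def test_csp_feature_dim_and_scale_invariance():
    rng = np.random.default_rng(11)
    epochs, labels, _ = _latent_dataset(rng, n=60, n_ch=6)
    eps = _epochset(epochs, labels)
    model = fit_csp(eps, n_filters=6)
    X = csp_features(model, eps)
    assert X.shape == (60, 6)
    scaled = _epochset(epochs * 3.7, labels)
    np.testing.assert_allclose(csp_features(model, scaled), X, atol=1e-9)


def test_csp_zero_epoch_rejected():
    rng = np.random.default_rng(12)
    epochs, labels, _ = _latent_dataset(rng, n=20, n_ch=3)
    model = fit_csp(_epochset(epochs, labels), n_filters=2)
    zeros = _epochset(np.zeros((1, 3, 200)), ["rest"])
    with pytest.raises(ValueError):
        csp_features(model, zeros)


def test_fbcsp_dimensions_and_single_band_reduction(epochs_strong):
    models = fit_fbcsp(epochs_strong, FBCSP_BANDS, 6)
    X = fbcsp_features(models, epochs_strong)
    assert X.shape[1] == 18
    single = fit_fbcsp(epochs_strong, ((6.0, 32.0),), 6)
    Xs = fbcsp_features(single, epochs_strong)
    from bfrehab.features import CSPExtractor
    ex = CSPExtractor((6.0, 32.0), 6).fit(epochs_strong)
    np.testing.assert_allclose(Xs, ex.transform(epochs_strong), atol=1e-8)


def test_fbcsp_band_with_injected_rhythm_is_most_discriminative():
    """ERD injected at 10 Hz separates the 6-15 Hz band, not 25-32 Hz."""
    cfg = bf.ERDSimConfig(fs_hz=250.0, erd_depth=0.7, erd_channels=("C3",),
                          beta_amp=0.0, seed=31)
    rec, sched = bf.simulate_run(cfg, 20)
    from bfrehab.signal import extract_epochs
    eps = extract_epochs(rec, sched, 0.5, 2.0)
    models = fit_fbcsp(eps, FBCSP_BANDS, 4)
    spreads = [np.abs(m.eigenvalues - 0.5).max() for m in models]
    assert spreads[0] > spreads[2]


def test_bandpower_dim_and_flat_spectrum():
    rng = np.random.default_rng(13)
    eps = _epochset(rng.standard_normal((100, 2, 500)), ["rest"] * 100)
    X = bandpower_features(eps)
    assert X.shape == (100, 17)
    mean_per_bin = np.exp(X).mean(axis=0)
    cv = mean_per_bin.std() / mean_per_bin.mean()
    assert cv < 0.1


def test_bandpower_peak_bin_contains_tone():
    fs = 250.0
    t = np.arange(500) / fs
    tone = np.sin(2 * np.pi * 10.0 * t)
    eps = _epochset(np.tile(tone, (5, 2, 1)), ["rest"] * 5, fs=fs)
    X = bandpower_features(eps)
    edges = np.linspace(6.0, 32.0, 18)
    expected_bin = int(np.searchsorted(edges, 10.0) - 1)
    assert np.all(np.argmax(X, axis=1) == expected_bin)


def test_bandpower_band_outside_nyquist_rejected():
    eps = _epochset(np.random.default_rng(0).standard_normal((2, 1, 100)),
                    ["rest", "rest"], fs=100.0)
    with pytest.raises(ValueError, match="Nyquist"):
        bandpower_features(eps, band_hz=(6.0, 60.0))
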
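"""Offline model search: features x classifiers x analysis windows.

The search enumerates every combination of feature extractor (BP, CSP,
FBCSP), linear classifier (LDA, SVM, REGLOG) and 2-s analysis-window
placement (start at 0.5 .. 3.0 s after the cue, 0.5-s step), 3 x 3 x 6 = 54
candidate binary models, and scores each with 10 repetitions of stratified
10-fold cross-validation.  Feature fitting (CSP filter estimation) is nested
inside each training fold; the regularization constant of SVM/REGLOG is
chosen on an inner stratified 5-fold over the grid 2^-15 .. 2^10.

REGLOG is an l2-regularized logistic regression standing in as the third
linear classifier of the search.  All classifiers emit a signed score
calibrated to [-1, 1] with imagery positive: the posterior difference
P(imagery) - P(rest) for the probabilistic models (equal to tanh(d/2) of
the linear decision value d) and tanh(d) of the margin for the SVM.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from . import features as _feat
from .features import (FeatureSpec, SpatialFilterModel, epoch_covariances,
                       csp_from_covariances, csp_features_from_covariances,
                       make_extractor)
from .signal import (EpochSet, Recording, design_fir_bandpass, extract_epochs,
                     filter_array, fir_bandpass, resample)

HYPER_GRID = tuple(float(2.0 ** k) for k in range(-15, 11))  # 26 values
WINDOW_STARTS = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
FEATURE_KINDS = ("BP", "CSP", "FBCSP")
CLASSIFIER_KINDS = ("LDA", "SVM", "REGLOG")

# tie-break orderings: earlier window, then simpler feature, then smaller
# hyperparameter, then classifier order (final determinism key)
_FEATURE_ORDER = {"CSP": 0, "BP": 1, "FBCSP": 2}
_CLASSIFIER_ORDER = {"LDA": 0, "SVM": 1, "REGLOG": 2}


@dataclass
class CVScheme:
    n_repeats: int = 10
    n_folds: int = 10


@dataclass
class SearchGrid:
    feature_kinds: tuple = FEATURE_KINDS
    classifier_kinds: tuple = CLASSIFIER_KINDS
    window_starts: tuple = WINDOW_STARTS
    hyper_values: tuple = HYPER_GRID
    cv_scheme: CVScheme = field(default_factory=CVScheme)

    @property
    def n_candidates(self) -> int:
        return (len(self.feature_kinds) * len(self.classifier_kinds)
                * len(self.window_starts))


@dataclass
class Candidate:
    feature_spec: FeatureSpec
    classifier_kind: str
    window_start_s: float = 0.5


def _as01(labels: np.ndarray) -> np.ndarray:
    """Map two-class labels to {0, 1} with imagery (when present) positive."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    if "imagery" in classes:
        return (labels == "imagery").astype(int)
    return (labels == classes[1]).astype(int)


class ClassifierState:
    """A fitted linear classifier with a score calibrated to [-1, 1]."""

    def __init__(self, kind: str, estimator, classes: tuple):
        self.kind = kind
        self.estimator = estimator
        self.classes = classes  # (negative, positive)

    @property
    def weights(self) -> np.ndarray:
        return np.ravel(self.estimator.coef_)

    @property
    def bias(self) -> float:
        return float(np.ravel(self.estimator.intercept_)[0])

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.weights + self.bias

    def score(self, X: np.ndarray) -> np.ndarray:
        d = self.decision(X)
        return np.tanh(d) if self.kind == "SVM" else np.tanh(d / 2.0)

    def predict01(self, X: np.ndarray) -> np.ndarray:
        return (self.decision(X) > 0).astype(int)


def _make_estimator(kind: str, hyperparameter: float | None):
    if kind == "LDA":
        return LinearDiscriminantAnalysis(solver="lsqr")
    c = 1.0 if hyperparameter is None else float(hyperparameter)
    if kind == "SVM":
        return LinearSVC(C=c, dual=False, max_iter=20_000)
    if kind == "REGLOG":
        return LogisticRegression(C=c, solver="lbfgs", max_iter=1_000)
    raise ValueError(f"unknown classifier kind {kind!r}")


def train_classifier(kind: str, X: np.ndarray, labels: np.ndarray,
                     hyperparameter: float | None = None) -> ClassifierState:
    """Fit one linear classifier; returns a signed-score wrapper."""
    X = np.asarray(X, dtype=float)
    y = _as01(labels)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    est = _make_estimator(kind, hyperparameter)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X, y)
    except np.linalg.LinAlgError:
        if kind != "LDA":
            raise
        warnings.warn("degenerate within-class scatter; LDA refit with "
                      "automatic shrinkage", RuntimeWarning)
        est = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        est.fit(X, y)
    classes = np.unique(np.asarray(labels))
    if "imagery" in classes:
        neg = [c for c in classes if c != "imagery"][0]
        pair = (neg, "imagery")
    else:
        pair = (classes[0], classes[1])
    return ClassifierState(kind, est, pair)


# --- fast Newton solvers for the regularization path ------------------------
#
# The nested search evaluates 26 regularization values on an inner 5-fold
# inside every outer fold; at 54 candidates that is ~10^5 tiny model fits,
# where generic estimator overhead dominates.  These solvers minimize the
# same objectives as the deployed estimators -- l2-logistic regression,
# C * sum log(1+exp(-y f)) + ||w||^2 / 2, and the squared-hinge linear SVM,
# C * sum max(0, 1 - y f)^2 + ||w||^2 / 2 (intercept unpenalized) -- by
# damped Newton iteration on (w, b), which converges in a handful of steps
# at these dimensions.  They are used only to rank C values; per-fold and
# final models are fitted with scikit-learn.

def _fit_linear_fast(kind: str, X: np.ndarray, ypm: np.ndarray, c: float,
                     z0: np.ndarray | None = None, max_iter: int = 30,
                     tol: float = 1e-7) -> np.ndarray:
    n, d = X.shape
    Xa = np.hstack([X, np.ones((n, 1))])
    reg = np.ones(d + 1)
    reg[-1] = 0.0
    z = np.zeros(d + 1) if z0 is None else z0.copy()
    for _ in range(max_iter):
        f = Xa @ z
        m = ypm * f
        if kind == "REGLOG":
            s = 1.0 / (1.0 + np.exp(np.clip(m, -500, 500)))  # sigmoid(-m)
            grad = reg * z - c * Xa.T @ (ypm * s)
            wdiag = s * (1.0 - s)
            H = np.diag(reg) + c * (Xa.T * wdiag) @ Xa
        else:  # squared-hinge SVM
            active = m < 1.0
            r = np.where(active, 1.0 - m, 0.0)
            grad = reg * z - 2.0 * c * Xa.T @ (ypm * r)
            Xact = Xa[active]
            H = np.diag(reg) + 2.0 * c * Xact.T @ Xact
        gnorm = np.linalg.norm(grad)
        if gnorm < tol:
            break
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # damped update: halve until the objective stops increasing
        obj0 = _linear_objective(kind, Xa, ypm, z, c, reg)
        alpha = 1.0
        for _ in range(20):
            z_new = z - alpha * step
            if _linear_objective(kind, Xa, ypm, z_new, c, reg) <= obj0:
                break
            alpha *= 0.5
        z = z_new
    return z


def _linear_objective(kind, Xa, ypm, z, c, reg) -> float:
    f = Xa @ z
    m = ypm * f
    if kind == "REGLOG":
        loss = np.logaddexp(0.0, -m).sum()
    else:
        loss = (np.maximum(0.0, 1.0 - m) ** 2).sum()
    return 0.5 * float(z @ (reg * z)) + c * float(loss)


def select_hyperparameter(kind: str, X: np.ndarray, y01: np.ndarray,
                          grid: Sequence[float] = HYPER_GRID,
                          n_folds: int = 5, seed: int = 0) -> float:
    """Inner stratified CV over the regularization grid; ties -> smaller value.

    The path is evaluated with the fast Newton solvers (warm-started along
    increasing C); the winning value is then used for a scikit-learn fit by
    the caller.
    """
    min_count = int(np.bincount(y01, minlength=2).min())
    k = min(n_folds, min_count)
    if k < 2:
        return float(grid[len(grid) // 2])
    ypm = np.where(y01 == 1, 1.0, -1.0)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y01))
    ordered = sorted(float(c) for c in grid)
    correct = {c: 0 for c in ordered}
    total = 0
    for tr, te in folds:
        Xtr, Xte = X[tr], X[te]
        ytr, yte = ypm[tr], ypm[te]
        total += len(te)
        z = None
        for c in ordered:
            z = _fit_linear_fast(kind, Xtr, ytr, c, z0=z)
            pred = np.sign(np.hstack([Xte, np.ones((len(te), 1))]) @ z)
            correct[c] += int((pred == yte).sum())
    best_c, best_acc = None, -1.0
    for c in ordered:
        acc = correct[c] / total
        if acc > best_acc:  # strict: the smallest value wins ties
            best_acc, best_c = acc, c
    return best_c


# --- prepared per-candidate data (label-independent, computed once) ---------

def _prepare_feature(spec: FeatureSpec, epochs: EpochSet):
    """Precompute everything label-independent for fast nested CV.

    BP features depend only on the signal, so the full feature matrix is
    computed once.  CSP/FBCSP filters depend on labels, but the per-epoch
    trace-normalized covariances of the band-filtered signals do not, so
    they are cached and the per-fold work reduces to an eigendecomposition.
    """
    if spec.kind == "BP":
        return ("X", _feat.bandpower_features(epochs, spec.band_hz, spec.n_bins))
    bands = [spec.band_hz] if spec.kind == "CSP" else list(spec.bands_hz)
    covs = []
    for band in bands:
        taps = design_fir_bandpass(band[0], band[1], epochs.fs_hz)
        filtered = filter_array(epochs.epochs, taps, mode="zero_phase", axis=-1)
        covs.append(epoch_covariances(filtered))
    return ("covs", covs, spec.n_filters)


def _fold_features(prep, labels, train_idx, test_idx):
    if prep[0] == "X":
        X = prep[1]
        return X[train_idx], X[test_idx]
    _, covs_list, n_filters = prep
    xtr, xte = [], []
    for covs in covs_list:
        m = csp_from_covariances(covs[train_idx], labels[train_idx], n_filters)
        xtr.append(csp_features_from_covariances(m, covs[train_idx]))
        xte.append(csp_features_from_covariances(m, covs[test_idx]))
    return np.hstack(xtr), np.hstack(xte)


def cross_validate(candidate: Candidate, epochs: EpochSet,
                   scheme: CVScheme | None = None, seed: int = 0,
                   hyper_grid: Sequence[float] = HYPER_GRID) -> float:
    """Mean accuracy over repeated stratified k-fold CV with nested fitting."""
    scheme = scheme or CVScheme()
    y = _as01(epochs.labels)
    labels = np.asarray(epochs.labels)
    min_count = int(np.bincount(y, minlength=2).min())
    if min_count < scheme.n_folds:
        raise ValueError(
            f"stratified {scheme.n_folds}-fold CV needs at least "
            f"{scheme.n_folds} epochs per class, got {min_count}")
    prep = _prepare_feature(candidate.feature_spec, epochs)
    needs_hyper = candidate.classifier_kind in ("SVM", "REGLOG")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31, size=scheme.n_repeats)
    accs = []
    for r in range(scheme.n_repeats):
        skf = StratifiedKFold(n_splits=scheme.n_folds, shuffle=True,
                              random_state=int(rep_seeds[r]))
        for tr, te in skf.split(np.zeros(len(y)), y):
            xtr, xte = _fold_features(prep, labels, tr, te)
            hyper = None
            if needs_hyper:
                hyper = select_hyperparameter(candidate.classifier_kind, xtr,
                                              y[tr], hyper_grid,
                                              seed=int(rep_seeds[r]))
            est = _make_estimator(candidate.classifier_kind, hyper)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(xtr, y[tr])
            accs.append((est.predict(xte) == y[te]).mean())
    return float(np.mean(accs))


# --- the fitted model -------------------------------------------------------

@dataclass
class BCIModel:
    """A fitted binary motor-imagery decoder.

    Bundles the feature extractor, the linear classifier weights, the
    analysis-window placement chosen by the search, the cross-validation
    accuracy, and (after online calibration) the activity threshold.
    """

    feature_spec: FeatureSpec
    window_start_s: float
    classifier_kind: str
    hyperparameter: float | None
    cv_accuracy: float
    extractor: object
    weights: np.ndarray
    bias: float
    fs_hz: float = 250.0
    prefilter_band: tuple[float, float] = (6.0, 35.0)
    window_len_s: float = 2.0
    activity_threshold: float | None = None

    def _score_from_decision(self, d: np.ndarray) -> np.ndarray:
        return np.tanh(d) if self.classifier_kind == "SVM" else np.tanh(d / 2.0)

    def score_features(self, X: np.ndarray) -> np.ndarray:
        return self._score_from_decision(np.asarray(X) @ self.weights + self.bias)

    def score_epochs(self, epochs: EpochSet) -> np.ndarray:
        """Raw signed score in [-1, 1] per epoch, imagery positive."""
        return self.score_features(self.extractor.transform(epochs))

    def predict(self, epochs: EpochSet) -> np.ndarray:
        s = self.score_epochs(epochs)
        return np.where(s > 0, "imagery", "rest")

    def score_buffer(self, samples: np.ndarray, fs_hz: float,
                     channel_labels: list[str] | None = None) -> float:
        """Score one trailing analysis buffer (channels x samples)."""
        samples = np.asarray(samples, dtype=float)
        taps = design_fir_bandpass(*self.prefilter_band, fs_hz)
        filtered = filter_array(samples, taps, mode="zero_phase", axis=-1)
        epochs = EpochSet(filtered[None, :, :], np.array(["rest"]), fs_hz,
                          0.0, samples.shape[1] / fs_hz,
                          channel_labels or [])
        return float(self.score_epochs(epochs)[0])

    # -- JSON round trip -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "feature_spec": _spec_to_dict(self.feature_spec),
            "window_start_s": self.window_start_s,
            "classifier_kind": self.classifier_kind,
            "hyperparameter": self.hyperparameter,
            "cv_accuracy": self.cv_accuracy,
            "extractor": _extractor_to_dict(self.extractor),
            "weights": np.asarray(self.weights).tolist(),
            "bias": self.bias,
            "fs_hz": self.fs_hz,
            "prefilter_band": list(self.prefilter_band),
            "window_len_s": self.window_len_s,
            "activity_threshold": self.activity_threshold,
        }, indent=2)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "BCIModel":
        d = json.loads(text)
        spec = _spec_from_dict(d["feature_spec"])
        return cls(
            feature_spec=spec,
            window_start_s=d["window_start_s"],
            classifier_kind=d["classifier_kind"],
            hyperparameter=d["hyperparameter"],
            cv_accuracy=d["cv_accuracy"],
            extractor=_extractor_from_dict(d["extractor"], spec),
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            fs_hz=d["fs_hz"],
            prefilter_band=tuple(d["prefilter_band"]),
            window_len_s=d["window_len_s"],
            activity_threshold=d["activity_threshold"],
        )

    @classmethod
    def load(cls, path) -> "BCIModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _spec_to_dict(spec: FeatureSpec) -> dict:
    return {"kind": spec.kind, "band_hz": list(spec.band_hz),
            "n_filters": spec.n_filters, "n_bins": spec.n_bins,
            "bands_hz": [list(b) for b in spec.bands_hz]}


def _spec_from_dict(d: dict) -> FeatureSpec:
    return FeatureSpec(kind=d["kind"], band_hz=tuple(d["band_hz"]),
                       n_filters=d["n_filters"], n_bins=d["n_bins"],
                       bands_hz=tuple(tuple(b) for b in d["bands_hz"]))


def _sfm_to_dict(m: SpatialFilterModel) -> dict:
    return {"filters": m.filters.tolist(), "eigenvalues": m.eigenvalues.tolist(),
            "band_hz": list(m.band_hz), "class_order": list(m.class_order)}


def _sfm_from_dict(d: dict) -> SpatialFilterModel:
    return SpatialFilterModel(filters=np.asarray(d["filters"]),
                              eigenvalues=np.asarray(d["eigenvalues"]),
                              band_hz=tuple(d["band_hz"]),
                              class_order=tuple(d["class_order"]))


def _extractor_to_dict(ex) -> dict:
    if isinstance(ex, _feat.BandPowerExtractor):
        return {"kind": "BP"}
    if isinstance(ex, _feat.CSPExtractor):
        return {"kind": "CSP", "model": _sfm_to_dict(ex.model)}
    if isinstance(ex, _feat.FBCSPExtractor):
        return {"kind": "FBCSP", "models": [_sfm_to_dict(m) for m in ex.models]}
    raise TypeError(f"unknown extractor {type(ex)!r}")


def _extractor_from_dict(d: dict, spec: FeatureSpec):
    ex = make_extractor(spec)
    if d["kind"] == "CSP":
        ex.model = _sfm_from_dict(d["model"])
    elif d["kind"] == "FBCSP":
        ex.models = [_sfm_from_dict(m) for m in d["models"]]
    return ex


# --- the search -------------------------------------------------------------

def tie_break_key(row: dict) -> tuple:
    """Candidate ordering: higher accuracy first; ties go to the earlier
    window, then the simpler feature (CSP < BP < FBCSP), then the smaller
    hyperparameter, then classifier order (LDA < SVM < REGLOG)."""
    hyper = row.get("hyperparameter")
    return (-row["cv_accuracy"], row["window_start_s"],
            _FEATURE_ORDER.get(row["feature"], 99),
            hyper if hyper is not None else 0.0,
            _CLASSIFIER_ORDER.get(row["classifier"], 99))

def _feature_spec_for(kind: str) -> FeatureSpec:
    if kind == "BP":
        return FeatureSpec("BP", band_hz=_feat.BP_BAND, n_bins=_feat.BP_DIM)
    if kind == "CSP":
        return FeatureSpec("CSP", band_hz=_feat.CSP_BAND, n_filters=_feat.CSP_DIM)
    if kind == "FBCSP":
        return FeatureSpec("FBCSP", bands_hz=_feat.FBCSP_BANDS,
                           n_filters=_feat.CSP_DIM)
    raise ValueError(f"unknown feature kind {kind!r}")


def preprocess_recording(recording: Recording, analysis_fs_hz: float = 250.0,
                         prefilter_band: tuple = (6.0, 35.0)) -> Recording:
    """Offline chain: resample to the analysis rate, zero-phase FIR band-pass."""
    rec = recording
    if rec.fs_hz > analysis_fs_hz:
        rec = resample(rec, analysis_fs_hz)
    return fir_bandpass(rec, *prefilter_band, mode="zero_phase")


def model_search(recordings, schedules, grid: SearchGrid | None = None,
                 seed: int = 0, analysis_fs_hz: float = 250.0,
                 prefilter_band: tuple = (6.0, 35.0),
                 window_len_s: float = 2.0):
    """Enumerate and cross-validate every candidate; return (best, leaderboard).

    ``recordings``/``schedules`` may be single objects or equal-length
    sequences (one per stimulus-presentation run); epochs are pooled across
    runs.  The leaderboard has one row per candidate.  Ties in accuracy are
    broken by earlier window, simpler feature (CSP < BP < FBCSP), smaller
    hyperparameter, then classifier order (LDA < SVM < REGLOG).
    """
    grid = grid or SearchGrid()
    if grid.n_candidates == 0:
        raise ValueError("empty search grid")
    if isinstance(recordings, Recording):
        recordings, schedules = [recordings], [schedules]
    processed = [preprocess_recording(r, analysis_fs_hz, prefilter_band)
                 for r in recordings]

    window_epochs: dict[float, EpochSet] = {}
    for ws in grid.window_starts:
        parts = [extract_epochs(rec, sched, ws, window_len_s)
                 for rec, sched in zip(processed, schedules)]
        window_epochs[ws] = EpochSet.concat(parts)

    rows = []
    for ws in grid.window_starts:
        epochs = window_epochs[ws]
        y = _as01(epochs.labels)
        for fk in grid.feature_kinds:
            spec = _feature_spec_for(fk)
            prep_seed = seed  # same folds across candidates: paired comparison
            for ck in grid.classifier_kinds:
                cand = Candidate(spec, ck, ws)
                acc = cross_validate(cand, epochs, grid.cv_scheme,
                                     seed=prep_seed,
                                     hyper_grid=grid.hyper_values)
                hyper = None
                if ck in ("SVM", "REGLOG"):
                    ex = make_extractor(spec).fit(epochs)
                    hyper = select_hyperparameter(ck, ex.transform(epochs), y,
                                                  grid.hyper_values, seed=seed)
                rows.append({"feature": fk, "classifier": ck,
                             "window_start_s": ws, "hyperparameter": hyper,
                             "cv_accuracy": acc})

    leaderboard = pd.DataFrame(rows)
    best_row = min(rows, key=tie_break_key)
    leaderboard = leaderboard.sort_values(
        by=["cv_accuracy"], ascending=False, kind="stable").reset_index(drop=True)

    epochs = window_epochs[best_row["window_start_s"]]
    spec = _feature_spec_for(best_row["feature"])
    extractor = make_extractor(spec).fit(epochs)
    X = extractor.transform(epochs)
    state = train_classifier(best_row["classifier"], X, epochs.labels,
                             best_row["hyperparameter"])
    best = BCIModel(
        feature_spec=spec,
        window_start_s=best_row["window_start_s"],
        classifier_kind=best_row["classifier"],
        hyperparameter=best_row["hyperparameter"],
        cv_accuracy=best_row["cv_accuracy"],
        extractor=extractor,
        weights=state.weights.copy(),
        bias=state.bias,
        fs_hz=analysis_fs_hz,
        prefilter_band=tuple(prefilter_band),
        window_len_s=window_len_s,
    )
    return best, leaderboard
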
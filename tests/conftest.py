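"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

import bfrehab as bf
from bfrehab.model import CVScheme, SearchGrid, preprocess_recording
from bfrehab.signal import EpochSet, extract_epochs


@pytest.fixture(scope="session")
def erd_cfg():
    """Strong bilateral-ERD configuration at the 250-Hz analysis rate."""
    return bf.ERDSimConfig(fs_hz=250.0, erd_depth=0.7,
                           erd_channels=("C3", "C4"), seed=3)


@pytest.fixture(scope="session")
def small_run(erd_cfg):
    return bf.simulate_run(erd_cfg, 20)


@pytest.fixture(scope="session")
def epochs_strong(erd_cfg):
    """100 pooled epochs (5 runs x 20 cues) after the offline chain."""
    runs = bf.simulate_session(erd_cfg, 5, 20)
    parts = []
    for rec, sched in runs:
        parts.append(extract_epochs(preprocess_recording(rec), sched, 0.5))
    return EpochSet.concat(parts)


@pytest.fixture(scope="session")
def tiny_grid():
    """Single-candidate grid with a reduced CV scheme for fast end-to-end runs."""
    return SearchGrid(feature_kinds=("CSP",), classifier_kinds=("LDA",),
                      window_starts=(0.5,), cv_scheme=CVScheme(2, 5))


@pytest.fixture(scope="session")
def fitted_model(erd_cfg, tiny_grid):
    """A quick CSP+LDA model with a calibrated activity threshold."""
    runs = bf.simulate_session(erd_cfg, 2, 20)
    model, _ = bf.model_search([r for r, _ in runs], [s for _, s in runs],
                               tiny_grid, seed=5)
    rest = bf.simulate_rest_stream(erd_cfg, 30.0,
                                   rng=np.random.default_rng(99))
    bf.calibrate_threshold(model, rest)
    return model
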
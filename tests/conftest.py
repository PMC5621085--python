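"""Shared fixtures: a miniature gait session and a toy separable feature set."""

import numpy as np
import pytest

from lmradapt.bank import SearchSpec, train_phase_bank
from lmradapt.features import deadzone_from_trials, extract_features
from lmradapt.simulate import DriftSchedule, build_default_config, generate_session

#: shorter cycles / fewer strides than the default protocol, for fast unit tests
TINY_OVERRIDES = dict(
    steps_per_mode=2,
    phase_durations_ms=(80.0, 150.0, 80.0, 100.0, 100.0),
)

SMALL_GRID = SearchSpec(C_grid=(2.0**2,), gamma_grid=(2.0**-5,), n_folds=2,
                        calibration_folds=2)


@pytest.fixture(scope="session")
def tiny_config():
    return build_default_config(0, **TINY_OVERRIDES)


@pytest.fixture(scope="session")
def tiny_session(tiny_config):
    """2 training reps + 2 stationary testing trials of the reduced protocol."""
    schedule = DriftSchedule(kind="none", seed=0)
    training, testing = generate_session(tiny_config, schedule, 2, 2)
    return training, testing


@pytest.fixture(scope="session")
def tiny_features(tiny_session):
    training, testing = tiny_session
    deadzone = deadzone_from_trials(training)
    train_feats = [
        extract_features(t, deadzone=deadzone, trial_index=i)
        for i, t in enumerate(training)
    ]
    test_feats = [
        extract_features(t, deadzone=deadzone, trial_index=k)
        for k, t in enumerate(testing, start=1)
    ]
    X = np.vstack([f.X for f in train_feats])
    phase = np.concatenate([f.phase for f in train_feats])
    y = np.concatenate([f.true_mode for f in train_feats])
    return (X, phase, y), test_feats


@pytest.fixture(scope="session")
def tiny_bank(tiny_features):
    (X, phase, y), _ = tiny_features
    return train_phase_bank(X, phase, y, search_spec=SMALL_GRID, seed=0)


def make_toy_phase_set(n_per_cell: int = 12, spread: float = 0.05, seed: int = 0):
    """Linearly separable 2-feature toy set covering every (phase, mode) cell.

    Mode k sits at angle 2*pi*k/5 on the unit circle in every phase.
    """
    rng = np.random.default_rng(seed)
    X, phase, y = [], [], []
    for p in range(1, 6):
        for k in range(5):
            center = np.array([np.cos(2 * np.pi * k / 5), np.sin(2 * np.pi * k / 5)])
            X.append(center + spread * rng.standard_normal((n_per_cell, 2)))
            phase.append(np.full(n_per_cell, p))
            y.append(np.full(n_per_cell, k))
    return np.vstack(X), np.concatenate(phase), np.concatenate(y)


@pytest.fixture(scope="session")
def toy_bank():
    X, phase, y = make_toy_phase_set()
    bank = train_phase_bank(X, phase, y, search_spec=SMALL_GRID, seed=1)
    return bank, (X, phase, y)
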
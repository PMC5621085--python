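"""Windowing and EMG/mechanical feature extraction against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lmradapt.features import (
    bandpass_emg,
    emg_td_features,
    extract_features,
    mech_features,
    segment_windows,
    window_count,
)
from lmradapt.simulate import DriftState, TrialRecording, generate_trial


def brute_force_td(x, eps):
    """Loop-based MAV/WL/SSC/ZC reference."""
    x = np.asarray(x, dtype=float)
    mav = sum(abs(v) for v in x) / len(x)
    wl = sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))
    zc = sum(
        1
        for i in range(len(x) - 1)
        if x[i] * x[i + 1] < 0 and abs(x[i]) > eps and abs(x[i + 1]) > eps
    )
    ssc = 0
    for i in range(1, len(x) - 1):
        d1 = x[i] - x[i - 1]
        d2 = x[i] - x[i + 1]
        if d1 * d2 > 0 and max(abs(d1), abs(d2)) > eps:
            ssc += 1
    return mav, wl, ssc, zc


class TestWindowCounts:
    @pytest.mark.parametrize(
        "T,L,step,expected",
        [
            (1000, 160, 20, 43),
            (160, 160, 20, 1),
            (1000, 160, 50, 17),  # online decision rate
            (999, 160, 20, 42),
        ],
    )
    def test_count_formula(self, T, L, step, expected):
        assert window_count(T, L, step) == expected

    def test_count_formula_randomized(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            L = int(rng.integers(1, 300))
            T = L + int(rng.integers(0, 2000))
            step = int(rng.integers(1, 100))
            assert window_count(T, L, step) == (T - L) // step + 1

    def test_trial_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            window_count(100, 160, 20)


class TestSegmentWindows:
    def test_phase_and_mode_taken_at_final_sample(self, tiny_config):
        trial = generate_trial(tiny_config, DriftState.identity(), 3)
        ws = segment_windows(trial)
        assert np.array_equal(ws.phase, trial.phase_labels[ws.last_sample])
        assert np.array_equal(ws.true_mode, trial.mode_labels[ws.last_sample])

    def test_window_content_matches_source(self, tiny_config):
        trial = generate_trial(tiny_config, DriftState.identity(), 3)
        ws = segment_windows(trial)
        i = len(ws) // 2
        s = ws.start_sample[i]
        assert np.array_equal(ws.emg[i], trial.emg[:, s : s + 160])
        assert np.array_equal(ws.mech[i], trial.mech[:, s : s + 160])


class TestBandpass:
    def test_dc_attenuated_by_40db(self):
        x = np.ones(2000)
        y = bandpass_emg(x, 1000.0)
        assert np.abs(y[500:]).max() < 10 ** (-40 / 20)

    def test_passband_gain_near_unity_at_100hz(self):
        t = np.arange(4000) / 1000.0
        x = np.sin(2 * np.pi * 100 * t)
        y = bandpass_emg(x, 1000.0)
        steady = y[2000:]
        gain = steady.std() / x[2000:].std()
        assert 10 ** (-1 / 20) < gain < 10 ** (1 / 20)

    def test_zero_input_zero_output(self):
        assert np.allclose(bandpass_emg(np.zeros(500), 1000.0), 0.0)

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError):
            bandpass_emg(np.zeros(500), 800.0)


class TestTimeDomainFeatures:
    @pytest.mark.parametrize(
        "x,eps,expected",
        [
            ([1, -1, 1, -1], 0.0, (1.0, 6.0, 2.0, 3.0)),
            ([0, 0, 0, 0], 0.5, (0.0, 0.0, 0.0, 0.0)),
            ([1, -1, 1, -1], 2.0, (1.0, 6.0, 0.0, 0.0)),
        ],
    )
    def test_hand_counted_examples(self, x, eps, expected):
        mav, wl, ssc, zc = emg_td_features(x, eps)
        assert (mav, wl, ssc, zc) == pytest.approx(expected)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            emg_td_features([1.0, 2.0])

    @settings(deadline=None, max_examples=150)
    @given(
        x=st.lists(st.floats(-10, 10, allow_nan=False), min_size=3, max_size=60),
        eps=st.floats(0, 2),
    )
    def test_matches_brute_force(self, x, eps):
        got = emg_td_features(np.array(x), eps)
        want = brute_force_td(x, eps)
        assert got[0] == pytest.approx(want[0], rel=1e-9, abs=1e-12)
        assert got[1] == pytest.approx(want[1], rel=1e-9, abs=1e-12)
        assert got[2] == want[2]
        assert got[3] == want[3]

    @settings(deadline=None, max_examples=100)
    @given(x=st.lists(st.floats(-10, 10, allow_nan=False), min_size=3, max_size=60))
    def test_waveform_length_dominates_net_excursion(self, x):
        _, wl, _, _ = emg_td_features(np.array(x))
        assert wl >= abs(x[-1] - x[0]) - 1e-9


class TestMechFeatures:
    @pytest.mark.parametrize(
        "x,expected",
        [
            ([1, 2, 3], (3, 1, 2, 0.816496580927726)),
            ([4, 4, 4], (4, 4, 4, 0)),
            ([-5, 5], (5, -5, 0, 5)),
        ],
    )
    def test_order_and_moment_statistics(self, x, expected):
        assert mech_features(x) == pytest.approx(expected)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            mech_features([1.0])


class TestExtractFeatures:
    def test_dimension_is_4emg_plus_4mech(self, tiny_config):
        trial = generate_trial(tiny_config, DriftState.identity(), 3)
        fs = extract_features(trial)
        assert fs.X.shape == (window_count(trial.n_samples, 160, 20), 52)
        assert not np.isnan(fs.X).any()

    def test_zero_signal_trial_gives_zero_features(self, tiny_config):
        trial = generate_trial(tiny_config, DriftState.identity(), 3)
        silent = TrialRecording(
            emg=np.zeros_like(trial.emg),
            mech=np.zeros_like(trial.mech),
            phase_labels=trial.phase_labels,
            mode_labels=trial.mode_labels,
            transition_events=trial.transition_events,
            sample_rate=trial.sample_rate,
        )
        fs = extract_features(silent)
        assert np.allclose(fs.X, 0.0)

    def test_extraction_is_pure(self, tiny_config):
        trial = generate_trial(tiny_config, DriftState.identity(), 3)
        a = extract_features(trial, deadzone=0.01)
        b = extract_features(trial, deadzone=0.01)
        assert np.array_equal(a.X, b.X)

    def test_windows_match_per_window_computation(self, tiny_config):
        """Vectorized extraction equals per-window scalar feature calls."""
        trial = generate_trial(tiny_config, DriftState.identity(), 9)
        eps = 0.02
        fs = extract_features(trial, deadzone=eps)
        ws = segment_windows(trial)
        for i in (0, len(ws) // 3, len(ws) - 1):
            filt = bandpass_emg(ws.emg[i], trial.sample_rate)
            for c in range(7):
                expected = emg_td_features(filt[c], eps)
                assert fs.X[i, 4 * c : 4 * c + 4] == pytest.approx(expected)
            for c in range(6):
                expected = mech_features(ws.mech[i][c])
                assert fs.X[i, 28 + 4 * c : 28 + 4 * c + 4] == pytest.approx(expected)
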
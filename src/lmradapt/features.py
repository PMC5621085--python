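"""Sliding-window segmentation and fused EMG + mechanical feature extraction.

Trials are segmented into overlapping analysis windows (160 ms length, 20 ms
increment by default; 50 ms increment in the online configuration).  Within
each window the EMG is band-passed (20-420 Hz, 8th-order Butterworth, forward
filtering of the window's own samples) and four classical time-domain features
are computed per channel: mean absolute value (MAV), waveform length (WL),
slope-sign changes (SSC) and zero crossings (ZC).  Mechanical channels
contribute the window maximum, minimum, mean and population standard
deviation of the raw samples.  The fused vector is ordered EMG-first
(channel 1..n, each MAV, WL, SSC, ZC) then mechanical (channel 1..n, each
max, min, mean, std) — 52 dimensions in the default 7 EMG + 6 mech setup.

A window's gait phase and true mode are attributed from its final sample
(the causal decision point).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from lmradapt.simulate import SimulationConfig, TrialRecording

_BP_LOW_HZ = 20.0
_BP_HIGH_HZ = 420.0


@dataclass(frozen=True)
class WindowSet:
    """Strided views of one trial's analysis windows plus window metadata."""

    emg: np.ndarray          # (n_windows, n_emg, L)
    mech: np.ndarray         # (n_windows, n_mech, L)
    phase: np.ndarray        # (n_windows,) phase id of each window's last sample
    true_mode: np.ndarray    # (n_windows,) mode index of each window's last sample
    start_sample: np.ndarray
    last_sample: np.ndarray

    def __len__(self) -> int:
        return self.emg.shape[0]


@dataclass
class FeatureSet:
    """Fused feature vectors for one trial (one row per analysis window)."""

    X: np.ndarray            # (n_windows, 4*n_emg + 4*n_mech)
    phase: np.ndarray
    true_mode: np.ndarray
    last_sample: np.ndarray
    window_index: np.ndarray
    trial_index: int
    feature_names: tuple[str, ...]

    def __len__(self) -> int:
        return self.X.shape[0]


def window_count(n_samples: int, window_samples: int, increment_samples: int) -> int:
    """floor((T - L) / increment) + 1 for T >= L."""
    if n_samples < window_samples:
        raise ValueError("trial shorter than one analysis window")
    return (n_samples - window_samples) // increment_samples + 1


def segment_windows(
    trial: TrialRecording, window_ms: float = 160.0, increment_ms: float = 20.0
) -> WindowSet:
    """Segment a trial into sliding analysis windows."""
    rate = trial.sample_rate
    L = int(round(window_ms * rate / 1000.0))
    step = int(round(increment_ms * rate / 1000.0))
    if step < 1 or L < 1:
        raise ValueError("window and increment must be at least one sample")
    n = window_count(trial.n_samples, L, step)
    starts = np.arange(n) * step
    last = starts + L - 1
    emg_w = np.lib.stride_tricks.sliding_window_view(trial.emg, L, axis=1)[:, starts, :]
    mech_w = np.lib.stride_tricks.sliding_window_view(trial.mech, L, axis=1)[:, starts, :]
    return WindowSet(
        emg=np.ascontiguousarray(np.swapaxes(emg_w, 0, 1)),
        mech=np.ascontiguousarray(np.swapaxes(mech_w, 0, 1)),
        phase=trial.phase_labels[last].copy(),
        true_mode=trial.mode_labels[last].copy(),
        start_sample=starts,
        last_sample=last,
    )


def _bandpass_sos(rate: float):
    if rate <= 2 * _BP_HIGH_HZ:
        raise ValueError(f"sample rate {rate} Hz too low for a {_BP_HIGH_HZ} Hz corner")
    # butter(4, bandpass) -> 8th-order band-pass transfer function
    return signal.butter(4, [_BP_LOW_HZ, _BP_HIGH_HZ], btype="bandpass", fs=rate, output="sos")


def bandpass_emg(samples: np.ndarray, rate: float) -> np.ndarray:
    """Forward band-pass (20-420 Hz, 8th-order Butterworth) along the last axis.

    Filtering is causal and applied to the given samples only, so each
    analysis window carries its own (short) start-up transient.
    """
    sos = _bandpass_sos(rate)
    return signal.sosfilt(sos, np.asarray(samples, dtype=float), axis=-1)


def emg_td_features(samples: np.ndarray, deadzone_eps: float = 0.0):
    """Time-domain features (MAV, WL, SSC, ZC) of one 1-D sample sequence.

    ZC counts sign changes between consecutive samples where both magnitudes
    exceed ``deadzone_eps``; SSC counts interior samples that are a local
    extremum with at least one neighbouring step larger than ``deadzone_eps``.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.shape[0] < 3:
        raise ValueError("need a 1-D sequence of length >= 3")
    mav, wl, ssc, zc = _td_feature_block(x[None, :], float(deadzone_eps))
    return float(mav[0]), float(wl[0]), float(ssc[0]), float(zc[0])


def _td_feature_block(x: np.ndarray, eps) -> tuple[np.ndarray, ...]:
    """Vectorized MAV/WL/SSC/ZC over the last axis.

    ``x``: (..., L); ``eps``: scalar or broadcastable to ``x[..., 0]``.
    """
    eps = np.asarray(eps)[..., None] if np.ndim(eps) else eps
    mav = np.mean(np.abs(x), axis=-1)
    d = np.diff(x, axis=-1)
    wl = np.sum(np.abs(d), axis=-1)
    zc = np.sum(
        (x[..., :-1] * x[..., 1:] < 0)
        & (np.abs(x[..., :-1]) > eps)
        & (np.abs(x[..., 1:]) > eps),
        axis=-1,
    )
    d1 = x[..., 1:-1] - x[..., :-2]
    d2 = x[..., 1:-1] - x[..., 2:]
    ssc = np.sum((d1 * d2 > 0) & (np.maximum(np.abs(d1), np.abs(d2)) > eps), axis=-1)
    return mav, wl, ssc.astype(float), zc.astype(float)


def mech_features(samples: np.ndarray):
    """(max, min, mean, population std) of one raw mechanical window."""
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.shape[0] < 2:
        raise ValueError("need a 1-D sequence of length >= 2")
    return float(x.max()), float(x.min()), float(x.mean()), float(x.std())


def feature_names(n_emg: int = 7, n_mech: int = 6) -> tuple[str, ...]:
    names: list[str] = []
    for c in range(1, n_emg + 1):
        names += [f"emg{c}_mav", f"emg{c}_wl", f"emg{c}_ssc", f"emg{c}_zc"]
    for c in range(1, n_mech + 1):
        names += [f"mech{c}_max", f"mech{c}_min", f"mech{c}_mean", f"mech{c}_std"]
    return tuple(names)


def deadzone_from_trials(trials, fraction: float = 0.01) -> np.ndarray:
    """Per-EMG-channel dead-zone for ZC/SSC: ``fraction`` x channel std.

    Computed once on the training trials and then held fixed, so feature
    extraction stays pure across testing trials.
    """
    emg = np.concatenate([t.emg for t in trials], axis=1)
    return fraction * emg.std(axis=1)


def extract_features(
    trial: TrialRecording,
    config: SimulationConfig | None = None,
    *,
    window_ms: float = 160.0,
    increment_ms: float = 20.0,
    deadzone: np.ndarray | float = 0.0,
    trial_index: int = 0,
) -> FeatureSet:
    """Compute the fused feature matrix of one trial.

    ``deadzone`` is a scalar or per-EMG-channel array used by the ZC/SSC
    counts (see :func:`deadzone_from_trials`).
    """
    ws = segment_windows(trial, window_ms, increment_ms)
    n_emg = trial.emg.shape[0]
    n_mech = trial.mech.shape[0]

    filtered = bandpass_emg(ws.emg, trial.sample_rate)  # (n, n_emg, L)
    eps = np.broadcast_to(np.asarray(deadzone, dtype=float), (n_emg,))
    mav, wl, ssc, zc = _td_feature_block(filtered, eps[None, :])
    emg_feats = np.stack([mav, wl, ssc, zc], axis=-1).reshape(len(ws), 4 * n_emg)

    mx = ws.mech.max(axis=-1)
    mn = ws.mech.min(axis=-1)
    mean = ws.mech.mean(axis=-1)
    std = ws.mech.std(axis=-1)
    mech_feats = np.stack([mx, mn, mean, std], axis=-1).reshape(len(ws), 4 * n_mech)

    return FeatureSet(
        X=np.hstack([emg_feats, mech_feats]),
        phase=ws.phase,
        true_mode=ws.true_mode,
        last_sample=ws.last_sample,
        window_index=np.arange(len(ws)),
        trial_index=trial_index,
        feature_names=feature_names(n_emg, n_mech),
    )
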
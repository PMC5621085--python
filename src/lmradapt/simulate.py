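"""Synthetic gait-signal simulator for locomotion-mode recognition.

Generates multichannel trials that emulate what a powered transfemoral
prosthesis records during ambulation: seven surface-EMG channels from thigh
muscles and six load-cell force/moment channels, sampled at 1000 Hz, with
per-sample gait-phase (1-5) and locomotion-mode labels for five modes —
level walking (W), ramp ascent/descent (RA/RD) and stair ascent/descent
(SA/SD).

The EMG model is a band-limited Gaussian carrier (20-400 Hz) amplitude-
modulated by a (mode, phase, channel) activation envelope, over a broadband
baseline-noise floor.  Mechanical channels follow smooth two-harmonic
periodic profiles per (mode, channel) locked to the gait cycle.  Signal
drift across trials — the phenomenon the adaptive classifiers exist to
handle — is modelled by :class:`DriftState` (per-channel amplitude scaling,
baseline-noise growth, spectral lowering, mechanical offsets) advanced by a
:class:`DriftSchedule` that is either gradual (human-prosthesis
accommodation) or abrupt (socket don/doff plus temperature change).

All randomness flows from named integer seeds through
``numpy.random.SeedSequence``; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

MODES: tuple[str, ...] = ("W", "RA", "RD", "SA", "SD")
MODE_INDEX: dict[str, int] = {m: i for i, m in enumerate(MODES)}
N_MODES = 5
N_PHASES = 5

#: default task sequence of one trial: walk, stairs up, walk, stairs down,
#: walk, ramp up, walk, ramp down, walk -> eight mode transitions
DEFAULT_SEQUENCE: tuple[str, ...] = ("W", "SA", "W", "SD", "W", "RA", "W", "RD", "W")

# stance is phases 1-3 (initial double support, single stance, pre-swing);
# swing is phases 4-5.  Phase 1 onset is the foot-contact analog.
STANCE_PHASES: tuple[int, ...] = (1, 2, 3)
SINGLE_STANCE_PHASE = 2

_EMG_BAND_LOW_HZ = 20.0
_EMG_BAND_HIGH_HZ = 400.0


@dataclass(frozen=True)
class SimulationConfig:
    """Immutable description of the signal generator.

    ``envelope_table`` has shape (5 modes, 5 phases, n_emg_channels) of
    non-negative activation amplitudes (arbitrary units).
    ``mech_profile_table`` has shape (5 modes, n_mech_channels, 5) holding
    per-profile parameters ``[a0, a1, phi1, a2, phi2]`` of
    ``a0 + a1 sin(2 pi t + phi1) + a2 sin(4 pi t + phi2)`` over cycle
    fraction ``t``.
    """

    n_emg_channels: int = 7
    n_mech_channels: int = 6
    sample_rate: float = 1000.0
    mode_sequence: tuple[str, ...] = DEFAULT_SEQUENCE
    steps_per_mode: int = 3
    phase_durations_ms: tuple[float, ...] = (100.0, 300.0, 100.0, 150.0, 150.0)
    envelope_table: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    mech_profile_table: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    noise_floor: float = 0.08
    mech_noise_sd: float = 0.18
    stride_gain_sd: float = 0.32
    mech_gain_sd: float = 0.32
    mode_separation: float = 0.30
    mech_mode_separation: float = 0.11
    phase_jitter: float = 0.10
    envelope_smooth_ms: float = 60.0
    transition_blend_ms: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.phase_durations_ms) != N_PHASES:
            raise ValueError("phase_durations_ms must have 5 entries")
        if any(d <= 0 for d in self.phase_durations_ms):
            raise ValueError("phase durations must be > 0")
        for m in self.mode_sequence:
            if m not in MODE_INDEX:
                raise ValueError(f"unknown mode {m!r} in mode_sequence")
        if self.envelope_table is not None:
            tab = np.asarray(self.envelope_table, dtype=float)
            if tab.shape != (N_MODES, N_PHASES, self.n_emg_channels):
                raise ValueError("envelope_table shape mismatch")
            if (tab < 0).any():
                raise ValueError("envelope amplitudes must be >= 0")

    @property
    def cycle_ms(self) -> float:
        return float(sum(self.phase_durations_ms))


@dataclass(frozen=True)
class DriftState:
    """Multiplicative/additive distortion applied to one generated trial."""

    emg_scale: np.ndarray          # (n_emg,) amplitude multipliers, > 0
    baseline_noise_scale: float    # multiplier on the EMG noise floor, > 0
    spectral_shift: float          # fractional lowering of the 400 Hz corner
    mech_offset: np.ndarray        # (n_mech,) additive biases

    def __post_init__(self) -> None:
        if (np.asarray(self.emg_scale) <= 0).any():
            raise ValueError("emg_scale entries must be > 0")
        if self.baseline_noise_scale <= 0:
            raise ValueError("baseline_noise_scale must be > 0")
        if not 0.0 <= self.spectral_shift < 1.0:
            raise ValueError("spectral_shift must be in [0, 1)")

    @classmethod
    def identity(cls, n_emg: int = 7, n_mech: int = 6) -> "DriftState":
        return cls(np.ones(n_emg), 1.0, 0.0, np.zeros(n_mech))


@dataclass(frozen=True)
class AbruptMagnitude:
    """The step applied at a don/doff + temperature-change analog."""

    emg_scale_factors: np.ndarray
    baseline_factor: float
    spectral_shift_add: float
    mech_offset_add: np.ndarray


@dataclass(frozen=True)
class DriftSchedule:
    """How drift evolves across testing trials.

    kind ``none``: stationary session.  ``gradual``: per-trial multiplicative
    random walk of the EMG amplitude scales (fixed per-channel direction with
    seeded jitter) plus slow baseline-noise growth, spectral lowering and
    mechanical-offset creep.  ``abrupt``: a single step of magnitude
    ``abrupt_magnitude`` applied at ``abrupt_trial_index``.
    """

    kind: str = "none"
    gradual_rate: float = 0.035
    abrupt_trial_index: int = 6
    abrupt_magnitude: AbruptMagnitude | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gradual", "abrupt"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.gradual_rate < 0:
            raise ValueError("gradual_rate must be >= 0")


@dataclass(frozen=True)
class TrialRecording:
    """One continuous multichannel trial with ground-truth labels.

    ``emg``: (n_emg, T); ``mech``: (n_mech, T); ``phase_labels``: (T,) in 1-5;
    ``mode_labels``: (T,) mode indices into :data:`MODES`;
    ``transition_events``: ordered (sample_index, from_mode_idx, to_mode_idx).
    """

    emg: np.ndarray
    mech: np.ndarray
    phase_labels: np.ndarray
    mode_labels: np.ndarray
    transition_events: tuple[tuple[int, int, int], ...]
    sample_rate: float

    @property
    def n_samples(self) -> int:
        return self.emg.shape[1]


def build_default_config(seed: int, **overrides) -> SimulationConfig:
    """Construct the default simulation configuration for a given seed.

    Envelope amplitudes share a common (phase, channel) base modulated by
    mode-specific lognormal deviations, so the five modes are separable in
    expectation but overlap enough that classification lands in the
    low-to-mid-90s accuracy regime a deployed recognition system occupies,
    rather than at ceiling.  Keyword overrides replace any
    :class:`SimulationConfig` field after the tables are built.
    """
    base_cfg = SimulationConfig(seed=seed)
    n_emg = int(overrides.get("n_emg_channels", base_cfg.n_emg_channels))
    n_mech = int(overrides.get("n_mech_channels", base_cfg.n_mech_channels))
    sep = float(overrides.get("mode_separation", base_cfg.mode_separation))
    mech_sep = float(overrides.get("mech_mode_separation", base_cfg.mech_mode_separation))

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    # EMG activation envelopes: shared phase/channel base x mode deviation
    base = rng.uniform(0.25, 1.0, size=(N_PHASES, n_emg))
    mode_dev = rng.standard_normal(size=(N_MODES, N_PHASES, n_emg))
    envelope = base[None, :, :] * np.exp(sep * mode_dev)

    # Mechanical profiles: per-channel base harmonics x mode deviation
    a0 = rng.uniform(-1.5, 1.5, size=n_mech)
    a1 = rng.uniform(0.8, 2.0, size=n_mech)
    a2 = rng.uniform(0.2, 0.8, size=n_mech)
    phi1 = rng.uniform(0, 2 * np.pi, size=n_mech)
    phi2 = rng.uniform(0, 2 * np.pi, size=n_mech)
    mech = np.empty((N_MODES, n_mech, 5))
    for m in range(N_MODES):
        amp_dev = np.exp(mech_sep * rng.standard_normal(size=(2, n_mech)))
        ph_dev = (2.5 * mech_sep) * rng.standard_normal(size=(2, n_mech))
        mech[m, :, 0] = a0 + 1.2 * mech_sep * rng.standard_normal(size=n_mech)
        mech[m, :, 1] = a1 * amp_dev[0]
        mech[m, :, 2] = phi1 + ph_dev[0]
        mech[m, :, 3] = a2 * amp_dev[1]
        mech[m, :, 4] = phi2 + ph_dev[1]

    cfg = replace(
        base_cfg,
        envelope_table=envelope,
        mech_profile_table=mech,
        n_emg_channels=n_emg,
        n_mech_channels=n_mech,
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


def _gradual_directions(schedule: DriftSchedule, n_emg: int, n_mech: int):
    """Fixed per-channel drift directions, a function of the schedule seed only."""
    rng = np.random.default_rng(np.random.SeedSequence(schedule.seed, spawn_key=(0,)))
    emg_dir = rng.choice([-1.0, 1.0], size=n_emg)
    mech_dir = rng.choice([-1.0, 1.0], size=n_mech)
    return emg_dir, mech_dir


def default_abrupt_magnitude(seed: int, n_emg: int = 7, n_mech: int = 6) -> AbruptMagnitude:
    """Don/doff + temperature analog: mainly EMG-side distortion."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    return AbruptMagnitude(
        emg_scale_factors=np.exp(rng.normal(0.0, 0.45, size=n_emg)),
        baseline_factor=1.6,
        spectral_shift_add=0.08,
        mech_offset_add=rng.normal(0.0, 0.15, size=n_mech),
    )


def advance_drift(state: DriftState, schedule: DriftSchedule, trial_index: int) -> DriftState:
    """Advance the drift state by one trial according to the schedule.

    ``trial_index`` is 1-based.  With ``kind='none'`` (or a zero gradual
    rate) the state is returned unchanged; with ``kind='abrupt'`` the step is
    applied only when ``trial_index == abrupt_trial_index``.
    """
    if trial_index < 1:
        raise ValueError("trial_index must be >= 1")
    n_emg = state.emg_scale.shape[0]
    n_mech = state.mech_offset.shape[0]
    if schedule.kind == "none":
        return state
    if schedule.kind == "gradual":
        rate = schedule.gradual_rate
        if rate == 0:
            return state
        emg_dir, mech_dir = _gradual_directions(schedule, n_emg, n_mech)
        rng = np.random.default_rng(
            np.random.SeedSequence(schedule.seed, spawn_key=(2, trial_index))
        )
        jit = 1.0 + 0.3 * rng.standard_normal(size=n_emg)
        new_scale = state.emg_scale * np.exp(rate * emg_dir * jit)
        new_baseline = state.baseline_noise_scale * float(np.exp(0.6 * rate))
        new_shift = min(state.spectral_shift + 0.25 * rate, 0.6)
        mech_jit = 1.0 + 0.3 * rng.standard_normal(size=n_mech)
        new_offset = state.mech_offset + 1.0 * rate * mech_dir * mech_jit
        return DriftState(new_scale, new_baseline, new_shift, new_offset)
    # abrupt
    if trial_index != schedule.abrupt_trial_index:
        return state
    mag = schedule.abrupt_magnitude
    if mag is None:
        mag = default_abrupt_magnitude(schedule.seed, n_emg, n_mech)
    return DriftState(
        state.emg_scale * mag.emg_scale_factors,
        state.baseline_noise_scale * mag.baseline_factor,
        min(state.spectral_shift + mag.spectral_shift_add, 0.6),
        state.mech_offset + mag.mech_offset_add,
    )


def _phase_plan(config: SimulationConfig, rng: np.random.Generator):
    """Per-sample phase/mode labels and cycle geometry for one trial."""
    if len(config.mode_sequence) == 0:
        raise ValueError("mode_sequence must not be empty")
    rate = config.sample_rate
    phase_labels: list[np.ndarray] = []
    mode_labels: list[np.ndarray] = []
    cycle_frac: list[np.ndarray] = []
    transition_events: list[tuple[int, int, int]] = []
    cursor = 0
    prev_mode: int | None = None
    for mode_name in config.mode_sequence:
        m = MODE_INDEX[mode_name]
        if prev_mode is not None and prev_mode != m:
            transition_events.append((cursor, prev_mode, m))
        prev_mode = m
        for _step in range(config.steps_per_mode):
            durs = np.array(
                [
                    max(
                        1,
                        int(round(d * rate / 1000.0 * (1.0 + rng.uniform(-config.phase_jitter, config.phase_jitter)))),
                    )
                    for d in config.phase_durations_ms
                ]
            )
            cyc_len = int(durs.sum())
            ph = np.repeat(np.arange(1, N_PHASES + 1), durs)
            phase_labels.append(ph)
            mode_labels.append(np.full(cyc_len, m, dtype=np.int64))
            cycle_frac.append(np.arange(cyc_len) / cyc_len)
            cursor += cyc_len
    return (
        np.concatenate(phase_labels),
        np.concatenate(mode_labels),
        np.concatenate(cycle_frac),
        tuple(transition_events),
    )


def _emg_band_sos(rate: float, spectral_shift: float):
    high = _EMG_BAND_HIGH_HZ * (1.0 - spectral_shift)
    high = min(high, 0.49 * rate)
    return signal.butter(4, [_EMG_BAND_LOW_HZ, high], btype="bandpass", fs=rate, output="sos")


def generate_trial(config: SimulationConfig, drift: DriftState, seed) -> TrialRecording:
    """Generate one trial under a fixed drift state.

    EMG channel ``c`` during (mode m, phase p) is
    ``envelope_table[m, p, c] * stride_gain * drift.emg_scale[c] * carrier``
    plus ``noise_floor * drift.baseline_noise_scale`` white noise, where the
    carrier is unit-variance band-limited (20-400 Hz, upper corner lowered by
    ``drift.spectral_shift``) Gaussian noise.  Mechanical channels follow the
    mode's periodic profile plus measurement noise and ``drift.mech_offset``.
    """
    if config.envelope_table is None or config.mech_profile_table is None:
        raise ValueError("config is missing signal tables; use build_default_config")
    rng = np.random.default_rng(seed)
    phase, mode, frac, events = _phase_plan(config, rng)
    T = phase.shape[0]
    rate = config.sample_rate

    # mode weights crossfade over ~transition_blend_ms around each mode
    # change: motor patterns shift over a step, not at a single sample
    W = np.zeros((T, N_MODES))
    W[np.arange(T), mode] = 1.0
    blend = max(1, int(round(config.transition_blend_ms * rate / 1000.0)))
    W = uniform_filter1d(W, size=blend, axis=0, mode="nearest")
    W /= W.sum(axis=1, keepdims=True)

    env_tab = np.asarray(config.envelope_table)
    # per-sample envelope: mode-blended table value, smoothed at phase edges
    env = np.einsum("tm,tmc->tc", W, env_tab[:, phase - 1, :].transpose(1, 0, 2))
    smooth = max(1, int(round(config.envelope_smooth_ms * rate / 1000.0)))
    env = uniform_filter1d(env, size=smooth, axis=0, mode="nearest")

    # stride-to-stride gain variability per channel (within-class spread)
    cycle_id = np.concatenate(([0], np.cumsum((frac[1:] < frac[:-1]).astype(int))))
    n_cycles = int(cycle_id[-1]) + 1
    gains = np.exp(config.stride_gain_sd * rng.standard_normal((n_cycles, config.n_emg_channels)))
    gain = gains[cycle_id, :]  # (T, n_emg)

    sos = _emg_band_sos(rate, drift.spectral_shift)
    emg = np.empty((config.n_emg_channels, T))
    for c in range(config.n_emg_channels):
        carrier = signal.sosfilt(sos, rng.standard_normal(T))
        sd = carrier.std()
        if sd > 0:
            carrier = carrier / sd
        baseline = rng.standard_normal(T)
        emg[c] = (
            env[:, c] * gain[:, c] * drift.emg_scale[c] * carrier
            + config.noise_floor * drift.baseline_noise_scale * baseline
        )

    prof = np.asarray(config.mech_profile_table)  # (modes, n_mech, 5)
    p = np.einsum("tm,mcp->tcp", W, prof)  # (T, n_mech, 5) mode-blended
    mech_gains = np.exp(
        config.mech_gain_sd * rng.standard_normal((n_cycles, config.n_mech_channels))
    )
    mech_gain = mech_gains[cycle_id, :]  # (T, n_mech) stride-to-stride variability
    mech = (
        p[:, :, 0]
        + mech_gain
        * (
            p[:, :, 1] * np.sin(2 * np.pi * frac[:, None] + p[:, :, 2])
            + p[:, :, 3] * np.sin(4 * np.pi * frac[:, None] + p[:, :, 4])
        )
    ).T
    mech = mech + config.mech_noise_sd * rng.standard_normal(mech.shape)
    mech = mech + drift.mech_offset[:, None]

    return TrialRecording(
        emg=emg,
        mech=mech,
        phase_labels=phase,
        mode_labels=mode,
        transition_events=events,
        sample_rate=rate,
    )


def generate_session(
    config: SimulationConfig,
    schedule: DriftSchedule,
    n_training_reps: int = 3,
    n_testing_trials: int = 10,
) -> tuple[list[TrialRecording], list[TrialRecording]]:
    """Generate a full experimental session.

    Training repetitions are generated at identity drift (the initial
    training session); testing trial ``k`` (1-based) is generated with the
    drift state advanced through trials ``1..k``.  All trial seeds derive
    deterministically from ``config.seed``.
    """
    if n_training_reps < 1:
        raise ValueError("n_training_reps must be >= 1")
    if n_testing_trials < 0:
        raise ValueError("n_testing_trials must be >= 0")
    ss = np.random.SeedSequence(config.seed, spawn_key=(7,))
    children = ss.spawn(n_training_reps + n_testing_trials)
    identity = DriftState.identity(config.n_emg_channels, config.n_mech_channels)
    training = [generate_trial(config, identity, children[i]) for i in range(n_training_reps)]
    testing: list[TrialRecording] = []
    state = identity
    for k in range(1, n_testing_trials + 1):
        state = advance_drift(state, schedule, k)
        testing.append(generate_trial(config, state, children[n_training_reps + k - 1]))
    return training, testing
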
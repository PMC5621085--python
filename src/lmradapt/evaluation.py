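"""Evaluation metrics and the two experiment harnesses.

Performance is reported separately for *static states* (stretches of a
single locomotion mode, scored by voted-label classification accuracy) and
*transitional periods* (from the foot contact preceding a terrain change to
the end of single stance in the following gait cycle, scored by missed
transitions: the transition is missed when the voted label at the period's
end is not the new mode).

Two harnesses mirror the study designs the drift model emulates:

* Part 1 — one training session (three repetitions of the task sequence)
  and ten gradually drifting testing trials, classified by the static
  baseline and each adaptation strategy on identical data.
* Part 2 — twenty alternating adaptive/non-adaptive online trials (50 ms
  decision increment) with an abrupt don/doff-analog shift after the fifth
  trial of each arm; the adaptive arm retrains only from its own trials.
  A proxy count of stance-phase recognition-error runs during stair/ramp
  descent stands in for user-reported instability events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lmradapt.adaptation import run_adaptive_session
from lmradapt.bank import DecisionStream, SearchSpec, train_phase_bank
from lmradapt.features import FeatureSet, deadzone_from_trials, extract_features
from lmradapt.simulate import (
    MODE_INDEX,
    SINGLE_STANCE_PHASE,
    STANCE_PHASES,
    DriftSchedule,
    DriftState,
    SimulationConfig,
    TrialRecording,
    advance_drift,
    build_default_config,
    generate_session,
    generate_trial,
)

_DESCENT_MODES = (MODE_INDEX["RD"], MODE_INDEX["SD"])


@dataclass(frozen=True)
class TransitionalPeriod:
    start_sample: int
    end_sample: int
    from_mode: int
    to_mode: int


@dataclass
class SessionReport:
    """Per-trial summary of one strategy's session."""

    strategy: str
    seed: int
    schedule_kind: str
    accuracy: list[float] = field(default_factory=list)        # voted, static windows, %
    raw_accuracy: list[float] = field(default_factory=list)    # pre-vote, diagnostics
    missed: list[int] = field(default_factory=list)
    n_transitions: list[int] = field(default_factory=list)
    instability: list[int] = field(default_factory=list)
    augmented: list[int] = field(default_factory=list)

    @property
    def total_missed(self) -> int:
        return int(sum(self.missed))

    @property
    def total_transitions(self) -> int:
        return int(sum(self.n_transitions))

    def to_frame(self) -> pd.DataFrame:
        n = len(self.accuracy)
        return pd.DataFrame(
            {
                "trial": np.arange(1, n + 1),
                "strategy": self.strategy,
                "static_accuracy_pct": self.accuracy,
                "raw_accuracy_pct": self.raw_accuracy,
                "missed_transitions": self.missed,
                "n_transitions": self.n_transitions,
                "instability_proxy": self.instability,
                "n_augmented": self.augmented,
            }
        )


# ---------------------------------------------------------------------------
# transitional periods and metrics
# ---------------------------------------------------------------------------

def _phase_onsets(phase_labels: np.ndarray, phase: int) -> np.ndarray:
    is_p = phase_labels == phase
    starts = is_p & ~np.concatenate(([False], is_p[:-1]))
    return np.flatnonzero(starts)


def find_transitional_periods(trial: TrialRecording) -> list[TransitionalPeriod]:
    """One period per transition event.

    The period starts at the foot-contact (phase-1 onset) at or before the
    event, and ends when single stance (phase 2) of the *following* gait
    cycle ends.
    """
    onsets = _phase_onsets(trial.phase_labels, 1)
    periods: list[TransitionalPeriod] = []
    for sample, from_mode, to_mode in trial.transition_events:
        before = onsets[onsets <= sample]
        if before.size == 0:
            raise ValueError("transition with no bracketing foot contact")
        start = int(before[-1])
        later = onsets[onsets > start]
        if later.size == 0:
            raise ValueError("transition too close to the end of the trial")
        next_cycle = int(later[0])
        ss = np.flatnonzero(
            (trial.phase_labels == SINGLE_STANCE_PHASE)
            & (np.arange(trial.n_samples) >= next_cycle)
        )
        if ss.size == 0:
            raise ValueError("no single-stance phase after the transition")
        ss_start = int(ss[0])
        after = np.flatnonzero(
            (trial.phase_labels != SINGLE_STANCE_PHASE)
            & (np.arange(trial.n_samples) > ss_start)
        )
        end = int(after[0] - 1) if after.size else trial.n_samples - 1
        periods.append(TransitionalPeriod(start, end, int(from_mode), int(to_mode)))
    return periods


def static_mask(trial: TrialRecording, last_sample: np.ndarray) -> np.ndarray:
    """True for windows (by final sample) outside every transitional period."""
    periods = find_transitional_periods(trial)
    last = np.asarray(last_sample)
    static = np.ones(last.shape[0], dtype=bool)
    for per in periods:
        static &= ~((last >= per.start_sample) & (last <= per.end_sample))
    return static


def static_accuracy(decisions: DecisionStream, mask: np.ndarray, *,
                    use_raw: bool = False) -> float:
    """Percent of static windows whose (voted) label matches the true mode."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no static windows to score")
    labels = decisions.raw_label if use_raw else decisions.voted_label
    return 100.0 * float((labels[mask] == decisions.true_mode[mask]).sum()) / n


def missed_transitions(decisions: DecisionStream, periods: list[TransitionalPeriod]) -> int:
    """Count periods whose last in-period decision is not the new mode."""
    missed = 0
    for per in periods:
        idx = np.flatnonzero(decisions.last_sample <= per.end_sample)
        if idx.size == 0:
            raise ValueError("transitional period contains no decision windows")
        if int(decisions.voted_label[idx[-1]]) != per.to_mode:
            missed += 1
    return missed


def instability_proxy(decisions: DecisionStream, min_run: int = 5) -> int:
    """Proxy for gait-instability events caused by recognition errors.

    Counts maximal runs (length >= ``min_run`` decisions) of wrong voted
    labels during stance phases of descent modes (RD/SD), where misclassified
    prosthesis behaviour is most destabilizing.  This is a synthetic stand-in
    for a user-triggered instability report, not a human measure.
    """
    wrong = decisions.voted_label != decisions.true_mode
    eligible = (
        wrong
        & np.isin(decisions.true_mode, _DESCENT_MODES)
        & np.isin(decisions.phase, STANCE_PHASES)
    )
    count = 0
    run = 0
    for flag in np.concatenate([eligible, [False]]):
        if flag:
            run += 1
        else:
            if run >= min_run:
                count += 1
            run = 0
    return count


def score_trial(trial: TrialRecording, stream: DecisionStream,
                vote_len: int = 5) -> dict:
    periods = find_transitional_periods(trial)
    mask = static_mask(trial, stream.last_sample)
    return {
        "accuracy": static_accuracy(stream, mask),
        "raw_accuracy": static_accuracy(stream, mask, use_raw=True),
        "missed": missed_transitions(stream, periods),
        "n_transitions": len(periods),
        "instability": instability_proxy(stream, min_run=vote_len),
    }


# ---------------------------------------------------------------------------
# experiment harnesses
# ---------------------------------------------------------------------------

def _train_from_trials(training, *, increment_ms: float, search_spec, seed: int):
    deadzone = deadzone_from_trials(training)
    feats = [
        extract_features(t, increment_ms=increment_ms, deadzone=deadzone, trial_index=i)
        for i, t in enumerate(training)
    ]
    X = np.vstack([f.X for f in feats])
    phase = np.concatenate([f.phase for f in feats])
    y = np.concatenate([f.true_mode for f in feats])
    bank = train_phase_bank(X, phase, y, search_spec=search_spec, seed=seed)
    return bank, (X, phase, y), deadzone


def _session_report(strategy, seed, schedule_kind, trials, streams, state) -> SessionReport:
    rep = SessionReport(strategy=strategy, seed=seed, schedule_kind=schedule_kind)
    for trial, stream, hist in zip(
        trials, streams, state.history if state.history else [{}] * len(trials)
    ):
        s = score_trial(trial, stream)
        rep.accuracy.append(s["accuracy"])
        rep.raw_accuracy.append(s["raw_accuracy"])
        rep.missed.append(s["missed"])
        rep.n_transitions.append(s["n_transitions"])
        rep.instability.append(s["instability"])
        rep.augmented.append(int(hist.get("n_selected", 0)))
    return rep


def run_part1_experiment(
    seed: int,
    sim_config: SimulationConfig | None = None,
    schedule: DriftSchedule | None = None,
    strategies: tuple[str, ...] = ("none", "eba", "lift", "tsvm"),
    *,
    n_training_reps: int = 3,
    n_testing_trials: int = 10,
    tau: float = 0.6,
    m: int = 5,
    vote_len: int = 5,
    increment_ms: float = 20.0,
    search_spec: SearchSpec | None = None,
) -> dict[str, SessionReport]:
    """Gradual-drift experiment: every strategy scored on identical trials."""
    config = sim_config if sim_config is not None else build_default_config(seed)
    if schedule is None:
        schedule = DriftSchedule(kind="gradual", seed=seed)
    training, testing = generate_session(config, schedule, n_training_reps, n_testing_trials)
    bank, base, deadzone = _train_from_trials(
        training, increment_ms=increment_ms, search_spec=search_spec, seed=seed
    )
    test_feats = [
        extract_features(t, increment_ms=increment_ms, deadzone=deadzone, trial_index=k)
        for k, t in enumerate(testing, start=1)
    ]
    reports: dict[str, SessionReport] = {}
    for strategy in strategies:
        streams, state = run_adaptive_session(
            strategy, bank, base, test_feats,
            tau=tau, m=m, vote_len=vote_len, retrain_seed=seed,
        )
        reports[strategy] = _session_report(
            strategy, seed, schedule.kind, testing, streams, state
        )
    return reports


def run_part2_experiment(
    seed: int,
    sim_config: SimulationConfig | None = None,
    *,
    n_training_reps: int = 3,
    n_trials_per_arm: int = 10,
    abrupt_after_arm_trial: int = 5,
    session_drift_rate: float = 0.015,
    tau: float = 0.6,
    vote_len: int = 5,
    increment_ms: float = 50.0,
    search_spec: SearchSpec | None = None,
) -> dict[str, SessionReport]:
    """Abrupt-shift online experiment with alternating adaptive arms.

    Global trials 1..2n alternate adaptive (odd) and non-adaptive (even);
    the abrupt drift step lands before global trial
    ``2 * abrupt_after_arm_trial + 1``, i.e. between the fifth and sixth
    trial of each arm under the defaults.  A mild gradual drift
    (``session_drift_rate``) runs throughout the session on top of the step:
    signals keep evolving after a don/doff, which is what makes the
    non-adaptive arm decay rather than plateau.
    """
    config = sim_config if sim_config is not None else build_default_config(seed)
    n_total = 2 * n_trials_per_arm
    schedule = DriftSchedule(
        kind="abrupt", abrupt_trial_index=2 * abrupt_after_arm_trial + 1, seed=seed
    )
    creep = DriftSchedule(kind="gradual", gradual_rate=session_drift_rate, seed=seed)
    training, _ = generate_session(config, schedule, n_training_reps, 0)
    bank, base, deadzone = _train_from_trials(
        training, increment_ms=increment_ms, search_spec=search_spec, seed=seed
    )

    ss = np.random.SeedSequence(config.seed, spawn_key=(8,))
    children = ss.spawn(n_total)
    state = DriftState.identity(config.n_emg_channels, config.n_mech_channels)
    arms: dict[str, list[TrialRecording]] = {"eba": [], "none": []}
    for g in range(1, n_total + 1):
        state = advance_drift(state, creep, g)
        state = advance_drift(state, schedule, g)
        trial = generate_trial(config, state, children[g - 1])
        arms["eba" if g % 2 == 1 else "none"].append(trial)

    reports: dict[str, SessionReport] = {}
    for strategy, trials in arms.items():
        feats = [
            extract_features(t, increment_ms=increment_ms, deadzone=deadzone, trial_index=k)
            for k, t in enumerate(trials, start=1)
        ]
        streams, st = run_adaptive_session(
            strategy, bank, base, feats, tau=tau, vote_len=vote_len, retrain_seed=seed
        )
        reports[strategy] = _session_report(strategy, seed, "abrupt", trials, streams, st)
    return reports
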
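"""Unsupervised classifier adaptation across testing trials.

Three self-adaptation strategies keep the phase-classifier bank aligned with
drifting input signals, without ever seeing a true testing label:

* **EBA** (entropy-based adaptation) — after each trial, windows whose
  decision entropy fell strictly below a threshold (default tau = 0.6 nats)
  join the retraining set with their predicted mode as pseudo-label.
* **LIFT** (LearnIng From Testing data) — a window joins the retraining set
  when exactly one of the five one-against-all binaries claims it; the
  claiming binary's mode is the pseudo-label.
* **TSVM** (transductive margin-classifier adaptation) — each binary
  hyperplane is updated by iteratively moving, per side, up to ``m``
  within-margin unlabeled points (signed distance in (0, 1), closest to 1)
  into the labeled set until every testing window is assigned a class.

All strategies retrain after each full trial, never mid-trial, reusing the
hyperparameters found in the initial training search.  Pseudo-labels come
from pre-vote raw labels, and each window augments only the classifier of
its own gait phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from lmradapt.bank import (
    DecisionStream,
    PhaseClassifierBank,
    classify_stream,
    refit_bank,
)
from lmradapt.features import FeatureSet
from lmradapt.simulate import N_MODES, N_PHASES

STRATEGIES = ("none", "eba", "lift", "tsvm")


@dataclass
class AdaptationState:
    """Base training set plus the growing pseudo-labeled augmented set."""

    base_X: np.ndarray
    base_phase: np.ndarray
    base_y: np.ndarray
    strategy: str = "none"
    tau: float = 0.6
    m: int = 5
    retrain_seed: int = 0
    max_augmented: int | None = None     # optional FIFO cap; unlimited by default
    aug_X: list = field(default_factory=list)
    aug_phase: list = field(default_factory=list)
    aug_y: list = field(default_factory=list)
    aug_trial: list = field(default_factory=list)
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.m < 1:
            raise ValueError("m must be >= 1")

    @property
    def n_augmented(self) -> int:
        return sum(x.shape[0] for x in self.aug_X)

    def add(self, trial_index: int, X: np.ndarray, phase: np.ndarray, y: np.ndarray) -> None:
        phase = np.asarray(phase)
        if phase.size and ((phase < 1) | (phase > N_PHASES)).any():
            raise ValueError("augmented sample with unknown gait phase")
        self.aug_X.append(np.asarray(X, dtype=float))
        self.aug_phase.append(phase)
        self.aug_y.append(np.asarray(y))
        self.aug_trial.append(np.full(phase.shape[0], trial_index))
        if self.max_augmented is not None:
            self._evict()

    def _evict(self) -> None:
        """FIFO eviction down to max_augmented, oldest windows first."""
        excess = self.n_augmented - self.max_augmented
        while excess > 0 and self.aug_X:
            head = self.aug_X[0].shape[0]
            drop = min(head, excess)
            if drop == head:
                for lst in (self.aug_X, self.aug_phase, self.aug_y, self.aug_trial):
                    lst.pop(0)
            else:
                self.aug_X[0] = self.aug_X[0][drop:]
                self.aug_phase[0] = self.aug_phase[0][drop:]
                self.aug_y[0] = self.aug_y[0][drop:]
                self.aug_trial[0] = self.aug_trial[0][drop:]
            excess -= drop

    def combined(self):
        if not self.aug_X:
            return self.base_X, self.base_phase, self.base_y
        return (
            np.vstack([self.base_X] + self.aug_X),
            np.concatenate([self.base_phase] + self.aug_phase),
            np.concatenate([self.base_y] + self.aug_y),
        )


# ---------------------------------------------------------------------------
# selection rules
# ---------------------------------------------------------------------------

def eba_select(decisions: DecisionStream, tau: float):
    """Indices and pseudo-labels of windows with entropy strictly below tau."""
    sel = np.flatnonzero(decisions.entropy < tau)
    return sel, decisions.raw_label[sel]


def lift_select(binary_decisions: np.ndarray):
    """Indices and pseudo-labels of windows claimed by exactly one OAA binary.

    ``binary_decisions``: (n, 5) array of {0, 1} (or bool) binary outputs.
    """
    b = np.asarray(binary_decisions)
    if b.ndim != 2 or b.shape[1] != N_MODES:
        raise ValueError("binary decisions must be an (n, 5) array")
    if not np.isin(b, (0, 1)).all():
        raise ValueError("binary decisions must be 0/1")
    b = b.astype(bool)
    sel = np.flatnonzero(b.sum(axis=1) == 1)
    return sel, b[sel].argmax(axis=1)


# ---------------------------------------------------------------------------
# transductive adaptation
# ---------------------------------------------------------------------------

def tsvm_adapt(
    X_lab: np.ndarray,
    y_lab: np.ndarray,
    X_unlab: np.ndarray,
    *,
    C: float = 1.0,
    gamma: float | str = "scale",
    m: int = 5,
    max_iter: int = 500,
):
    """Transductive update of one binary margin classifier.

    Iteratively: fit the hyperplane on the labeled set; among still-unlabeled
    points whose signed distance lies strictly inside the margin (0 < d < 1
    on the positive side, -1 < d < 0 on the negative side), move up to ``m``
    per side — those with distance closest to 1 — into the labeled set with
    their predicted side as label; refit.  When no point qualifies (or
    ``max_iter`` is hit, flagged in the result), all remaining points are
    assigned by the current hyperplane's sign.

    Returns ``(classifier, labels, info)`` with ``labels`` in {-1, +1} for
    every unlabeled point and ``info`` carrying iteration diagnostics.
    """
    y_lab = np.asarray(y_lab)
    if not ((y_lab == 1).any() and (y_lab == -1).any()):
        raise ValueError("labeled set must contain both classes")
    X_l = np.asarray(X_lab, dtype=float)
    y_l = y_lab.copy()
    X_u = np.asarray(X_unlab, dtype=float)
    n_u = X_u.shape[0]
    labels = np.zeros(n_u, dtype=int)
    remaining = np.arange(n_u)
    moved_per_iter: list[int] = []
    exhausted = False

    clf = SVC(C=C, gamma=gamma, kernel="rbf")
    clf.fit(X_l, y_l)
    it = 0
    while remaining.size:
        if it >= max_iter:
            exhausted = True
            break
        d = clf.decision_function(X_u[remaining])
        pos = np.flatnonzero((d > 0) & (d < 1))
        neg = np.flatnonzero((d < 0) & (d > -1))
        chosen_pos = pos[np.argsort(-d[pos])[:m]]
        chosen_neg = neg[np.argsort(d[neg])[:m]]
        n_moved = chosen_pos.size + chosen_neg.size
        if n_moved == 0:
            break
        moved = np.concatenate([remaining[chosen_pos], remaining[chosen_neg]])
        new_y = np.concatenate(
            [np.ones(chosen_pos.size, dtype=int), -np.ones(chosen_neg.size, dtype=int)]
        )
        labels[moved] = new_y
        X_l = np.vstack([X_l, X_u[moved]])
        y_l = np.concatenate([y_l, new_y])
        keep = np.ones(remaining.size, dtype=bool)
        keep[np.concatenate([chosen_pos, chosen_neg])] = False
        remaining = remaining[keep]
        moved_per_iter.append(int(n_moved))
        clf = SVC(C=C, gamma=gamma, kernel="rbf")
        clf.fit(X_l, y_l)
        it += 1

    if remaining.size:
        d = clf.decision_function(X_u[remaining])
        labels[remaining] = np.where(d >= 0, 1, -1)
    info = {
        "n_iterations": len(moved_per_iter),
        "moved_per_iteration": moved_per_iter,
        "max_iter_exhausted": exhausted,
    }
    return clf, labels, info


def tsvm_multiclass(
    bank: PhaseClassifierBank,
    X_lab: np.ndarray,
    phase_lab: np.ndarray,
    y_lab: np.ndarray,
    X_unlab: np.ndarray,
    phase_unlab: np.ndarray,
    *,
    m: int = 5,
    max_iter: int = 500,
    retrain_seed: int = 0,
    calibration_folds: int = 3,
):
    """Transductive adaptation of the whole phase bank.

    Runs :func:`tsvm_adapt` independently for each of the five binary
    problems within each phase (in the phase's standardized feature space,
    with its frozen C and gamma).  The multiclass label of each unlabeled
    window is the argmax of the calibrated posterior under the transductively
    updated binaries; the returned bank is then refit on labeled plus
    newly-labeled data so its calibrators stay consistent.

    Returns ``(updated bank, labels, info)``.
    """
    X_unlab = np.asarray(X_unlab, dtype=float)
    if X_unlab.shape[0] == 0:
        return bank, np.zeros(0, dtype=int), {}
    phase_lab = np.asarray(phase_lab)
    phase_unlab = np.asarray(phase_unlab)
    y_lab = np.asarray(y_lab)
    labels = np.zeros(X_unlab.shape[0], dtype=int)
    info: dict[int, dict] = {}
    for p in np.unique(phase_unlab):
        p = int(p)
        model = bank.model(p)
        rows_l = phase_lab == p
        rows_u = phase_unlab == p
        Xs_l = model.standardizer.transform(np.asarray(X_lab, dtype=float)[rows_l])
        Xs_u = model.standardizer.transform(X_unlab[rows_u])
        yp = y_lab[rows_l]
        margins = np.zeros((Xs_u.shape[0], N_MODES))
        phase_info = {}
        for k in range(N_MODES):
            clf, _, it_info = tsvm_adapt(
                Xs_l, np.where(yp == k, 1, -1), Xs_u,
                C=model.C, gamma=model.gamma, m=m, max_iter=max_iter,
            )
            margins[:, k] = clf.decision_function(Xs_u)
            phase_info[k] = it_info
        labels[rows_u] = model.posteriors_from_margins(margins).argmax(axis=1)
        info[p] = phase_info

    new_bank = refit_bank(
        bank,
        np.vstack([X_lab, X_unlab]),
        np.concatenate([phase_lab, phase_unlab]),
        np.concatenate([y_lab, labels]),
        calibration_folds=calibration_folds,
        seed=retrain_seed,
    )
    return new_bank, labels, info


# ---------------------------------------------------------------------------
# retraining loop
# ---------------------------------------------------------------------------

def retrain(bank: PhaseClassifierBank, state: AdaptationState,
            calibration_folds: int = 3) -> PhaseClassifierBank:
    """Refit the bank on base plus augmented data with frozen hyperparameters.

    With an empty augmented set the bank is returned unchanged (refitting on
    identical data with the same seed would reproduce it).
    """
    if state.n_augmented == 0:
        return bank
    X, phase, y = state.combined()
    return refit_bank(bank, X, phase, y,
                      calibration_folds=calibration_folds, seed=state.retrain_seed)


def run_adaptive_session(
    strategy: str,
    bank: PhaseClassifierBank,
    base: tuple[np.ndarray, np.ndarray, np.ndarray],
    trials: list[FeatureSet],
    *,
    tau: float = 0.6,
    m: int = 5,
    vote_len: int = 5,
    retrain_seed: int = 0,
    calibration_folds: int = 3,
    max_augmented: int | None = None,
) -> tuple[list[DecisionStream], AdaptationState]:
    """Classify an ordered sequence of testing trials with trial-wise adaptation.

    Trial ``k`` is classified with the bank as updated after trial ``k - 1``
    (the first trial uses the initial bank).  After each trial the strategy's
    selection rule runs and the bank is retrained; ``strategy='none'`` skips
    both and reproduces the static baseline.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    state = AdaptationState(
        base_X=np.asarray(base[0], dtype=float),
        base_phase=np.asarray(base[1]),
        base_y=np.asarray(base[2]),
        strategy=strategy,
        tau=tau,
        m=m,
        retrain_seed=retrain_seed,
        max_augmented=max_augmented,
    )
    streams: list[DecisionStream] = []
    current = bank
    for k, fs in enumerate(trials, start=1):
        stream = classify_stream(
            current, fs.X, fs.phase, fs.true_mode, fs.last_sample, vote_len=vote_len
        )
        streams.append(stream)
        n_selected = 0
        selected_idx = np.empty(0, dtype=int)
        extra: dict = {}
        if strategy == "eba":
            idx, labels = eba_select(stream, tau)
            n_selected = idx.size
            selected_idx = idx
            if n_selected:
                state.add(k, fs.X[idx], fs.phase[idx], labels)
                current = retrain(current, state, calibration_folds)
        elif strategy == "lift":
            idx, labels = lift_select(stream.binary_pos.astype(int))
            n_selected = idx.size
            selected_idx = idx
            if n_selected:
                state.add(k, fs.X[idx], fs.phase[idx], labels)
                current = retrain(current, state, calibration_folds)
        elif strategy == "tsvm":
            X_lab, phase_lab, y_lab = state.combined()
            current, labels, info = tsvm_multiclass(
                current, X_lab, phase_lab, y_lab, fs.X, fs.phase,
                m=m, retrain_seed=retrain_seed, calibration_folds=calibration_folds,
            )
            n_selected = len(fs)
            selected_idx = np.arange(len(fs))
            state.add(k, fs.X, fs.phase, labels)
            extra["tsvm_iterations"] = {
                p: {mode: d["n_iterations"] for mode, d in per.items()}
                for p, per in info.items()
            }
        state.history.append(
            {"trial": k, "n_selected": int(n_selected),
             "n_augmented_total": int(state.n_augmented),
             "selected_indices": selected_idx, **extra}
        )
    return streams, state
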
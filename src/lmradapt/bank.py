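"""Phase-dependent bank of one-against-all RBF margin classifiers.

One multiclass classifier per gait phase (five in total), each built from
five binary RBF-kernel support-vector classifiers (mode k vs rest) sharing a
per-phase feature standardizer.  Each binary margin is mapped to a
probability with a Platt sigmoid fitted on cross-validated margins; the five
one-against-all probabilities are renormalized into a 5-class posterior.
Decision confidence is the Shannon entropy of that posterior,
``E(n) = -sum_k p_k(n) ln p_k(n)`` (nats, max ``ln 5``), and a trailing
majority vote over recent decisions smooths the label stream.

Kernels are precomputed per phase (one pairwise squared-distance matrix,
re-exponentiated for each candidate gamma), which makes the (C, gamma) grid
search and the repeated retraining of the adaptation loop cheap.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from lmradapt.simulate import MODES, N_MODES, N_PHASES

LN_N_MODES = float(np.log(N_MODES))


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclass
class Standardizer:
    mean: np.ndarray
    scale: np.ndarray
    constant_mask: np.ndarray  # True where the training column had zero variance

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale


def fit_standardizer(X: np.ndarray) -> Standardizer:
    """Per-feature mean/scale (population std); zero-variance columns pass through."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    constant = scale == 0.0
    scale = np.where(constant, 1.0, scale)
    return Standardizer(mean=mean, scale=scale, constant_mask=constant)


# ---------------------------------------------------------------------------
# Platt sigmoid calibration
# ---------------------------------------------------------------------------

@dataclass
class PlattCalibrator:
    """p(y=1 | margin f) = 1 / (1 + exp(A f + B)), fitted by regularized MLE."""

    A: float
    B: float

    def predict(self, margins: np.ndarray) -> np.ndarray:
        z = self.A * np.asarray(margins, dtype=float) + self.B
        return 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))


def fit_platt(margins: np.ndarray, y: np.ndarray) -> PlattCalibrator:
    """Fit the sigmoid on margins with Platt's smoothed targets."""
    f = np.asarray(margins, dtype=float)
    y = np.asarray(y)
    pos = y == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    t = np.where(pos, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(ab):
        z = np.clip(ab[0] * f + ab[1], -500, 500)
        # cross-entropy of targets t against sigmoid(-z) written stably
        return float(np.sum(t * z + np.log1p(np.exp(-z))))

    b0 = np.log((n_neg + 1.0) / (n_pos + 1.0))
    res = minimize(nll, x0=np.array([-1.0, b0]), method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 400})
    return PlattCalibrator(A=float(res.x[0]), B=float(res.x[1]))


# ---------------------------------------------------------------------------
# bank structures
# ---------------------------------------------------------------------------

@dataclass
class SearchSpec:
    """Hyperparameter grid for the per-phase (C, gamma) search."""

    C_grid: tuple[float, ...] = (2.0 ** -3, 2.0 ** 2, 2.0 ** 7)
    gamma_grid: tuple[float, ...] = (2.0 ** -9, 2.0 ** -5, 2.0 ** -1)
    n_folds: int = 3
    calibration_folds: int = 3


@dataclass
class PhaseModel:
    """One gait phase's OAA classifier: 5 binaries on a shared precomputed kernel."""

    standardizer: Standardizer
    C: float
    gamma: float
    X_train: np.ndarray                  # standardized training features
    svms: list                           # 5 SVC(kernel='precomputed')
    calibrators: list                    # 5 PlattCalibrator
    n_train: int = 0

    def margins(self, X_std: np.ndarray) -> np.ndarray:
        K = rbf_kernel_matrix(X_std, self.X_train, self.gamma)
        return np.column_stack([svm.decision_function(K) for svm in self.svms])

    def posteriors_from_margins(self, margins: np.ndarray) -> np.ndarray:
        scores = np.column_stack(
            [self.calibrators[k].predict(margins[:, k]) for k in range(N_MODES)]
        )
        total = scores.sum(axis=1, keepdims=True)
        uniform = np.full_like(scores, 1.0 / N_MODES)
        return np.where(total > 0, scores / np.where(total == 0, 1.0, total), uniform)


@dataclass
class PhaseClassifierBank:
    """Five phase-indexed OAA classifiers with shared contracts."""

    phases: dict[int, PhaseModel]
    search_record: dict[int, dict] = field(default_factory=dict)
    fingerprint: str = ""
    seed: int = 0

    def model(self, phase: int) -> PhaseModel:
        if phase not in self.phases:
            raise ValueError(f"unknown gait phase {phase}; expected 1..{N_PHASES}")
        return self.phases[phase]


@dataclass
class DecisionStream:
    """Per-window decisions of one trial, in stream order.

    ``raw_label`` is the argmax of the calibrated posterior before voting;
    ``voted_label`` is the trailing-majority-vote label; ``binary_pos`` marks,
    per OAA binary, whether that classifier claimed the window (calibrated
    binary probability > 0.5).
    """

    raw_label: np.ndarray
    voted_label: np.ndarray
    posterior: np.ndarray    # (n, 5)
    entropy: np.ndarray
    margins: np.ndarray      # (n, 5)
    binary_pos: np.ndarray   # (n, 5) bool
    phase: np.ndarray
    true_mode: np.ndarray
    last_sample: np.ndarray

    def __len__(self) -> int:
        return self.raw_label.shape[0]


# ---------------------------------------------------------------------------
# kernels and training
# ---------------------------------------------------------------------------

def rbf_kernel_matrix(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    return np.exp(-gamma * cdist(A, B, metric="sqeuclidean"))


def _fit_oaa(K: np.ndarray, y: np.ndarray, C: float) -> list:
    svms = []
    for k in range(N_MODES):
        y_bin = np.where(y == k, 1, -1)
        svm = SVC(C=C, kernel="precomputed")
        svm.fit(K, y_bin)
        svms.append(svm)
    return svms


def _oaa_margins(svms, K_test: np.ndarray) -> np.ndarray:
    return np.column_stack([svm.decision_function(K_test) for svm in svms])


def _grid_search(D: np.ndarray, y: np.ndarray, spec: SearchSpec, seed: int):
    """Pick (C, gamma) maximizing cross-validated OAA accuracy for one phase."""
    n_folds = min(spec.n_folds, int(np.bincount(y, minlength=N_MODES).min()))
    n_folds = max(n_folds, 2)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros_like(y), y))
    best = (-1.0, None, None)
    record = []
    for gamma in spec.gamma_grid:
        K = np.exp(-gamma * D)
        for C in spec.C_grid:
            correct = 0
            for tr, va in folds:
                svms = _fit_oaa(K[np.ix_(tr, tr)], y[tr], C)
                pred = _oaa_margins(svms, K[np.ix_(va, tr)]).argmax(axis=1)
                correct += int((pred == y[va]).sum())
            acc = correct / y.shape[0]
            record.append({"C": C, "gamma": gamma, "cv_accuracy": acc})
            if acc > best[0]:
                best = (acc, C, gamma)
    return best[1], best[2], best[0], record


def _calibrate(K: np.ndarray, y: np.ndarray, C: float, n_folds: int, seed: int):
    """Platt sigmoids per binary, fitted on out-of-fold margins."""
    n_folds = max(2, min(n_folds, int(np.bincount(y, minlength=N_MODES).min())))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.zeros((y.shape[0], N_MODES))
    for tr, va in skf.split(np.zeros_like(y), y):
        svms = _fit_oaa(K[np.ix_(tr, tr)], y[tr], C)
        oof[va] = _oaa_margins(svms, K[np.ix_(va, tr)])
    return [fit_platt(oof[:, k], np.where(y == k, 1, -1)) for k in range(N_MODES)]


def _fit_phase_model(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    gamma: float,
    calibration_folds: int,
    seed: int,
) -> PhaseModel:
    std = fit_standardizer(X)
    Xs = std.transform(X)
    D = cdist(Xs, Xs, metric="sqeuclidean")
    K = np.exp(-gamma * D)
    svms = _fit_oaa(K, y, C)
    calibrators = _calibrate(K, y, C, calibration_folds, seed)
    return PhaseModel(
        standardizer=std, C=C, gamma=gamma, X_train=Xs,
        svms=svms, calibrators=calibrators, n_train=X.shape[0],
    )


def _training_fingerprint(X, phase, y, seed: int) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(phase).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    h.update(str(seed).encode())
    return h.hexdigest()[:16]


def train_phase_bank(
    X: np.ndarray,
    phase: np.ndarray,
    y: np.ndarray,
    search_spec: SearchSpec | None = None,
    seed: int = 0,
) -> PhaseClassifierBank:
    """Train the five-phase bank from labelled feature rows.

    For each phase: standardize, grid-search (C, gamma) by stratified
    cross-validation on that phase's rows, fit the five OAA binaries on the
    full phase data, and fit one Platt calibrator per binary on out-of-fold
    margins.  Every (phase, mode) cell must be non-empty.
    """
    spec = search_spec or SearchSpec()
    X = np.asarray(X, dtype=float)
    phase = np.asarray(phase)
    y = np.asarray(y)
    bank = PhaseClassifierBank(phases={}, seed=seed,
                               fingerprint=_training_fingerprint(X, phase, y, seed))
    for p in range(1, N_PHASES + 1):
        rows = phase == p
        yp = y[rows]
        for k in range(N_MODES):
            if not (yp == k).any():
                raise ValueError(
                    f"no training samples for (phase {p}, mode {MODES[k]})"
                )
        Xp = X[rows]
        std = fit_standardizer(Xp)
        Xs = std.transform(Xp)
        D = cdist(Xs, Xs, metric="sqeuclidean")
        C, gamma, cv_acc, record = _grid_search(D, yp, spec, seed)
        bank.search_record[p] = {"C": C, "gamma": gamma, "cv_accuracy": cv_acc,
                                 "grid": record}
        bank.phases[p] = _fit_phase_model(Xp, yp, C, gamma, spec.calibration_folds, seed)
    return bank


def refit_bank(
    bank: PhaseClassifierBank,
    X: np.ndarray,
    phase: np.ndarray,
    y: np.ndarray,
    calibration_folds: int = 3,
    seed: int = 0,
) -> PhaseClassifierBank:
    """Refit every phase model on new data, reusing the original (C, gamma)."""
    new = PhaseClassifierBank(
        phases={}, search_record=bank.search_record, seed=seed,
        fingerprint=_training_fingerprint(X, phase, y, seed),
    )
    for p in range(1, N_PHASES + 1):
        rows = np.asarray(phase) == p
        yp = np.asarray(y)[rows]
        for k in range(N_MODES):
            if not (yp == k).any():
                raise ValueError(f"no training samples for (phase {p}, mode {MODES[k]})")
        old = bank.model(p)
        new.phases[p] = _fit_phase_model(
            np.asarray(X, dtype=float)[rows], yp, old.C, old.gamma,
            calibration_folds, seed,
        )
    return new


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def entropy(p: np.ndarray) -> float:
    """Shannon entropy (nats) of a 5-class posterior, with 0 ln 0 = 0."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("posterior entries must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("posterior must sum to 1 within 1e-6")
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def _entropy_rows(P: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P), 0.0)
    return -terms.sum(axis=1)


def classify_window(bank: PhaseClassifierBank, fv: np.ndarray, phase: int,
                    true_mode: int = -1, last_sample: int = 0) -> DecisionStream:
    """Classify a single feature vector (a one-row decision stream, unvoted)."""
    return classify_stream(
        bank,
        np.asarray(fv, dtype=float)[None, :],
        np.array([phase]),
        np.array([true_mode]),
        np.array([last_sample]),
        vote_len=1,
    )


def classify_stream(
    bank: PhaseClassifierBank,
    X: np.ndarray,
    phase: np.ndarray,
    true_mode: np.ndarray | None = None,
    last_sample: np.ndarray | None = None,
    vote_len: int = 5,
) -> DecisionStream:
    """Route each window to its phase's classifier and majority-vote the stream."""
    X = np.asarray(X, dtype=float)
    phase = np.asarray(phase)
    n = X.shape[0]
    if true_mode is None:
        true_mode = np.full(n, -1)
    if last_sample is None:
        last_sample = np.arange(n)
    margins = np.zeros((n, N_MODES))
    posterior = np.zeros((n, N_MODES))
    binary_pos = np.zeros((n, N_MODES), dtype=bool)
    for p in np.unique(phase):
        model = bank.model(int(p))
        rows = phase == p
        Xs = model.standardizer.transform(X[rows])
        m = model.margins(Xs)
        margins[rows] = m
        posterior[rows] = model.posteriors_from_margins(m)
        binary_pos[rows] = np.column_stack(
            [model.calibrators[k].predict(m[:, k]) > 0.5 for k in range(N_MODES)]
        )
    raw = posterior.argmax(axis=1)
    voted = majority_vote(raw, vote_len)
    return DecisionStream(
        raw_label=raw,
        voted_label=voted,
        posterior=posterior,
        entropy=_entropy_rows(posterior),
        margins=margins,
        binary_pos=binary_pos,
        phase=phase.copy(),
        true_mode=np.asarray(true_mode).copy(),
        last_sample=np.asarray(last_sample).copy(),
    )


def majority_vote(raw_labels: np.ndarray, vote_len: int = 5) -> np.ndarray:
    """Trailing majority vote over the last ``vote_len`` decisions of the trial.

    The window shrinks at the start of the stream.  Ties are broken toward
    the mode whose most recent occurrence in the window is latest.
    """
    if vote_len < 1 or vote_len % 2 == 0:
        raise ValueError("vote_len must be odd and >= 1")
    raw = np.asarray(raw_labels)
    voted = np.empty_like(raw)
    for i in range(raw.shape[0]):
        win = raw[max(0, i - vote_len + 1): i + 1]
        counts = np.bincount(win, minlength=N_MODES)
        top = counts.max()
        tied = np.flatnonzero(counts == top)
        if tied.shape[0] == 1:
            voted[i] = tied[0]
        else:
            # most recent occurrence among tied labels wins
            for lab in win[::-1]:
                if lab in tied:
                    voted[i] = lab
                    break
    return voted
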
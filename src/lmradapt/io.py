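"""On-disk formats: trial files, session manifests, decision files, banks.

Trials and decisions are delimited text (CSV) for inspectability; floats are
written with ``%.17g`` so a write/read round trip is bit-exact.  A session
manifest is a YAML file listing trial files, their roles and drift metadata.
Fitted classifier banks are stored in a versioned joblib container (they
hold fitted estimators, which have no faithful text form).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from lmradapt.bank import DecisionStream, PhaseClassifierBank
from lmradapt.simulate import MODE_INDEX, MODES, TrialRecording

_FLOAT_FMT = "%.17g"
BANK_FORMAT_VERSION = 1


def write_trial(trial: TrialRecording, path) -> None:
    """Write one trial as CSV: time_ms, emg_1.., mech_1.., phase, mode."""
    n_emg = trial.emg.shape[0]
    n_mech = trial.mech.shape[0]
    cols = {"time_ms": np.arange(trial.n_samples) * 1000.0 / trial.sample_rate}
    for c in range(n_emg):
        cols[f"emg_{c + 1}"] = trial.emg[c]
    for c in range(n_mech):
        cols[f"mech_{c + 1}"] = trial.mech[c]
    cols["phase"] = trial.phase_labels
    cols["mode"] = [MODES[m] for m in trial.mode_labels]
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trial(path, sample_rate: float | None = None) -> TrialRecording:
    """Read a trial CSV back into a :class:`TrialRecording`.

    Transition events are reconstructed from the mode-label column.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    emg_cols = sorted(
        (c for c in df.columns if c.startswith("emg_")), key=lambda c: int(c.split("_")[1])
    )
    mech_cols = sorted(
        (c for c in df.columns if c.startswith("mech_")), key=lambda c: int(c.split("_")[1])
    )
    if sample_rate is None:
        t = df["time_ms"].to_numpy()
        sample_rate = 1000.0 / (t[1] - t[0]) if len(t) > 1 else 1000.0
    modes = np.array([MODE_INDEX[m] for m in df["mode"]])
    change = np.flatnonzero(modes[1:] != modes[:-1]) + 1
    events = tuple((int(i), int(modes[i - 1]), int(modes[i])) for i in change)
    return TrialRecording(
        emg=df[emg_cols].to_numpy().T,
        mech=df[mech_cols].to_numpy().T,
        phase_labels=df["phase"].to_numpy(),
        mode_labels=modes,
        transition_events=events,
        sample_rate=round(sample_rate, 6),
    )


def write_manifest(path, trial_entries: list[dict], metadata: dict | None = None) -> None:
    """Session manifest: list of {file, role, trial_index, drift} entries."""
    doc = {"format": "lmradapt-session/1", "trials": trial_entries,
           "metadata": metadata or {}}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_manifest(path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or doc.get("format") != "lmradapt-session/1":
        raise ValueError(f"{path} is not an lmradapt session manifest")
    return doc


def write_decisions(stream: DecisionStream, path, selected: np.ndarray | None = None) -> None:
    """Decision file: one row per analysis window."""
    n = len(stream)
    if selected is None:
        selected = np.zeros(n, dtype=bool)
    df = pd.DataFrame(
        {
            "window": np.arange(n),
            "last_sample": stream.last_sample,
            "phase": stream.phase,
            "true_mode": [MODES[m] if m >= 0 else "?" for m in stream.true_mode],
            "raw_label": [MODES[m] for m in stream.raw_label],
            "voted_label": [MODES[m] for m in stream.voted_label],
            "entropy": stream.entropy,
            "selected": selected.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def save_bank(bank: PhaseClassifierBank, path, config_hash: str = "",
              extra: dict | None = None) -> None:
    joblib.dump(
        {
            "format": "lmradapt-bank",
            "version": BANK_FORMAT_VERSION,
            "fingerprint": bank.fingerprint,
            "config_hash": config_hash,
            "search_record": bank.search_record,
            "extra": extra or {},
            "bank": bank,
        },
        path,
    )


def load_bank_container(path) -> dict:
    doc = joblib.load(path)
    if not isinstance(doc, dict) or doc.get("format") != "lmradapt-bank":
        raise ValueError(f"{path} is not an lmradapt bank file")
    if doc.get("version") != BANK_FORMAT_VERSION:
        raise ValueError(f"unsupported bank version {doc.get('version')}")
    return doc


def load_bank(path) -> PhaseClassifierBank:
    return load_bank_container(path)["bank"]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_provenance(path, config_obj, seed: int) -> None:
    from lmradapt import __version__

    record = {
        "config_hash": config_hash(config_obj),
        "seed": seed,
        "lmradapt_version": __version__,
    }
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
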
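"""Run configuration: defaults, YAML loading, strict validation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with field-level range validation.

    Defaults mirror the standard operating point: 160 ms analysis window,
    20 ms increment (50 ms in the online Part-2 setting), entropy threshold
    tau = 0.6 nats, TSVM batch m = 5 per class per iteration, 5-decision
    majority vote.
    """

    manifest: str | None = None
    bank: str | None = None
    output_dir: str = "."
    experiment: str = "part1"
    strategy: str = "eba"
    tau: float = 0.6
    m: int = 5
    vote_len: int = 5
    window_ms: float = 160.0
    increment_ms: float = 20.0
    deadzone_fraction: float = 0.01
    seed: int = 0
    steps_per_mode: int = 3
    n_training_reps: int = 3
    n_testing_trials: int = 10
    schedule_kind: str = "gradual"
    gradual_rate: float = 0.035
    abrupt_trial_index: int = 6
    write_plots: bool = False

    _RANGES = {
        "tau": (0.0, 10.0),
        "m": (1, 1000),
        "vote_len": (1, 99),
        "window_ms": (1.0, 5000.0),
        "increment_ms": (1.0, 5000.0),
        "deadzone_fraction": (0.0, 1.0),
        "steps_per_mode": (1, 100),
        "n_training_reps": (1, 100),
        "n_testing_trials": (0, 1000),
        "gradual_rate": (0.0, 1.0),
        "abrupt_trial_index": (1, 1000),
    }

    def __post_init__(self) -> None:
        for key, (lo, hi) in self._RANGES.items():
            v = getattr(self, key)
            if not lo <= v <= hi:
                raise ValueError(f"config key {key!r}={v} outside allowed range [{lo}, {hi}]")
        if self.strategy not in ("none", "eba", "lift", "tsvm"):
            raise ValueError(f"config key 'strategy' has unknown value {self.strategy!r}")
        if self.schedule_kind not in ("none", "gradual", "abrupt"):
            raise ValueError(f"config key 'schedule_kind' has unknown value {self.schedule_kind!r}")
        if self.experiment not in ("part1", "part2"):
            raise ValueError(f"config key 'experiment' has unknown value {self.experiment!r}")
        if self.vote_len % 2 == 0:
            raise ValueError("config key 'vote_len' must be odd")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected by name."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    doc = yaml.safe_load(p.read_text())
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValueError(f"config file {p} must contain a mapping")
    known = {f.name for f in fields(RunConfig) if not f.name.startswith("_")}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return RunConfig(**doc)
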
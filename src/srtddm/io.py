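"""Reading and writing the package's delimited-text table formats.

Trial tables and participant tables are plain CSV with a header row; RTs
are stored in milliseconds (they are converted to seconds only inside
the diffusion engine).  ``docs/schema.md`` in the repository documents
every column.  Round-trips through these functions are lossless for the
column types the pipeline uses.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import DesignConfig

__all__ = [
    "write_trials", "read_trials", "write_participants", "read_participants",
    "write_design_config", "read_design_config", "RunConfig",
]

_TRIAL_BOOL = ["correct", "deadline_exceeded", "post_feedback", "motor_regular"]
_TRIAL_INT = [
    "participant", "block", "block_pair", "trial", "stimulus_location",
    "predicted_location", "pressed_key",
]
_PARTICIPANT_BOOL = ["belief_sequenced"]
_PARTICIPANT_INT = ["participant", "free_recall_correct", "forced_choice_correct"]


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in _TRIAL_BOOL:
        if c in df.columns:
            df[c] = df[c].astype(bool)
    for c in _TRIAL_INT:
        if c in df.columns:
            df[c] = df[c].astype(np.int64)
    return df


def write_participants(participants: pd.DataFrame, path: str | Path) -> None:
    participants.to_csv(path, index=False)


def read_participants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in _PARTICIPANT_BOOL:
        if c in df.columns:
            df[c] = df[c].astype(bool)
    for c in _PARTICIPANT_INT:
        if c in df.columns:
            df[c] = df[c].astype(np.int64)
    return df


def write_design_config(config: DesignConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def read_design_config(path: str | Path) -> DesignConfig:
    with open(path) as fh:
        return DesignConfig.from_dict(yaml.safe_load(fh))


class RunConfig:
    """Sectioned run configuration for the command-line pipeline.

    Known sections: ``design``, ``scenario``, ``prep``, ``stats``,
    ``model``, ``sampler``; global keys: ``seed``, ``out_dir``,
    ``verbosity``.  Unknown keys are rejected to catch typos early.
    """

    SECTIONS = ("design", "scenario", "prep", "stats", "model", "sampler")
    GLOBALS = ("seed", "out_dir", "verbosity")

    def __init__(self, mapping: dict | None = None):
        mapping = dict(mapping or {})
        unknown = set(mapping) - set(self.SECTIONS) - set(self.GLOBALS)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        self.seed = int(mapping.get("seed", 0))
        self.out_dir = Path(mapping.get("out_dir", "."))
        self.verbosity = int(mapping.get("verbosity", 1))
        for section in self.SECTIONS:
            setattr(self, section, dict(mapping.get(section) or {}))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        out = {"seed": self.seed, "out_dir": str(self.out_dir), "verbosity": self.verbosity}
        for section in self.SECTIONS:
            block = getattr(self, section)
            if block:
                out[section] = block
        return out

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
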
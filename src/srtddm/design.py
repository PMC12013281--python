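"""Experimental protocol of the serial response time task (SRTT).

The task presents stimuli at six horizontal screen locations; participants
press the spatially compatible key.  Unbeknownst to (some) participants, the
stimulus locations follow a six-item repeating sequence, either
probabilistically (each transition follows the sequence with probability
``p_regular``) or in a mixed-deterministic regime where whole blocks are
either fully sequenced or fully random.

This module encodes the protocol constants, generates per-participant
six-item sequences, and builds trial-by-trial stimulus plans with
regularity labels ready for the behavioural simulator.

Location indices are 1-based, left to right, matching the conventional
"2-1-6-5-3-4" notation for sequences.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignConfig",
    "SequenceSpec",
    "TrialPlanEntry",
    "generate_sequence",
    "build_probabilistic_plan",
    "build_mixed_deterministic_plan",
    "build_instruction_phase",
    "label_regularity",
    "plan_to_frame",
]

#: trial_type labels
REGULAR = "regular"
NONREGULAR = "nonregular"
DETERMINISTIC = "deterministic"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class DesignConfig:
    """Constants of the SRTT protocol.

    Defaults reproduce the study design: 14 blocks of 144 trials
    (2,016 responses), a 250 ms response-stimulus interval, a response
    deadline that ramps down over block 1 (900/800/700/600 ms for 24
    trials each, then 500 ms) and stays at 500 ms afterwards, and — for
    probabilistic material — a .6 probability that each transition
    follows the six-item sequence.
    """

    n_locations: int = 6
    n_blocks: int = 14
    trials_per_block: int = 144
    p_regular: float = 0.6
    rsi_ms: float = 250.0
    deadline_schedule: tuple[tuple[float, int], ...] = (
        (900.0, 24),
        (800.0, 24),
        (700.0, 24),
        (600.0, 24),
        (500.0, 48),
    )
    deadline_main_ms: float = 500.0
    material: str = "probabilistic"  # or "mixed_deterministic"
    instructions: str = "concealed"  # or "revealed"
    practice_cycles: int = 3
    #: whether the non-regular draw excludes the sequence successor in
    #: addition to the previous location (4 candidates instead of 5).
    nonregular_excludes_successor: bool = True

    def __post_init__(self) -> None:
        if self.n_blocks % 2:
            raise ValueError("n_blocks must be even (blocks collapse into pairs)")
        if self.trials_per_block % self.n_locations:
            raise ValueError("trials_per_block must be divisible by n_locations")
        if not 0.0 < self.p_regular < 1.0:
            raise ValueError("p_regular must lie in (0, 1)")
        if sum(n for _, n in self.deadline_schedule) != self.trials_per_block:
            raise ValueError("deadline_schedule trial counts must sum to trials_per_block")
        if self.material not in ("probabilistic", "mixed_deterministic"):
            raise ValueError(f"unknown material {self.material!r}")
        if self.instructions not in ("concealed", "revealed"):
            raise ValueError(f"unknown instructions {self.instructions!r}")

    @property
    def n_block_pairs(self) -> int:
        return self.n_blocks // 2

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def replace(self, **kwargs) -> "DesignConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["deadline_schedule"] = [list(x) for x in self.deadline_schedule]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DesignConfig":
        d = dict(d)
        if "deadline_schedule" in d:
            d["deadline_schedule"] = tuple(tuple(x) for x in d["deadline_schedule"])
        return cls(**d)


@dataclass(frozen=True)
class SequenceSpec:
    """A six-item sequence: a permutation of the locations, read cyclically.

    The successor of the last element is the first element, so the
    sequence defines a single cycle over all locations.
    """

    order: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.order)
        if sorted(self.order) != list(range(1, n + 1)):
            raise ValueError(f"order must be a permutation of 1..{n}: {self.order}")

    @property
    def n_locations(self) -> int:
        return len(self.order)

    def successor_map(self) -> dict[int, int]:
        n = len(self.order)
        return {self.order[i]: self.order[(i + 1) % n] for i in range(n)}

    def successor(self, location: int) -> int:
        return self.successor_map()[location]


@dataclass
class TrialPlanEntry:
    """One planned SRTT trial (stimulus side only, before behaviour)."""

    block: int
    trial_in_block: int
    stimulus_location: int
    trial_type: str  # regular / nonregular / deterministic / undefined
    block_kind: str  # probabilistic / random / deterministic
    deadline_ms: float


def generate_sequence(rng_seed: int | np.random.Generator, n_locations: int = 6) -> SequenceSpec:
    """Draw a uniformly random permutation of the locations as the sequence."""
    rng = _as_rng(rng_seed)
    order = tuple(int(x) for x in rng.permutation(n_locations) + 1)
    return SequenceSpec(order)


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _deadline_for(config: DesignConfig, block: int, trial_in_block: int) -> float:
    if block == 1:
        cum = 0
        for deadline, n in config.deadline_schedule:
            cum += n
            if trial_in_block <= cum:
                return deadline
    return config.deadline_main_ms


def _draw_nonregular(
    rng: np.random.Generator, prev: int, succ: int, n_locations: int, exclude_successor: bool
) -> int:
    excluded = {prev}
    if exclude_successor:
        excluded.add(succ)
    candidates = [loc for loc in range(1, n_locations + 1) if loc not in excluded]
    return int(candidates[rng.integers(len(candidates))])


def build_probabilistic_plan(
    config: DesignConfig, seq: SequenceSpec, rng_seed: int | np.random.Generator
) -> list[TrialPlanEntry]:
    """Stimulus plan for probabilistic material.

    Each transition follows the sequence successor with probability
    ``p_regular``; otherwise another location is drawn uniformly,
    excluding the previous location (no immediate repetitions) and — by
    default — the successor itself, leaving four candidates.  The first
    trial of the session is drawn uniformly.
    """
    if config.material != "probabilistic":
        raise ValueError("config.material must be 'probabilistic'")
    rng = _as_rng(rng_seed)
    succ = seq.successor_map()
    plan: list[TrialPlanEntry] = []
    prev: int | None = None
    for block in range(1, config.n_blocks + 1):
        for trial in range(1, config.trials_per_block + 1):
            if prev is None:
                stim = int(rng.integers(1, config.n_locations + 1))
            elif rng.random() < config.p_regular:
                stim = succ[prev]
            else:
                stim = _draw_nonregular(
                    rng, prev, succ[prev], config.n_locations, config.nonregular_excludes_successor
                )
            plan.append(
                TrialPlanEntry(
                    block=block,
                    trial_in_block=trial,
                    stimulus_location=stim,
                    trial_type=UNDEFINED,
                    block_kind="probabilistic",
                    deadline_ms=_deadline_for(config, block, trial),
                )
            )
            prev = stim
    return label_regularity(plan, seq)


def build_mixed_deterministic_plan(
    config: DesignConfig, seq: SequenceSpec, rng_seed: int | np.random.Generator
) -> list[TrialPlanEntry]:
    """Stimulus plan for mixed-deterministic material.

    Either the odd or the even blocks are deterministic (parity drawn at
    random per participant); deterministic blocks cycle through the
    sequence from a uniformly drawn starting phase, random blocks draw
    uniformly over the five non-repeating locations (so roughly 1/5 of
    their transitions follow the sequence by chance).
    """
    if config.material != "mixed_deterministic":
        raise ValueError("config.material must be 'mixed_deterministic'")
    rng = _as_rng(rng_seed)
    succ = seq.successor_map()
    det_parity = int(rng.integers(2))  # 0 -> odd blocks deterministic, 1 -> even
    plan: list[TrialPlanEntry] = []
    prev: int | None = None
    for block in range(1, config.n_blocks + 1):
        deterministic = (block % 2 == 1) if det_parity == 0 else (block % 2 == 0)
        if deterministic:
            phase = int(rng.integers(config.n_locations))
            # continue the cycle from a fresh uniformly drawn phase
            stim_cycle = [seq.order[(phase + i) % config.n_locations] for i in range(config.n_locations)]
            if prev is not None and stim_cycle[0] == prev:
                # avoid an immediate repetition at the block boundary
                phase = (phase + 1) % config.n_locations
                stim_cycle = [
                    seq.order[(phase + i) % config.n_locations] for i in range(config.n_locations)
                ]
        for trial in range(1, config.trials_per_block + 1):
            if deterministic:
                stim = stim_cycle[(trial - 1) % config.n_locations]
            elif prev is None:
                stim = int(rng.integers(1, config.n_locations + 1))
            else:
                stim = _draw_nonregular(rng, prev, succ[prev], config.n_locations, False)
            plan.append(
                TrialPlanEntry(
                    block=block,
                    trial_in_block=trial,
                    stimulus_location=stim,
                    trial_type=UNDEFINED,
                    block_kind="deterministic" if deterministic else "random",
                    deadline_ms=_deadline_for(config, block, trial),
                )
            )
            prev = stim
    return label_regularity(plan, seq)


def build_instruction_phase(config: DesignConfig, seq: SequenceSpec) -> list[TrialPlanEntry]:
    """Practice trials shown to sequence-revealed participants.

    Three full repetitions of the sequence (18 trials) by default; these
    precede block 1 and carry no deadline pressure (deadline set to the
    block-1 starting deadline).
    """
    if config.instructions != "revealed":
        raise ValueError("instruction phase exists only in the revealed condition")
    deadline = config.deadline_schedule[0][0]
    plan = []
    for cycle in range(config.practice_cycles):
        for i, loc in enumerate(seq.order):
            plan.append(
                TrialPlanEntry(
                    block=0,
                    trial_in_block=cycle * config.n_locations + i + 1,
                    stimulus_location=loc,
                    trial_type=REGULAR,
                    block_kind="deterministic",
                    deadline_ms=deadline,
                )
            )
    return plan


def label_regularity(plan: list[TrialPlanEntry], seq: SequenceSpec) -> list[TrialPlanEntry]:
    """Label each trial regular/nonregular by the sequence-successor rule.

    A trial is *regular* iff its stimulus equals the sequence successor
    of the previous trial's stimulus.  The first trial of each block is
    labelled ``undefined`` (downstream analyses drop the first four
    trials of every block anyway).  Trials in deterministic blocks keep
    the label ``deterministic``.
    """
    if not plan:
        raise ValueError("empty plan")
    succ = seq.successor_map()
    prev: int | None = None
    for entry in plan:
        if entry.stimulus_location not in succ:
            raise ValueError(f"unknown location index {entry.stimulus_location}")
        if entry.block_kind == "deterministic":
            entry.trial_type = DETERMINISTIC
        elif entry.trial_in_block == 1 or prev is None:
            entry.trial_type = UNDEFINED
        else:
            entry.trial_type = REGULAR if entry.stimulus_location == succ[prev] else NONREGULAR
        prev = entry.stimulus_location
    return plan


def plan_to_frame(plan: Iterable[TrialPlanEntry]) -> pd.DataFrame:
    """Serialize a plan as a tidy table (one row per trial)."""
    return pd.DataFrame([dataclasses.asdict(e) for e in plan])
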
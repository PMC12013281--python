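"""Synthetic SRTT cohorts: full study datasets generated from the DDM.

A :class:`CohortScenario` describes one experimental group — its design,
the trajectories of the diffusion parameters over block pairs, the
between-participant spread, and how much sequence knowledge participants
can report afterwards.  :func:`simulate_cohort` turns a list of
scenarios into a trial-level dataset plus a participant table with
post-experimental interview responses, so the whole analysis pipeline is
testable without any external data.

Parameter conventions follow *regularity coding*: the upper boundary is
the sequence-predicted (regular) response.  Drift rates are therefore
positive for regular/deterministic trials (evidence favours the upper
boundary) and negative for nonregular trials (evidence favours the
correct, lower response).  Between-participant variation is applied on
the link scale (log for alpha and theta, logit for beta, identity for
delta and xi) as a per-parameter random intercept shared across cells,
matching the hierarchical model used for inference.

The shipped presets are illustrative: they qualitatively mimic the four
groups' parameter patterns (probabilistic groups express learning in
starting point, drift and response competition; mixed-deterministic
groups show strong starting-point shifts and nondecision speed-ups in
deterministic blocks), with invented numbers calibrated to produce
plausible RT, error and deadline-violation rates under the 500 ms
deadline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ddm import DiffusionParams, effective_nondecision, sample_decision_times
from .design import (
    DETERMINISTIC,
    NONREGULAR,
    REGULAR,
    UNDEFINED,
    DesignConfig,
    SequenceSpec,
    build_mixed_deterministic_plan,
    build_probabilistic_plan,
    generate_sequence,
)

__all__ = [
    "ParameterTrajectory",
    "LearningTrajectory",
    "CohortScenario",
    "simulate_participant",
    "simulate_cohort",
    "simulate_interview",
    "preset_scenarios",
    "recovery_scenario",
]

#: link functions per base parameter (shared with hierarchical inference)
LINKS = {
    "alpha": (np.log, np.exp),
    "beta": (lambda p: np.log(p / (1.0 - p)), lambda x: 1.0 / (1.0 + np.exp(-x))),
    "delta": (lambda x: x, lambda x: x),
    "theta": (np.log, np.exp),
    "xi": (lambda x: x, lambda x: x),
}
BASE_PARAMS = ("alpha", "beta", "delta", "theta", "xi")


@dataclass(frozen=True)
class ParameterTrajectory:
    """Start/end values of one parameter over the session's block pairs."""

    start: float
    end: float | None = None
    shape: str = "linear"  # constant | linear | exponential

    def value(self, block_pair: int, n_pairs: int) -> float:
        end = self.start if self.end is None else self.end
        if self.shape == "constant" or n_pairs <= 1:
            return self.start
        frac = (block_pair - 1) / (n_pairs - 1)
        if self.shape == "linear":
            return self.start + (end - self.start) * frac
        if self.shape == "exponential":
            if self.start * end <= 0.0:
                raise ValueError("exponential trajectories need same-sign endpoints")
            return self.start * (end / self.start) ** frac
        raise ValueError(f"unknown trajectory shape {self.shape!r}")


@dataclass(frozen=True)
class LearningTrajectory:
    """Trajectories per parameter and trial type.

    Keys are either a base parameter name (``"beta"``) or a
    cell-specific variant (``"delta:regular"``, ``"theta:deterministic"``,
    ``"alpha:random"``); lookup falls back from the specific to the base
    key.
    """

    cells: Mapping[str, ParameterTrajectory]

    def lookup(self, param: str, trial_type: str) -> ParameterTrajectory:
        key = f"{param}:{trial_type}"
        if key in self.cells:
            return self.cells[key]
        if param in self.cells:
            return self.cells[param]
        raise KeyError(f"no trajectory for {key} or {param}")

    def value(self, param: str, trial_type: str, block_pair: int, n_pairs: int) -> float:
        return self.lookup(param, trial_type).value(block_pair, n_pairs)


@dataclass(frozen=True)
class CohortScenario:
    """One experimental group's generative recipe."""

    name: str
    config: DesignConfig
    n_participants: int
    trajectory: LearningTrajectory
    #: link-scale SDs; delta is identity-scaled (evidence/s), xi is seconds
    between_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "alpha": 0.10, "beta": 0.10, "delta": 0.25, "theta": 0.08, "xi": 0.015,
        }
    )
    slip_prob: float = 0.15
    interview_knowledge: float = 0.2

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not 0.0 <= self.slip_prob <= 1.0:
            raise ValueError("slip_prob must lie in [0, 1]")
        if not 0.0 <= self.interview_knowledge <= 1.0:
            raise ValueError("interview_knowledge must lie in [0, 1]")


def _effective_trial_type(trial_type: str, block_kind: str) -> str:
    """Trial type used for parameter lookup (cell assignment)."""
    if block_kind == "deterministic":
        return DETERMINISTIC
    if trial_type == UNDEFINED:
        return NONREGULAR  # neutral choice; these trials are filtered downstream
    return trial_type


def _cell_params(
    scenario: CohortScenario, trial_type: str, block_pair: int, n_pairs: int,
    offsets: Mapping[str, float],
) -> DiffusionParams:
    vals = {}
    for p in BASE_PARAMS:
        link, inv = LINKS[p]
        # boundary separation is a property of the block kind, not the trial type
        tt = trial_type
        if p == "alpha":
            tt = DETERMINISTIC if trial_type == DETERMINISTIC else "random"
        mean = scenario.trajectory.value(p, tt, block_pair, n_pairs)
        vals[p] = float(inv(link(mean) + offsets[p]))
    # keep the nondecision split feasible: |xi|/2 must not exceed theta
    cap = 1.9 * vals["theta"]
    vals["xi"] = float(np.clip(vals["xi"], -cap, cap))
    return DiffusionParams(**vals)


def simulate_participant(
    config: DesignConfig,
    scenario: CohortScenario,
    rng_seed: int | np.random.Generator,
    participant: int = 0,
    seq: SequenceSpec | None = None,
    offsets: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate one participant's full SRTT session as trial records."""
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    if seq is None:
        seq = generate_sequence(rng, config.n_locations)
    if offsets is None:
        offsets = {
            p: float(rng.normal(0.0, scenario.between_sd.get(p, 0.0))) for p in BASE_PARAMS
        }
    if config.material == "probabilistic":
        plan = build_probabilistic_plan(config, seq, rng)
    else:
        plan = build_mixed_deterministic_plan(config, seq, rng)

    succ = seq.successor_map()
    n_pairs = config.n_block_pairs
    n = len(plan)
    eff_tt = [_effective_trial_type(e.trial_type, e.block_kind) for e in plan]
    pairs = [(e.block + 1) // 2 for e in plan]

    # one parameter set per (trial type, block pair) cell; batch-draw
    # decision times per cell, then walk the session in order
    cells: dict[tuple[str, int], DiffusionParams] = {}
    cell_of_trial = list(zip(eff_tt, pairs))
    for key in sorted(set(cell_of_trial)):
        cells[key] = _cell_params(scenario, key[0], key[1], n_pairs, offsets)
    dts = np.empty(n)
    ups = np.empty(n, dtype=bool)
    for key in sorted(cells):
        idx = np.array([i for i, k in enumerate(cell_of_trial) if k == key])
        t, u = sample_decision_times(cells[key], len(idx), rng)
        dts[idx] = t
        ups[idx] = u

    records = []
    prev_stim: int | None = None
    prev_feedback = False
    all_locs = list(range(1, config.n_locations + 1))
    for i, entry in enumerate(plan):
        stim = entry.stimulus_location
        predicted = succ[prev_stim] if prev_stim is not None else None
        params = cells[cell_of_trial[i]]
        up = bool(ups[i])
        # map the binary boundary outcome onto one of the six keys
        if predicted is None:
            pressed = stim if up else _uniform_choice(rng, all_locs, {stim})
        elif stim == predicted:  # regular or deterministic trial
            if up:
                pressed = stim
            else:
                pressed = _uniform_choice(rng, all_locs, {stim, prev_stim})
        else:  # nonregular trial
            if up:
                pressed = predicted
            elif rng.random() >= scenario.slip_prob:
                pressed = stim
            else:
                pressed = _uniform_choice(rng, all_locs, {stim, predicted, prev_stim})
        motor_regular = predicted is not None and pressed == predicted
        rt = dts[i] + effective_nondecision(params.theta, params.xi, motor_regular)
        rt_ms = rt * 1000.0
        correct = pressed == stim
        exceeded = rt_ms > entry.deadline_ms
        records.append(
            (
                participant, scenario.name, scenario.config.material,
                scenario.config.instructions, entry.block, pairs[i],
                entry.trial_in_block, stim, entry.trial_type, entry.block_kind,
                0 if predicted is None else predicted, pressed, rt_ms, correct,
                entry.deadline_ms, exceeded, prev_feedback, motor_regular,
            )
        )
        prev_feedback = (not correct) or exceeded
        prev_stim = stim
    return pd.DataFrame.from_records(records, columns=TRIAL_COLUMNS)


TRIAL_COLUMNS = [
    "participant", "scenario", "material", "instructions", "block", "block_pair",
    "trial", "stimulus_location", "trial_type", "block_kind", "predicted_location",
    "pressed_key", "rt_ms", "correct", "deadline_ms", "deadline_exceeded",
    "post_feedback", "motor_regular",
]


def _uniform_choice(rng: np.random.Generator, candidates: Sequence[int], excluded: set) -> int:
    pool = [c for c in candidates if c not in excluded]
    return int(pool[rng.integers(len(pool))])


def simulate_interview(
    scenario: CohortScenario, seq: SequenceSpec, rng: np.random.Generator
) -> tuple[bool, int, int]:
    """(believed sequenced, free-recall correct 0-6, forced-choice correct 0-6).

    Each of the six transitions is known with probability
    ``interview_knowledge``; unknown forced-choice probes are guessed
    uniformly over the five admissible locations (chance 1/5), so wrong
    answers land uniformly on the four admissible-but-incorrect ones.
    Belief in a sequenced condition rises linearly with knowledge.
    """
    k = scenario.interview_knowledge
    n = seq.n_locations
    belief = bool(rng.random() < min(1.0, 0.25 + 0.75 * k))
    free = int(rng.binomial(n, k))
    forced = int(rng.binomial(n, k + (1.0 - k) / (n - 1)))
    return belief, free, forced


def simulate_cohort(
    scenarios: Iterable[CohortScenario], rng_seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate all scenarios; returns (trial table, participant table).

    Participant ids are unique across scenarios; the participant table
    carries the interview responses, the generating sequence, and the
    true link-scale participant offsets (useful for recovery studies).
    """
    ss = np.random.SeedSequence(rng_seed)
    trial_frames = []
    participants = []
    pid = 0
    for scenario in scenarios:
        for _ in range(scenario.n_participants):
            rng = np.random.default_rng(ss.spawn(1)[0])
            seq = generate_sequence(rng, scenario.config.n_locations)
            offsets = {
                p: float(rng.normal(0.0, scenario.between_sd.get(p, 0.0)))
                for p in BASE_PARAMS
            }
            trials = simulate_participant(
                scenario.config, scenario, rng, participant=pid, seq=seq, offsets=offsets
            )
            belief, free, forced = simulate_interview(scenario, seq, rng)
            trial_frames.append(trials)
            participants.append(
                {
                    "participant": pid,
                    "scenario": scenario.name,
                    "material": scenario.config.material,
                    "instructions": scenario.config.instructions,
                    "sequence": "-".join(str(x) for x in seq.order),
                    "belief_sequenced": belief,
                    "free_recall_correct": free,
                    "forced_choice_correct": forced,
                    **{f"offset_{p}": offsets[p] for p in BASE_PARAMS},
                }
            )
            pid += 1
    return pd.concat(trial_frames, ignore_index=True), pd.DataFrame(participants)


def recovery_scenario(
    n_participants: int = 12, xi: float = 0.03, name: str = "recovery"
) -> CohortScenario:
    """Reduced scenario for parameter-recovery studies.

    Four blocks of 72 trials (288 per participant, two block pairs, so
    2 trial types x 2 block pairs = 4 cells for starting point and
    drift), without deadline pressure so that no trials are lost to the
    deadline and the fitted likelihood matches the generative process.
    """
    cfg = DesignConfig(
        n_blocks=4, trials_per_block=72,
        deadline_schedule=((2000.0, 72),), deadline_main_ms=2000.0,
        material="probabilistic", instructions="concealed",
    )
    return CohortScenario(
        name=name, config=cfg, n_participants=n_participants,
        trajectory=LearningTrajectory({
            "alpha": ParameterTrajectory(1.0, None, "constant"),
            "beta:regular": ParameterTrajectory(0.55, 0.65),
            "beta:nonregular": ParameterTrajectory(0.48, 0.42),
            "delta:regular": ParameterTrajectory(2.6, 3.4),
            "delta:nonregular": ParameterTrajectory(-2.4, -2.8),
            "theta": ParameterTrajectory(0.20, None, "constant"),
            "xi": ParameterTrajectory(xi, None, "constant"),
        }),
    )


def _traj(start, end=None, shape="linear"):
    return ParameterTrajectory(start, end, shape if end is not None else "constant")


def preset_scenarios(n_participants: int = 25) -> dict[str, CohortScenario]:
    """The four study groups with illustrative generative parameters."""
    prob_conc = DesignConfig(material="probabilistic", instructions="concealed")
    prob_rev = DesignConfig(material="probabilistic", instructions="revealed")
    mix_conc = DesignConfig(material="mixed_deterministic", instructions="concealed")
    mix_rev = DesignConfig(material="mixed_deterministic", instructions="revealed")
    scenarios = {
        "probabilistic-concealed": CohortScenario(
            name="probabilistic-concealed", config=prob_conc, n_participants=n_participants,
            trajectory=LearningTrajectory({
                "alpha": _traj(1.10, 0.95),
                "beta": _traj(0.50, 0.60),
                "delta:regular": _traj(2.6, 3.4),
                "delta:nonregular": _traj(-2.6, -2.2),
                "theta": _traj(0.19),
                "xi": _traj(0.0, 0.04),
            }),
            interview_knowledge=0.15,
        ),
        "probabilistic-revealed": CohortScenario(
            name="probabilistic-revealed", config=prob_rev, n_participants=n_participants,
            trajectory=LearningTrajectory({
                "alpha": _traj(1.10, 0.95),
                "beta": _traj(0.50, 0.57),
                "delta:regular": _traj(2.6, 3.6),
                "delta:nonregular": _traj(-2.6, -2.1),
                "theta": _traj(0.19),
                "xi": _traj(0.0, 0.04),
            }),
            interview_knowledge=0.30,
        ),
        "mixed-concealed": CohortScenario(
            name="mixed-concealed", config=mix_conc, n_participants=n_participants,
            trajectory=LearningTrajectory({
                "alpha:random": _traj(1.10, 0.95),
                "alpha:deterministic": _traj(1.10, 1.05),
                "beta": _traj(0.50, 0.54),
                "beta:deterministic": _traj(0.50, 0.72),
                "delta:regular": _traj(2.6, 2.9),
                "delta:nonregular": _traj(-2.6, -2.45),
                "delta:deterministic": _traj(2.6, 2.8),
                "theta": _traj(0.19),
                "theta:deterministic": _traj(0.19, 0.15),
                "xi": _traj(0.0, 0.03),
            }),
            interview_knowledge=0.55,
        ),
        "mixed-revealed": CohortScenario(
            name="mixed-revealed", config=mix_rev, n_participants=n_participants,
            trajectory=LearningTrajectory({
                "alpha:random": _traj(1.10, 0.95),
                "alpha:deterministic": _traj(1.15, 1.10),
                "beta": _traj(0.50, 0.53),
                "beta:deterministic": _traj(0.62, 0.82),
                "delta:regular": _traj(2.6, 2.9),
                "delta:nonregular": _traj(-2.6, -2.5),
                "delta:deterministic": _traj(2.6, 2.8),
                "theta": _traj(0.19),
                "theta:deterministic": _traj(0.17, 0.13),
                "xi": _traj(0.0),
            }),
            interview_knowledge=0.85,
        ),
    }
    return scenarios
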
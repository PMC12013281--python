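"""Stimulus-plan generation: sequences, regularity structure, deadlines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from srtddm.design import (
    DesignConfig,
    SequenceSpec,
    TrialPlanEntry,
    build_instruction_phase,
    build_mixed_deterministic_plan,
    build_probabilistic_plan,
    generate_sequence,
    label_regularity,
)

MIXED = DesignConfig(material="mixed_deterministic")


class TestSequence:
    def test_is_permutation_and_reproducible(self):
        s1 = generate_sequence(42)
        s2 = generate_sequence(42)
        assert sorted(s1.order) == [1, 2, 3, 4, 5, 6]
        assert s1.order == s2.order

    def test_successor_map_is_single_cycle(self):
        seq = SequenceSpec((2, 1, 6, 5, 3, 4))
        succ = seq.successor_map()
        loc, seen = 2, []
        for _ in range(6):
            seen.append(loc)
            loc = succ[loc]
        assert loc == 2 and sorted(seen) == [1, 2, 3, 4, 5, 6]

    def test_first_position_uniform_over_locations(self):
        counts = np.zeros(6)
        for seed in range(10_000):
            counts[generate_sequence(seed).order[0] - 1] += 1
        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 1e-4

    def test_invalid_permutation_rejected(self):
        with pytest.raises(ValueError):
            SequenceSpec((1, 1, 2, 3, 4, 5))


class TestProbabilisticPlan:
    def test_session_length_and_deadline_schedule(self):
        cfg = DesignConfig()
        plan = build_probabilistic_plan(cfg, generate_sequence(0), 1)
        assert len(plan) == 2016
        block1 = [e for e in plan if e.block == 1]
        assert [e.deadline_ms for e in block1[:24]] == [900.0] * 24
        assert block1[24].deadline_ms == 800.0
        assert block1[96].deadline_ms == 500.0
        assert all(e.deadline_ms == 500.0 for e in plan if e.block > 1)

    def test_degenerate_p_regular_one_follows_successors(self):
        cfg = DesignConfig(p_regular=1 - 1e-12)
        seq = generate_sequence(3)
        plan = build_probabilistic_plan(cfg, seq, 5)
        succ = seq.successor_map()
        for prev, cur in zip(plan[:-1], plan[1:]):
            assert cur.stimulus_location == succ[prev.stimulus_location]

    def test_pooled_regular_fraction_near_p_regular(self):
        cfg = DesignConfig()
        labelled = []
        for seed in range(50):
            plan = build_probabilistic_plan(cfg, generate_sequence(seed), 1000 + seed)
            labelled += [e.trial_type for e in plan if e.trial_type != "undefined"]
        frac = np.mean([t == "regular" for t in labelled])
        assert frac == pytest.approx(0.60, abs=0.01)

    def test_without_successor_exclusion_chance_regularity_is_one_fifth(self):
        # with the nonregular draw uniform over all five non-repeating
        # locations, a nearly-zero p_regular still yields ~1/5 regular
        cfg = DesignConfig(p_regular=1e-9, nonregular_excludes_successor=False)
        labelled = []
        for seed in range(30):
            plan = build_probabilistic_plan(cfg, generate_sequence(seed), seed)
            labelled += [e.trial_type for e in plan if e.trial_type != "undefined"]
        assert np.mean([t == "regular" for t in labelled]) == pytest.approx(0.2, abs=0.012)

    def test_material_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_probabilistic_plan(MIXED, generate_sequence(0), 0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_no_immediate_repetitions(self, seed):
        cfg = DesignConfig(n_blocks=2)
        plan = build_probabilistic_plan(cfg, generate_sequence(seed), seed)
        stims = [e.stimulus_location for e in plan]
        assert all(a != b for a, b in zip(stims[:-1], stims[1:]))


class TestMixedDeterministicPlan:
    def test_block_structure(self):
        plan = build_mixed_deterministic_plan(MIXED, generate_sequence(1), 2)
        kinds = {e.block: e.block_kind for e in plan}
        det = [b for b, k in kinds.items() if k == "deterministic"]
        rand = [b for b, k in kinds.items() if k == "random"]
        assert len(det) == 7 and len(rand) == 7
        for pair in range(1, 8):
            pair_kinds = {kinds[2 * pair - 1], kinds[2 * pair]}
            assert pair_kinds == {"deterministic", "random"}

    def test_both_parities_occur_across_participants(self):
        parities = set()
        for seed in range(20):
            plan = build_mixed_deterministic_plan(MIXED, generate_sequence(seed), seed)
            parities.add(min(e.block for e in plan if e.block_kind == "deterministic"))
        assert parities == {1, 2}

    def test_deterministic_blocks_follow_sequence_exactly(self):
        seq = generate_sequence(9)
        succ = seq.successor_map()
        plan = build_mixed_deterministic_plan(MIXED, seq, 9)
        for prev, cur in zip(plan[:-1], plan[1:]):
            if cur.block_kind == "deterministic" and cur.block == prev.block:
                assert cur.stimulus_location == succ[prev.stimulus_location]

    def test_random_block_chance_regularity_20_percent(self):
        seq_frac = []
        for seed in range(50):
            seq = generate_sequence(seed)
            succ = seq.successor_map()
            plan = build_mixed_deterministic_plan(MIXED, seq, 3000 + seed)
            for prev, cur in zip(plan[:-1], plan[1:]):
                if cur.block_kind == "random" and cur.block == prev.block:
                    seq_frac.append(cur.stimulus_location == succ[prev.stimulus_location])
        assert 100 * np.mean(seq_frac) == pytest.approx(20.0, abs=1.0)

    def test_no_immediate_repetitions(self):
        plan = build_mixed_deterministic_plan(MIXED, generate_sequence(4), 4)
        stims = [e.stimulus_location for e in plan]
        assert all(a != b for a, b in zip(stims[:-1], stims[1:]))


class TestInstructionPhase:
    def test_default_has_18_trials(self):
        cfg = DesignConfig(instructions="revealed")
        plan = build_instruction_phase(cfg, generate_sequence(0))
        assert len(plan) == 18

    def test_single_cycle_equals_sequence(self):
        cfg = DesignConfig(instructions="revealed", practice_cycles=1)
        seq = generate_sequence(7)
        plan = build_instruction_phase(cfg, seq)
        assert tuple(e.stimulus_location for e in plan) == seq.order

    def test_concealed_condition_rejected(self):
        with pytest.raises(ValueError):
            build_instruction_phase(DesignConfig(), generate_sequence(0))


class TestLabelRegularity:
    def _plan(self, stims, block=1):
        return [
            TrialPlanEntry(block, i + 1, s, "undefined", "probabilistic", 500.0)
            for i, s in enumerate(stims)
        ]

    def test_example_sequence_labels(self):
        seq = SequenceSpec((2, 1, 6, 5, 3, 4))
        plan = label_regularity(self._plan([2, 1, 6]), seq)
        assert plan[0].trial_type == "undefined"  # first trial of the block
        assert plan[1].trial_type == "regular"  # 1 follows 2 in the sequence
        assert plan[2].trial_type == "regular"  # 6 follows 1
        plan2 = label_regularity(self._plan([2, 6]), seq)
        assert plan2[1].trial_type == "nonregular"  # 6 is not the successor of 2

    def test_unknown_location_rejected(self):
        seq = SequenceSpec((2, 1, 6, 5, 3, 4))
        with pytest.raises(ValueError):
            label_regularity(self._plan([2, 9]), seq)

    def test_empty_plan_rejected(self):
        with pytest.raises(ValueError):
            label_regularity([], SequenceSpec((1, 2, 3, 4, 5, 6)))


class TestDesignConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_blocks": 13},
            {"trials_per_block": 100},
            {"p_regular": 0.0},
            {"deadline_schedule": ((900.0, 24),)},
            {"material": "blocked"},
        ],
    )
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DesignConfig(**kwargs)

    def test_round_trip_through_dict(self):
        cfg = DesignConfig(material="mixed_deterministic", instructions="revealed")
        assert DesignConfig.from_dict(cfg.to_dict()) == cfg
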
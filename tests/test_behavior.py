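"""Behavioural statistics: cell means, ANOVA, error analyses, interview scoring."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from srtddm.anova import mixed_anova
from srtddm.behavior import (
    InterviewScore,
    aggregate_cells,
    chance_baseline,
    classify_awareness,
    error_rt_analysis,
    rule_adhering_analysis,
    score_free_recall,
    within_subject_ci,
)
from srtddm.design import SequenceSpec

SEQ = SequenceSpec((2, 1, 6, 5, 3, 4))


def _trial_frame(rows):
    defaults = dict(
        participant=0, block=1, block_pair=1, trial=5, stimulus_location=1,
        trial_type="regular", block_kind="probabilistic", predicted_location=1,
        pressed_key=1, rt_ms=400.0, correct=True, deadline_ms=500.0,
        deadline_exceeded=False, post_feedback=False, motor_regular=True,
    )
    out = []
    for r in rows:
        d = dict(defaults)
        d.update(r)
        out.append(d)
    return pd.DataFrame(out)


class TestAggregateCells:
    def test_group_mean_is_unweighted_participant_mean(self):
        rows = (
            [dict(participant=0, rt_ms=400.0)] * 3
            + [dict(participant=1, rt_ms=500.0)] * 7
        )
        per, group = aggregate_cells(_trial_frame(rows), "rt_correct", ["trial_type"])
        assert group.loc[0, "mean"] == pytest.approx(450.0)

    def test_error_rate_zero_on_all_correct_data(self):
        rows = [dict(participant=p, trial_type=t)
                for p in range(3) for t in ("regular", "nonregular")]
        per, group = aggregate_cells(_trial_frame(rows), "error_rate", ["trial_type"])
        assert (group["mean"] == 0).all()

    def test_empty_cell_reported_missing_not_zero(self):
        rows = [dict(participant=0, trial_type="regular", correct=True)]
        per, _ = aggregate_cells(_trial_frame(rows), "rt_error", ["trial_type"])
        assert per.empty  # no error trials anywhere: nothing to aggregate

    def test_unknown_dv_rejected(self):
        with pytest.raises(ValueError):
            aggregate_cells(_trial_frame([{}]), "accuracy", ["trial_type"])


def _hand_ss_two_by_two(df):
    """Independent SS computation for a 2(between)x2(within) design via
    explicit mean decomposition."""
    grand = df["y"].mean()
    ss = {}
    ss["grp"] = sum(
        len(g) * (g["y"].mean() - grand) ** 2 for _, g in df.groupby("grp")
    )
    ss["cond"] = sum(
        len(g) * (g["y"].mean() - grand) ** 2 for _, g in df.groupby("cond")
    )
    cell = df.groupby(["grp", "cond"])["y"].mean()
    n_per_cell = len(df) / 4
    ss["grp x cond"] = sum(
        n_per_cell
        * (cell[g, c] - df[df.grp == g]["y"].mean() - df[df.cond == c]["y"].mean() + grand) ** 2
        for g, c in itertools.product(df.grp.unique(), df.cond.unique())
    )
    subj = df.groupby("participant")["y"].mean()
    grp_of = df.groupby("participant")["grp"].first()
    ss["subj_within"] = 2 * sum(
        (subj[s] - df[df.grp == grp_of[s]]["y"].mean()) ** 2 for s in subj.index
    )
    return ss


class TestMixedAnova:
    def test_matches_hand_worked_sums_of_squares(self):
        rng = np.random.default_rng(3)
        rows = []
        for g in range(2):
            for s in range(6):
                pid = g * 6 + s
                base = rng.normal()
                for c in range(2):
                    rows.append(dict(participant=pid, grp=f"g{g}", cond=f"c{c}",
                                     y=base + 0.6 * c + 0.4 * g + rng.normal()))
        df = pd.DataFrame(rows)
        hand = _hand_ss_two_by_two(df)
        table = mixed_anova(df, "y", within=["cond"], between=["grp"]).set_index("effect")
        assert table.loc["grp", "SS"] == pytest.approx(hand["grp"])
        assert table.loc["cond", "SS"] == pytest.approx(hand["cond"])
        assert table.loc["grp x cond", "SS"] == pytest.approx(hand["grp x cond"])

    def test_matches_pingouin_one_between_one_within(self):
        import pingouin as pg

        rng = np.random.default_rng(11)
        rows = []
        for g in range(2):
            for s in range(8):
                pid = g * 8 + s
                base = rng.normal()
                for c in range(4):
                    rows.append(dict(participant=pid, grp=f"g{g}", cond=f"c{c}",
                                     y=base + 0.3 * c + rng.normal()))
        df = pd.DataFrame(rows)
        ours = mixed_anova(df, "y", within=["cond"], between=["grp"]).set_index("effect")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = pg.mixed_anova(df, dv="y", within="cond", between="grp",
                                 subject="participant", correction=True).set_index("Source")
        for ours_name, ref_name in [("grp", "grp"), ("cond", "cond"),
                                    ("grp x cond", "Interaction")]:
            assert ours.loc[ours_name, "F"] == pytest.approx(ref.loc[ref_name, "F"], rel=1e-9)
            assert ours.loc[ours_name, "p"] == pytest.approx(ref.loc[ref_name, "p_unc"], rel=1e-9)
        assert ours.loc["cond", "eps"] == pytest.approx(ref.loc["cond", "eps"], abs=0.05)

    def test_matches_statsmodels_pure_within_two_factor(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(7)
        rows = []
        for s in range(9):
            base = rng.normal()
            for a in range(2):
                for b in range(3):
                    rows.append(dict(participant=s, A=f"a{a}", B=f"b{b}",
                                     y=base + 0.5 * a + rng.normal()))
        df = pd.DataFrame(rows)
        ours = mixed_anova(df, "y", within=["A", "B"]).set_index("effect")
        ref = AnovaRM(df, "y", "participant", within=["A", "B"]).fit().anova_table
        for ours_name, ref_name in [("A", "A"), ("B", "B"), ("A x B", "A:B")]:
            assert ours.loc[ours_name, "F"] == pytest.approx(ref.loc[ref_name, "F Value"])

    def test_two_level_within_factor_has_epsilon_one(self):
        rng = np.random.default_rng(0)
        rows = [dict(participant=s, cond=f"c{c}", y=rng.normal())
                for s in range(10) for c in range(2)]
        table = mixed_anova(pd.DataFrame(rows), "y", within=["cond"])
        assert table.set_index("effect").loc["cond", "eps"] == 1.0

    def test_constant_dv_yields_zero_effect_ss(self):
        rows = [dict(participant=s, cond=f"c{c}", y=1.0)
                for s in range(6) for c in range(3)]
        table = mixed_anova(pd.DataFrame(rows), "y", within=["cond"])
        assert table["SS"].abs().max() < 1e-12

    def test_unbalanced_design_rejected(self):
        rows = [dict(participant=0, cond="c0", y=1.0),
                dict(participant=0, cond="c1", y=2.0),
                dict(participant=1, cond="c0", y=3.0)]
        with pytest.raises(ValueError):
            mixed_anova(pd.DataFrame(rows), "y", within=["cond"])

    def test_generalized_eta_squared_bounded(self):
        rng = np.random.default_rng(5)
        rows = []
        for g in range(2):
            for s in range(6):
                pid = g * 6 + s
                for c in range(3):
                    rows.append(dict(participant=pid, grp=g, cond=c,
                                     y=rng.normal() + g + 0.5 * c))
        table = mixed_anova(pd.DataFrame(rows), "y", within=["cond"], between=["grp"])
        assert ((table["ges"] >= 0) & (table["ges"] <= 1)).all()

    def test_type_one_error_calibrated_under_null(self):
        rng = np.random.default_rng(42)
        alpha, n_rep = 0.05, 400
        rejections = 0
        for _ in range(n_rep):
            rows = [dict(participant=g * 5 + s, grp=g, cond=c, y=rng.normal())
                    for g in range(2) for s in range(5) for c in range(2)]
            table = mixed_anova(pd.DataFrame(rows), "y", within=["cond"], between=["grp"])
            rejections += table.set_index("effect").loc["cond", "p"] < alpha
        mc_err = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert rejections / n_rep <= alpha + 2 * mc_err


class TestChanceBaseline:
    def test_enumerated_baselines(self):
        assert chance_baseline(6, 2) == 0.25  # exclude correct key + repetition
        assert chance_baseline(6, 1) == 0.2  # exclude probe repetition
        assert chance_baseline(6, 0) == pytest.approx(1 / 6)

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ValueError):
            chance_baseline(6, 6)


class TestRuleAdhering:
    def test_always_regular_error_responder_scores_one(self):
        rows = []
        for p in range(4):
            for i in range(10):
                rows.append(dict(
                    participant=p, trial=5 + i, trial_type="nonregular",
                    stimulus_location=3, predicted_location=4 + (i % 2),
                    pressed_key=4 + (i % 2), correct=False, motor_regular=True,
                ))
        per, test = rule_adhering_analysis(_trial_frame(rows))
        assert (per["prop_rule_adhering"] == 1.0).all()
        assert test.p < 0.01

    def test_participants_without_errors_reported_excluded(self):
        rows = [dict(participant=0, trial_type="nonregular", correct=False,
                     pressed_key=5, predicted_location=5, motor_regular=True,
                     stimulus_location=3, trial=5),
                dict(participant=1, correct=True)]
        per, test = rule_adhering_analysis(_trial_frame(rows))
        assert test.n_excluded == 1
        assert set(per["participant"]) == {0}

    def test_invariant_to_relabeling_nonregular_wrong_keys(self):
        rows = []
        for p in range(3):
            for i in range(8):
                wrong = [2, 5, 6][i % 3]
                rows.append(dict(
                    participant=p, trial=5 + i, trial_type="nonregular",
                    stimulus_location=3, predicted_location=4,
                    pressed_key=4 if i % 4 == 0 else wrong,
                    correct=False, motor_regular=i % 4 == 0,
                ))
        base = rule_adhering_analysis(_trial_frame(rows))[1]
        swapped_rows = [dict(r, pressed_key={2: 5, 5: 6, 6: 2}.get(r["pressed_key"], r["pressed_key"]))
                        if not r["motor_regular"] else r for r in rows]
        swapped = rule_adhering_analysis(_trial_frame(swapped_rows))[1]
        assert base.mean == pytest.approx(swapped.mean)


class TestErrorRT:
    def test_single_error_per_cell_mean_equals_trial(self):
        rows = [
            dict(participant=0, correct=False, motor_regular=True, rt_ms=333.0,
                 block_pair=1),
            dict(participant=0, correct=False, motor_regular=False, rt_ms=444.0,
                 block_pair=1),
            dict(participant=0, correct=True, rt_ms=400.0, block_pair=1),
        ]
        per = error_rt_analysis(_trial_frame(rows))
        cell = per.set_index(["response_regularity", "block_pair"])["rt_error"]
        assert cell[("motor_regular", 1)] == 333.0
        assert cell[("motor_nonregular", 1)] == 444.0

    def test_positive_xi_makes_motor_regular_errors_faster(self, small_cohort):
        trials, _ = small_cohort
        g = trials[(trials["scenario"] == "probabilistic-concealed")
                   & (trials["block_pair"] >= 5)]
        per = error_rt_analysis(g)
        means = per.groupby("response_regularity")["rt_error"].mean()
        assert means["motor_regular"] < means["motor_nonregular"]


class TestWithinSubjectCI:
    def test_removes_between_subject_variance(self):
        # two participants with a large level difference but identical
        # within-subject condition effects: the within-subject CI must be
        # tight while the between-subject CI is wide
        rows = []
        for pid, base in [(0, 300.0), (1, 700.0)]:
            for c, eff in [("a", 0.0), ("b", 50.0)]:
                rows.append(dict(participant=pid, cond=c, y=base + eff))
        df = pd.DataFrame(rows)
        out = within_subject_ci(df, "y", ["cond"]).set_index("cond")
        assert out.loc["a", "mean"] == pytest.approx(500.0)
        assert out.loc["b", "mean"] == pytest.approx(550.0)
        # condition effects are perfectly consistent across participants
        assert out["ci_high"].sub(out["ci_low"]).max() == pytest.approx(0.0, abs=1e-9)

    def test_morey_factor_widens_raw_normalized_ci(self):
        rng = np.random.default_rng(2)
        rows = [dict(participant=p, cond=c, y=rng.normal(400 + 30 * (c == "b"), 20))
                for p in range(12) for c in ("a", "b")]
        df = pd.DataFrame(rows)
        out = within_subject_ci(df, "y", ["cond"])
        width = (out["ci_high"] - out["ci_low"]).mean()
        assert width > 0


class TestInterviewScoring:
    def test_full_cyclic_report_scores_six(self):
        assert score_free_recall([2, 1, 6, 5, 3, 4], SEQ) == 6

    def test_partial_report_counts_transitions(self):
        assert score_free_recall([2, 1, 6], SEQ) == 2

    def test_empty_report_scores_zero(self):
        assert score_free_recall([], SEQ) == 0

    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValueError):
            score_free_recall([2, 9], SEQ)

    def test_rotated_full_report_still_scores_six(self):
        assert score_free_recall([6, 5, 3, 4, 2, 1], SEQ) == 6

    @pytest.mark.parametrize(
        "belief,free,forced,expected",
        [
            (False, 1, 0, "implicit"),
            (False, 0, 0, "implicit"),
            (True, 6, 6, "explicit"),
            (True, 4, 6, "intermediate"),
            (False, 3, 0, "intermediate"),
            (True, 6, 5, "intermediate"),
            (False, 1, 2, "intermediate"),
        ],
    )
    def test_awareness_classification(self, belief, free, forced, expected):
        score = InterviewScore(belief, free, forced)
        assert classify_awareness(score) == expected
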
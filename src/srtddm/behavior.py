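"""Behavioural analyses of SRTT performance.

Cell means with confidence intervals, mixed ANOVAs (delegated to
:mod:`srtddm.anova`), the rule-adhering-error analysis with its 1/4
chance baseline, error-RT analyses by motor regularity, and scoring and
classification of the post-experimental interview.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .anova import AnovaTable, mixed_anova
from .design import SequenceSpec

__all__ = [
    "aggregate_cells",
    "mixed_anova",
    "chance_baseline",
    "rule_adhering_analysis",
    "error_rt_analysis",
    "within_subject_ci",
    "score_free_recall",
    "classify_awareness",
    "InterviewScore",
    "BaselineTest",
]

IMPLICIT = "implicit"
INTERMEDIATE = "intermediate"
EXPLICIT = "explicit"


@dataclass(frozen=True)
class InterviewScore:
    belief_sequenced: bool
    free_recall_correct: int
    forced_choice_correct: int

    def __post_init__(self) -> None:
        if not 0 <= self.free_recall_correct <= 6 or not 0 <= self.forced_choice_correct <= 6:
            raise ValueError("interview counts must lie in 0..6")


class BaselineTest(NamedTuple):
    mean: float
    t: float
    p: float
    df: int
    baseline: float
    n_excluded: int  # participants without qualifying trials


def aggregate_cells(
    dataset: pd.DataFrame,
    dv: str,
    factors: Sequence[str],
    subject: str = "participant",
    ci: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Participant-level and group-level cell means.

    ``dv`` is one of ``rt_correct`` (mean correct-response RT),
    ``error_rate``, or ``rt_error`` (mean error-response RT).  Group
    means are unweighted means of participant means; the CI uses the t
    distribution on the participant means (between-subject CI).  Empty
    participant cells are reported as missing, not as zero.
    """
    data = dataset
    if dv == "rt_correct":
        data = dataset[dataset["correct"]]
        col, fun = "rt_ms", "mean"
    elif dv == "rt_error":
        data = dataset[~dataset["correct"]]
        col, fun = "rt_ms", "mean"
    elif dv == "error_rate":
        col, fun = "correct", lambda c: 1.0 - np.mean(c)
    else:
        raise ValueError(f"unknown dv {dv!r}")
    per_subject = (
        data.groupby([subject] + list(factors), observed=True)[col].agg(fun).rename(dv).reset_index()
    )
    if per_subject.empty:
        empty = pd.DataFrame(columns=list(factors) + ["mean", "ci_low", "ci_high", "n"])
        return per_subject, empty
    def _summ(g: pd.Series) -> pd.Series:
        n = g.notna().sum()
        m = g.mean()
        if n > 1:
            half = stats.t.ppf(0.5 + ci / 2.0, n - 1) * g.std(ddof=1) / np.sqrt(n)
        else:
            half = np.nan
        return pd.Series({"mean": m, "ci_low": m - half, "ci_high": m + half, "n": n})
    group = per_subject.groupby(list(factors), observed=True)[dv].apply(_summ).unstack().reset_index()
    return per_subject, group


def chance_baseline(n_locations: int, n_excluded: int) -> float:
    """1 / (number of admissible candidate responses).

    With six keys, excluding the correct key and the repetition leaves
    four candidates (baseline 1/4 for rule-adhering errors); excluding
    only the probe repetition leaves five (baseline 1/5 for the
    forced-choice test).
    """
    candidates = n_locations - n_excluded
    if candidates < 1:
        raise ValueError("exclusions leave no candidate responses")
    return 1.0 / candidates


def rule_adhering_analysis(
    dataset: pd.DataFrame, subject: str = "participant"
) -> tuple[pd.DataFrame, BaselineTest]:
    """Proportion of rule-adhering errors on nonregular trials.

    Among error responses on nonregular trials — with response
    repetitions (pressing the previous trial's key) excluded — the
    proportion whose key is the sequence-predicted one, per participant,
    with a one-sided t test against the 1/4 chance baseline.
    Participants without qualifying errors are excluded from the test
    and reported.
    """
    d = dataset[(dataset["trial_type"] == "nonregular") & (~dataset["correct"])]
    prev_pressed = dataset.groupby(subject)["pressed_key"].shift(1)
    repetition = dataset["pressed_key"] == prev_pressed
    d = d[~repetition.loc[d.index]]
    per = (
        d.groupby(subject)
        .agg(
            n_errors=("pressed_key", "size"),
            prop_rule_adhering=("motor_regular", "mean"),
        )
        .reset_index()
    )
    all_ids = dataset[subject].unique()
    n_excluded = len(all_ids) - len(per)
    baseline = chance_baseline(6, 2)
    vals = per["prop_rule_adhering"].to_numpy()
    if len(vals) > 1:
        t, p = stats.ttest_1samp(vals, baseline, alternative="greater")
    else:
        t, p = np.nan, np.nan
    return per, BaselineTest(
        float(np.mean(vals)) if len(vals) else np.nan,
        float(t), float(p), len(vals) - 1, baseline, n_excluded,
    )


def error_rt_analysis(
    dataset: pd.DataFrame, subject: str = "participant"
) -> pd.DataFrame:
    """Mean error RT per participant x (motor regularity, block pair).

    Only error responses enter; the result is a long cell-means table
    ready for :func:`mixed_anova` with ``response_regularity`` as a
    within factor.
    """
    d = dataset[~dataset["correct"]].copy()
    d["response_regularity"] = np.where(d["motor_regular"], "motor_regular", "motor_nonregular")
    per = (
        d.groupby([subject, "response_regularity", "block_pair"], observed=True)["rt_ms"]
        .mean()
        .rename("rt_error")
        .reset_index()
    )
    return per


def within_subject_ci(
    cell_means: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    subject: str = "participant",
    ci: float = 0.95,
) -> pd.DataFrame:
    """Cousineau-Morey within-subject confidence intervals per cell.

    Each participant's cell means are recentred on the grand mean
    (removing between-subject level differences), the cell SDs of the
    recentred values are inflated by the Morey factor sqrt(k/(k-1)) for
    k within cells, and a t-based CI is formed.  Use for plots of
    within-participant contrasts; between-subject CIs come from
    :func:`aggregate_cells`.
    """
    data = cell_means.copy()
    grand = data[dv].mean()
    subj_means = data.groupby(subject)[dv].transform("mean")
    data["_norm"] = data[dv] - subj_means + grand
    k = data.groupby(within, observed=True).ngroups
    morey = np.sqrt(k / max(k - 1, 1))

    def _summ(g: pd.Series) -> pd.Series:
        n = g.notna().sum()
        m = g.mean()
        half = (
            stats.t.ppf(0.5 + ci / 2.0, n - 1) * morey * g.std(ddof=1) / np.sqrt(n)
            if n > 1 else np.nan
        )
        return pd.Series({"mean": m, "ci_low": m - half, "ci_high": m + half, "n": n})

    out = data.groupby(list(within), observed=True)["_norm"].apply(_summ).unstack().reset_index()
    # means are reported on the raw scale (normalization preserves cell means
    # only up to participant balance; recompute them directly)
    raw = data.groupby(list(within), observed=True)[dv].mean().reset_index(name="raw_mean")
    out = out.merge(raw, on=list(within))
    shift = out["raw_mean"] - out["mean"]
    out["mean"] = out["raw_mean"]
    out["ci_low"] += shift
    out["ci_high"] += shift
    return out.drop(columns="raw_mean")


def score_free_recall(reported: Iterable[int], seq: SequenceSpec) -> int:
    """Number of correctly reported sequence transitions (0-6).

    Counts adjacent pairs in the report that are successor pairs of the
    sequence; a full-length report is read cyclically (its last-to-first
    transition counts too), so a perfect report scores 6.
    """
    rep = list(reported)
    succ = seq.successor_map()
    for loc in rep:
        if loc not in succ:
            raise ValueError(f"invalid location symbol {loc!r}")
    if not rep:
        return 0
    pairs = list(zip(rep[:-1], rep[1:]))
    if len(rep) == seq.n_locations:
        pairs.append((rep[-1], rep[0]))
    score = sum(1 for a, b in pairs if succ[a] == b)
    return min(score, seq.n_locations)


def classify_awareness(score: InterviewScore) -> str:
    """Three-way awareness classification from the interview.

    *implicit*: believes the material was random and reproduces fewer
    than two transitions in both tests; *explicit*: believes it was
    sequenced and reproduces all six transitions in both tests;
    everything in between is *intermediate*.
    """
    if (
        not score.belief_sequenced
        and score.free_recall_correct < 2
        and score.forced_choice_correct < 2
    ):
        return IMPLICIT
    if (
        score.belief_sequenced
        and score.free_recall_correct == 6
        and score.forced_choice_correct == 6
    ):
        return EXPLICIT
    return INTERMEDIATE
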
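"""Participant screening and trial filtering for SRTT datasets.

Screening excludes participants who, in at least one of block pairs 2-7,
exceed a 50% error rate or respond too slowly (deadline violations) on
more than 30% of trials; block pair 1 (with its deadline ramp) never
triggers exclusion, and both thresholds are strict inequalities.

Trial filtering removes, independently and then as a union: trials that
follow an error or deadline violation (post-feedback trials), the first
four trials of each block, and trials with RTs below 20 ms or above 2 s.
Error responses that survive these filters are retained — they feed the
rule-adhering-error and error-RT analyses as well as the DDM likelihood.
Deadline-exceeded trials are additionally dropped when preparing data
for DDM fitting (their observed RT competes with the deadline), which is
exposed as a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ScreeningReport", "screen_participants", "filter_trials", "assign_block_pairs"]


@dataclass
class ScreeningReport:
    """Per-participant screening rates and inclusion decisions."""

    rates: pd.DataFrame  # participant x block_pair error/too-slow rates (long form)
    included: pd.DataFrame  # participant, included flag, exclusion reason

    @property
    def included_ids(self) -> list:
        return list(self.included.loc[self.included["included"], "participant"])

    @property
    def excluded_ids(self) -> list:
        return list(self.included.loc[~self.included["included"], "participant"])


def assign_block_pairs(dataset: pd.DataFrame, n_blocks: int | None = None) -> pd.DataFrame:
    """Add/overwrite the block_pair column: pair = ceil(block / 2)."""
    blocks = dataset["block"].to_numpy()
    upper = int(blocks.max()) if n_blocks is None else n_blocks
    if blocks.min() < 1 or (n_blocks is not None and blocks.max() > n_blocks):
        raise ValueError(f"block indices must lie in [1..{upper}]")
    out = dataset.copy()
    out["block_pair"] = (out["block"] + 1) // 2
    return out


def screen_participants(
    dataset: pd.DataFrame,
    error_threshold: float = 0.50,
    slow_threshold: float = 0.30,
    screened_pairs: tuple[int, int] = (2, 7),
) -> ScreeningReport:
    """Apply the per-block-pair performance screening.

    A participant is excluded iff, in at least one block pair within
    ``screened_pairs`` (inclusive), the error rate strictly exceeds
    ``error_threshold`` or the deadline-violation rate strictly exceeds
    ``slow_threshold``.  Rates are computed over all trials of the pair.
    """
    if dataset.empty:
        raise ValueError("empty dataset")
    data = dataset if "block_pair" in dataset.columns else assign_block_pairs(dataset)
    expected_pairs = set(range(1, int(data["block_pair"].max()) + 1))
    rates = (
        data.groupby(["participant", "block_pair"])
        .agg(
            error_rate=("correct", lambda c: 1.0 - np.mean(c)),
            slow_rate=("deadline_exceeded", "mean"),
            n_trials=("correct", "size"),
        )
        .reset_index()
    )
    rows = []
    lo, hi = screened_pairs
    for pid, sub in rates.groupby("participant"):
        if set(sub["block_pair"]) != expected_pairs:
            raise ValueError(f"participant {pid} has missing blocks")
        window = sub[(sub["block_pair"] >= lo) & (sub["block_pair"] <= hi)]
        bad_err = window["error_rate"] > error_threshold
        bad_slow = window["slow_rate"] > slow_threshold
        reasons = []
        if bad_err.any():
            pairs = window.loc[bad_err, "block_pair"].tolist()
            reasons.append(f"error rate > {error_threshold:.0%} in block pair(s) {pairs}")
        if bad_slow.any():
            pairs = window.loc[bad_slow, "block_pair"].tolist()
            reasons.append(f"too-slow rate > {slow_threshold:.0%} in block pair(s) {pairs}")
        rows.append(
            {
                "participant": pid,
                "included": not reasons,
                "reason": "; ".join(reasons),
            }
        )
    return ScreeningReport(rates=rates, included=pd.DataFrame(rows))


def filter_trials(
    dataset: pd.DataFrame,
    rt_min_ms: float = 20.0,
    rt_max_ms: float = 2000.0,
    first_trials_per_block: int = 4,
    drop_deadline_exceeded: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Remove post-feedback trials, block warm-up trials and RT outliers.

    Returns the filtered dataset and per-rule removal counts (counted
    independently before the union is dropped, so they can overlap).
    Set ``drop_deadline_exceeded`` when preparing data for DDM fitting.
    """
    post_feedback = dataset["post_feedback"].to_numpy(dtype=bool)
    warmup = dataset["trial"].to_numpy() <= first_trials_per_block
    too_fast = dataset["rt_ms"].to_numpy() < rt_min_ms
    too_slow = dataset["rt_ms"].to_numpy() > rt_max_ms
    drop = post_feedback | warmup | too_fast | too_slow
    counts = {
        "post_feedback": int(post_feedback.sum()),
        "first_trials": int(warmup.sum()),
        "rt_too_fast": int(too_fast.sum()),
        "rt_too_slow": int(too_slow.sum()),
    }
    if drop_deadline_exceeded:
        exceeded = dataset["deadline_exceeded"].to_numpy(dtype=bool)
        drop = drop | exceeded
        counts["deadline_exceeded"] = int(exceeded.sum())
    counts["removed_total"] = int(drop.sum())
    counts["retained"] = int((~drop).sum())
    return dataset.loc[~drop].reset_index(drop=True), pd.Series(counts, name="n_trials")
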
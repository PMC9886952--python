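"""Trial-, block- and participant-level exclusion rules and aggregation.

The pipeline mirrors the standard RT-cleaning sequence for additional-
singleton experiments:

1. remove incorrect, no-response and anticipatory (< 200 ms) trials;
2. remove whole blocks with accuracy below 50% (accuracy computed on the
   raw, unfiltered trials, counting no-responses as incorrect);
3. exclude participants (low accuracy in more than one block, grand-mean
   RT beyond 2.5 SD of their task group, or no responses in the practice
   block; a stricter criterion additionally drops participants with any
   single block below 50%);
4. trim RT outliers beyond 2.5 SD of the participant x condition x block
   cell mean.

Boundary conventions: rt = 200 ms is retained, a trial at exactly 2.5 SD is
retained, accuracy of exactly 50% is retained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExclusionReport",
    "filter_trials",
    "trim_outliers",
    "drop_low_accuracy_blocks",
    "exclude_participants",
    "remove_location_repeats",
    "aggregate",
    "preprocess",
]

logger = logging.getLogger(__name__)

RT_FLOOR = 200.0
OUTLIER_SD = 2.5
ACCURACY_FLOOR = 0.5


@dataclass
class ExclusionReport:
    """Bookkeeping for every removal step."""

    n_trials_in: int = 0
    n_removed_error_or_fast: int = 0
    n_removed_outlier: int = 0
    n_blocks_removed: int = 0
    n_removed_block_trials: int = 0
    n_removed_participant_trials: int = 0
    participants_removed: list[tuple[str, str]] = field(default_factory=list)
    n_trials_out: int = 0

    @property
    def n_removed_total(self) -> int:
        return (self.n_removed_error_or_fast + self.n_removed_outlier
                + self.n_removed_block_trials + self.n_removed_participant_trials)

    def merge(self, other: "ExclusionReport") -> "ExclusionReport":
        return ExclusionReport(
            n_trials_in=self.n_trials_in,
            n_removed_error_or_fast=self.n_removed_error_or_fast
            + other.n_removed_error_or_fast,
            n_removed_outlier=self.n_removed_outlier + other.n_removed_outlier,
            n_blocks_removed=self.n_blocks_removed + other.n_blocks_removed,
            n_removed_block_trials=self.n_removed_block_trials
            + other.n_removed_block_trials,
            n_removed_participant_trials=self.n_removed_participant_trials
            + other.n_removed_participant_trials,
            participants_removed=self.participants_removed
            + other.participants_removed,
            n_trials_out=other.n_trials_out,
        )

    def to_dict(self) -> dict:
        return {
            "n_trials_in": self.n_trials_in,
            "n_removed_error_or_fast": self.n_removed_error_or_fast,
            "n_removed_outlier": self.n_removed_outlier,
            "n_blocks_removed": self.n_blocks_removed,
            "n_removed_block_trials": self.n_removed_block_trials,
            "n_removed_participant_trials": self.n_removed_participant_trials,
            "participants_removed": [list(t) for t in self.participants_removed],
            "n_trials_out": self.n_trials_out,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def __str__(self) -> str:  # plain-text report
        lines = [
            f"trials in:                 {self.n_trials_in}",
            f"removed error/no-resp/fast:{self.n_removed_error_or_fast:>7}",
            f"removed 2.5-SD outliers:   {self.n_removed_outlier:>7}",
            f"blocks removed (<50% acc): {self.n_blocks_removed:>7}",
            f"participants removed:      {len(self.participants_removed):>7}",
        ]
        for pid, reason in self.participants_removed:
            lines.append(f"    {pid}: {reason}")
        lines.append(f"trials out:                {self.n_trials_out}")
        return "\n".join(lines)


def _responded(trials: pd.DataFrame) -> pd.Series:
    return trials["rt"].notna()


def _block_accuracy(trials: pd.DataFrame) -> pd.DataFrame:
    """Accuracy per participant x block on all attempted trials
    (no-response counted as incorrect)."""
    acc = (trials["correct"] & _responded(trials)).groupby(
        [trials["participant_id"], trials["block"]]
    ).mean()
    return acc.rename("accuracy").reset_index()


def filter_trials(trials: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Remove incorrect, no-response and < 200 ms trials."""
    report = ExclusionReport(n_trials_in=len(trials))
    keep = trials["correct"] & _responded(trials) & (trials["rt"] >= RT_FLOOR)
    out = trials.loc[keep]
    report.n_removed_error_or_fast = int((~keep).sum())
    report.n_trials_out = len(out)
    return out, report


def trim_outliers(trials: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Trim trials beyond 2.5 SD of their participant x condition x block cell.

    SD uses the n-1 denominator; cells with fewer than 2 trials (or zero SD)
    are left untouched.  A trial at exactly 2.5 SD is retained.
    """
    report = ExclusionReport(n_trials_in=len(trials))
    if trials.empty:
        return trials, report
    grp = trials.groupby(["participant_id", "condition", "block"])["rt"]
    mean = grp.transform("mean")
    sd = grp.transform("std")  # ddof=1; NaN for singleton cells
    n = grp.transform("size")
    z_ok = (trials["rt"] - mean).abs() <= OUTLIER_SD * sd
    keep = (n < 2) | sd.isna() | (sd == 0) | z_ok
    degenerate = int(((n < 2) | (sd == 0)).sum())
    if degenerate:
        logger.debug("trim_outliers: %d trials in degenerate cells", degenerate)
    out = trials.loc[keep]
    report.n_removed_outlier = int((~keep).sum())
    report.n_trials_out = len(out)
    return out, report


def drop_low_accuracy_blocks(
    trials: pd.DataFrame, reference: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Remove all trials of participant x block cells with accuracy < 50%.

    Accuracy is computed on ``reference`` (the raw, pre-filtering table;
    defaults to the input itself) so the rule can run after error-trial
    removal without trivially seeing 100% accuracy.
    """
    report = ExclusionReport(n_trials_in=len(trials))
    ref = trials if reference is None else reference
    if trials.empty:
        return trials, report
    acc = _block_accuracy(ref)
    bad = acc.loc[acc["accuracy"] < ACCURACY_FLOOR, ["participant_id", "block"]]
    key = pd.MultiIndex.from_frame(trials[["participant_id", "block"]])
    bad_key = pd.MultiIndex.from_frame(bad)
    keep = ~key.isin(bad_key)
    out = trials.loc[keep]
    report.n_blocks_removed = len(bad)
    report.n_removed_block_trials = int((~keep).sum())
    report.n_trials_out = len(out)
    return out, report


def exclude_participants(
    trials: pd.DataFrame,
    criterion: str = "standard",
    reference: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply participant-level exclusion rules.

    standard: accuracy < 50% in more than one block, grand-mean RT beyond
    2.5 SD of the participant's task group, or zero responses in the
    practice block.  strict: additionally, any single block (including
    practice) below 50% accuracy.  Accuracy and practice-response rules use
    ``reference`` (raw table, defaults to the input).
    """
    if criterion not in ("standard", "strict"):
        raise ValueError(f"unknown criterion {criterion!r}")
    report = ExclusionReport(n_trials_in=len(trials))
    ref = trials if reference is None else reference
    if trials.empty:
        return trials, report

    removed: dict[str, str] = {}
    acc = _block_accuracy(ref)
    low = acc.loc[acc["accuracy"] < ACCURACY_FLOOR]
    n_low = low.groupby("participant_id").size()
    for pid in n_low.index[n_low > 1]:
        removed.setdefault(pid, "low_accuracy_multi_block")

    grand = trials.groupby(["task", "participant_id"])["rt"].mean()
    for task, sub in grand.groupby(level="task"):
        mu, sd = sub.mean(), sub.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            continue
        for (_, pid), val in sub.items():
            if abs(val - mu) > OUTLIER_SD * sd:
                removed.setdefault(pid, "slow_rt")

    practice = ref.loc[ref["block"] == 1]
    responded = _responded(practice).groupby(practice["participant_id"]).sum()
    all_pids = ref["participant_id"].unique()
    for pid in all_pids:
        if responded.get(pid, 0) == 0:
            removed.setdefault(pid, "no_practice_responses")

    if criterion == "strict":
        for pid in n_low.index[n_low >= 1]:
            removed.setdefault(pid, "strict_any_block")

    keep = ~trials["participant_id"].isin(removed)
    out = trials.loc[keep]
    report.participants_removed = sorted(removed.items())
    report.n_removed_participant_trials = int((~keep).sum())
    report.n_trials_out = len(out)
    return out, report


def remove_location_repeats(trials: pd.DataFrame) -> pd.DataFrame:
    """Drop distractor-present trials whose distractor location repeats the
    immediately preceding trial of the same participant (session order)."""
    ordered = trials.sort_values(["participant_id", "block", "trial"])
    prev = ordered.groupby("participant_id")["distractor_location"].shift(1)
    repeat = (
        ordered["distractor_location"].notna()
        & prev.notna()
        & (ordered["distractor_location"] == prev)
    )
    return trials.loc[ordered.index[~repeat]]


_GROUPINGS = {
    "condition": ["condition"],
    "block_condition": ["block", "condition"],
    "distance": ["distance_to_hp"],
    "target_at_hp": ["target_at_hp"],
}


def aggregate(trials: pd.DataFrame, by: str = "condition") -> pd.DataFrame:
    """Per-participant cell mean RTs.

    Groupings: "condition", "block_condition" (the learning-curve input;
    the only grouping that keeps the practice block), "distance"
    (distractor-present trials by distance to the HP location) and
    "target_at_hp" (distractor-absent trials, target at vs. away from the
    HP location).
    """
    if by not in _GROUPINGS:
        raise ValueError(f"unknown grouping {by!r}; one of {sorted(_GROUPINGS)}")
    df = trials
    if by != "block_condition":
        df = df.loc[df["block"] > 1]  # practice excluded everywhere else
    if by == "distance":
        df = df.loc[df["condition"] != "absent"]
    elif by == "target_at_hp":
        df = df.loc[df["condition"] == "absent"].copy()
        df["target_at_hp"] = df["distance_to_hp"] == 0.0
    keys = ["participant_id", "task"] + _GROUPINGS[by]
    out = (
        df.groupby(keys, observed=True)["rt"]
        .agg(mean_rt="mean", n_trials="size")
        .reset_index()
    )
    if out["n_trials"].eq(0).any():  # pragma: no cover - groupby drops these
        logger.warning("aggregate: empty cells omitted")
    return out


def preprocess(
    trials: pd.DataFrame, criterion: str = "standard"
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Full cleaning pipeline in the fixed order.

    filter_trials -> drop_low_accuracy_blocks -> exclude_participants ->
    trim_outliers, with block/participant accuracy rules evaluated on the
    raw input table.
    """
    raw = trials
    out, report = filter_trials(trials)
    out, r2 = drop_low_accuracy_blocks(out, reference=raw)
    report = report.merge(r2)
    out, r3 = exclude_participants(out, criterion=criterion, reference=raw)
    report = report.merge(r3)
    out, r4 = trim_outliers(out)
    report = report.merge(r4)
    return out, report
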
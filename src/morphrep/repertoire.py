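"""Gesture-action repertoire construction and frequency statistics.

Covers the 3-token repertoire threshold, the per-action contribution table
(token counts, percentages, cumulative percentages, deviation from the
uniform-use expectation), the regular-use prefix, accumulation/asymptote
curves, and the overall gesturing rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .util import round_half_away

DEFAULT_MIN_TOKENS = 3
DEFAULT_REGULAR_USE_TARGET = 0.695


@dataclass
class ThresholdReport:
    min_tokens: int
    excluded_actions: dict[str, int]

    @property
    def n_excluded_tokens(self) -> int:
        return sum(self.excluded_actions.values())


def apply_repertoire_threshold(
    tokens: pd.DataFrame, min_tokens: int = DEFAULT_MIN_TOKENS
) -> tuple[pd.DataFrame, list[str], ThresholdReport]:
    """Drop actions observed fewer than ``min_tokens`` times, with their tokens."""
    counts = tokens["gesture_action"].value_counts()
    kept_actions = sorted(counts.index[counts >= min_tokens])
    excluded = {a: int(counts[a]) for a in sorted(counts.index[counts < min_tokens])}
    kept = tokens[tokens["gesture_action"].isin(kept_actions)].copy()
    return kept, kept_actions, ThresholdReport(min_tokens, excluded)


def build_contribution_table(tokens: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-action contribution rows sorted by descending token count.

    Returns the table and the average contribution (tokens per action under
    uniform selection from the repertoire, unrounded; round for display).
    Ties in token count are broken alphabetically for stable output.
    """
    if len(tokens) == 0:
        raise ValueError("empty repertoire")
    counts = tokens["gesture_action"].value_counts()
    frame = (
        counts.rename_axis("gesture_action")
        .reset_index(name="token_count")
        .sort_values(["token_count", "gesture_action"], ascending=[False, True])
        .reset_index(drop=True)
    )
    total = int(frame["token_count"].sum())
    n_actions = len(frame)
    average = total / n_actions
    share = frame["token_count"] / total
    frame["contribution_pct"] = [round_half_away(100 * s, 1) for s in share]
    frame["cumulative_pct"] = [
        round_half_away(100 * c, 1) for c in share.cumsum()
    ]
    frame["deviation_from_average"] = [
        int(round_half_away(c - total / n_actions)) for c in frame["token_count"]
    ]
    return frame, average


def regular_use_set(
    table: pd.DataFrame, target_fraction: float = DEFAULT_REGULAR_USE_TARGET
) -> list[str]:
    """Minimal prefix of most-frequent actions whose unrounded token share
    reaches ``target_fraction``."""
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    total = table["token_count"].sum()
    cumulative = table["token_count"].cumsum() / total
    n = int(np.searchsorted(cumulative.to_numpy(), target_fraction, side="left")) + 1
    return table["gesture_action"].head(n).tolist()


@dataclass
class AccumulationCurve:
    points: np.ndarray  # distinct units observed after token 1..n
    last_novelty_index: int  # 1-based token index of the final first occurrence
    n_tokens: int
    envelope_mean: np.ndarray | None = None
    envelope_low: np.ndarray | None = None
    envelope_high: np.ndarray | None = None

    @property
    def last_novelty_fraction(self) -> float:
        return self.last_novelty_index / self.n_tokens

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"token_index": np.arange(1, self.n_tokens + 1), "units_observed": self.points}
        )
        if self.envelope_mean is not None:
            frame["permutation_mean"] = self.envelope_mean
            frame["permutation_low"] = self.envelope_low
            frame["permutation_high"] = self.envelope_high
        return frame


def _curve(labels: np.ndarray) -> tuple[np.ndarray, int]:
    seen: set = set()
    points = np.empty(len(labels), dtype=int)
    last_novel = 0
    for i, label in enumerate(labels):
        if label not in seen:
            seen.add(label)
            last_novel = i + 1
        points[i] = len(seen)
    return points, last_novel


def accumulation_curve(
    tokens: pd.DataFrame,
    unit_of: str = "action",
    n_permutations: int = 0,
    seed: int | None = None,
) -> AccumulationCurve:
    """Unit-detection curve over observed order, optionally with a
    permutation (rarefaction) envelope.

    ``unit_of`` selects the repertoire unit: ``"action"`` uses the
    gesture-action label, ``"morph"`` expects a ``morph_id`` column.
    """
    if unit_of == "action":
        column = "gesture_action"
    elif unit_of == "morph":
        column = "morph_id"
    else:
        raise ValueError(f"unknown unit_of {unit_of!r}")
    if column not in tokens.columns:
        raise ValueError(f"tokens lack required column {column!r}")
    ordered = tokens.sort_values("order_index")
    labels = ordered[column].to_numpy()
    points, last_novel = _curve(labels)
    curve = AccumulationCurve(points, last_novel, len(labels))
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        stack = np.empty((n_permutations, len(labels)), dtype=int)
        for p in range(n_permutations):
            stack[p], _ = _curve(rng.permutation(labels))
        curve.envelope_mean = stack.mean(axis=0)
        curve.envelope_low = np.percentile(stack, 2.5, axis=0)
        curve.envelope_high = np.percentile(stack, 97.5, axis=0)
    return curve


def overall_rate(tokens: pd.DataFrame, effort: pd.DataFrame) -> float:
    """Tokens per follow-hour over the whole dataset."""
    follow = effort.drop_duplicates(subset=["group_id", "season_id"])["follow_hours"].sum()
    if follow <= 0:
        raise ValueError("total follow hours must be positive")
    return len(tokens) / follow


@dataclass
class FlagSummary:
    """Shared/new composition of the repertoire, from per-action flags."""

    n_actions: int
    n_new: int
    new_token_count: int
    total_tokens: int
    excluded_new: list[str] = field(default_factory=list)

    @property
    def shared_pct(self) -> float:
        return 100.0 * (self.n_actions - self.n_new) / self.n_actions

    @property
    def new_token_pct(self) -> float:
        return 100.0 * self.new_token_count / self.total_tokens


def flag_summary(table: pd.DataFrame, new_actions: frozenset[str] | set[str]) -> FlagSummary:
    """Summarise the contribution of flagged (potentially species-specific)
    actions within a contribution table."""
    in_table = set(table["gesture_action"])
    new_in_table = in_table & set(new_actions)
    new_tokens = int(
        table.loc[table["gesture_action"].isin(new_in_table), "token_count"].sum()
    )
    return FlagSummary(
        n_actions=len(in_table),
        n_new=len(new_in_table),
        new_token_count=new_tokens,
        total_tokens=int(table["token_count"].sum()),
        excluded_new=sorted(set(new_actions) - in_table),
    )
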
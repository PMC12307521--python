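"""Reading, validation, and writing of the three input tables.

All files are UTF-8 comma-separated with a mandatory header row.  Output
tables are written with a fixed column order so that ``read(write(T)) == T``
holds field-for-field for any valid table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .vocab import MODIFIERS, ModifierVocabulary, OUTCOMES

TOKEN_COLUMNS: tuple[str, ...] = (
    "token_id",
    "communication_id",
    "signaller_id",
    "recipient_id",
    "gesture_action",
    "body_part",
    "contact_recipient",
    "lateral_use",
    "repetition",
    "context_after",
    "group_id",
    "season_id",
    "order_index",
    "outcome",
)

INDIVIDUAL_COLUMNS: tuple[str, ...] = (
    "individual_id",
    "sex",
    "birth_date",
    "parity_dates",
)

EFFORT_COLUMNS: tuple[str, ...] = (
    "season_id",
    "group_id",
    "individual_id",
    "season_start",
    "season_end",
    "follow_hours",
    "video_hours",
)


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class TokenValidationError(ValueError):
    """One or more rows violate the token contract; offending rows are listed."""

    def __init__(self, message: str, rows: list[dict]):
        super().__init__(message)
        self.rows = rows


def _require_columns(frame: pd.DataFrame, required: Iterable[str], path: str | Path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_tokens(path: str | Path, vocab: ModifierVocabulary) -> pd.DataFrame:
    """Read and validate a gesture-token table.

    Rows with gesture actions or modifier levels outside the declared
    vocabulary are rejected with a :class:`TokenValidationError` that names
    every offending row; nothing is silently coerced.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(frame, TOKEN_COLUMNS, path)
    frame = frame[list(TOKEN_COLUMNS)].copy()
    frame["order_index"] = frame["order_index"].astype(int)

    bad: list[dict] = []
    for idx, row in frame.iterrows():
        problems = []
        if not vocab.is_valid_action(row["gesture_action"]):
            problems.append(f"unknown gesture_action {row['gesture_action']!r}")
        for modifier in MODIFIERS:
            if not vocab.is_valid_level(modifier, row[modifier]):
                problems.append(f"unknown {modifier} level {row[modifier]!r}")
        if row["outcome"] not in OUTCOMES:
            problems.append(f"unknown outcome {row['outcome']!r}")
        if row["signaller_id"] == row["recipient_id"]:
            problems.append("signaller_id equals recipient_id")
        if problems:
            bad.append({"row": int(idx), "token_id": row["token_id"], "problems": problems})
    if bad:
        raise TokenValidationError(
            f"{path}: {len(bad)} invalid row(s): {bad[:5]}", rows=bad
        )
    dupes = frame["token_id"][frame["token_id"].duplicated()].unique().tolist()
    if dupes:
        raise TokenValidationError(
            f"{path}: duplicated token_id(s) {dupes[:5]}",
            rows=[{"token_id": t, "problems": ["duplicate token_id"]} for t in dupes],
        )
    return frame


def write_tokens(tokens: pd.DataFrame, path: str | Path) -> None:
    tokens[list(TOKEN_COLUMNS)].to_csv(path, index=False)


def read_individuals(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(frame, INDIVIDUAL_COLUMNS, path)
    frame = frame[list(INDIVIDUAL_COLUMNS)].copy()
    bad_sex = frame.loc[~frame["sex"].isin(("female", "male")), "individual_id"].tolist()
    if bad_sex:
        raise TokenValidationError(
            f"{path}: invalid sex for {bad_sex}",
            rows=[{"individual_id": i, "problems": ["invalid sex"]} for i in bad_sex],
        )
    males_with_parity = frame.loc[
        (frame["sex"] == "male") & (frame["parity_dates"] != ""), "individual_id"
    ].tolist()
    if males_with_parity:
        raise TokenValidationError(
            f"{path}: parity_dates set for male(s) {males_with_parity}",
            rows=[{"individual_id": i, "problems": ["parity on male"]} for i in males_with_parity],
        )
    return frame


def write_individuals(individuals: pd.DataFrame, path: str | Path) -> None:
    individuals[list(INDIVIDUAL_COLUMNS)].to_csv(path, index=False)


def read_effort(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(frame, EFFORT_COLUMNS, path)
    frame = frame[list(EFFORT_COLUMNS)].copy()
    frame["follow_hours"] = frame["follow_hours"].astype(float)
    frame["video_hours"] = frame["video_hours"].astype(float)
    if (frame["follow_hours"] < 0).any() or (frame["video_hours"] < 0).any():
        raise TokenValidationError(f"{path}: negative hours", rows=[])
    return frame


def write_effort(effort: pd.DataFrame, path: str | Path) -> None:
    out = effort[list(EFFORT_COLUMNS)].copy()
    out.to_csv(path, index=False)


@dataclass
class ValidationFailure:
    kind: str
    message: str


@dataclass
class ValidationReport:
    """Cross-referential consistency report; validation itself never raises."""

    failures: list[ValidationFailure] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures

    def to_json(self) -> str:
        return json.dumps(
            {"ok": self.ok, "failures": [vars(f) for f in self.failures]},
            indent=2,
        )


def validate_dataset(
    tokens: pd.DataFrame,
    individuals: pd.DataFrame,
    effort: pd.DataFrame,
) -> ValidationReport:
    """Check cross-references between the three tables without mutating them."""
    report = ValidationReport()
    known = set(individuals["individual_id"])
    for col, kind in (("signaller_id", "orphan signaller"), ("recipient_id", "orphan recipient")):
        for token_id, value in tokens.loc[~tokens[col].isin(known), ["token_id", col]].itertuples(
            index=False
        ):
            report.failures.append(
                ValidationFailure(kind, f"token {token_id}: {col} {value!r} not in individuals")
            )
    effort_keys = set(zip(effort["group_id"], effort["season_id"]))
    seen_pairs = tokens[["group_id", "season_id", "token_id"]].drop_duplicates(
        subset=["group_id", "season_id"]
    )
    for group_id, season_id, token_id in seen_pairs.itertuples(index=False):
        if (group_id, season_id) not in effort_keys:
            report.failures.append(
                ValidationFailure(
                    "orphan group-season",
                    f"token {token_id}: ({group_id}, {season_id}) not in effort table",
                )
            )
    collisions = tokens["order_index"][tokens["order_index"].duplicated()].unique()
    for value in collisions:
        report.failures.append(
            ValidationFailure("order collision", f"order_index {value} occurs more than once")
        )
    return report
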
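"""Individual repertoire sizes, gesturing rates, and maturation classes.

Repertoire sizes count distinct gesture actions per signaller at two
thresholds (used at least once, used at least three times).  Rates divide a
signaller's token count by group-follow hours (``igr_obs``) or by hours of
video featuring the individual (``igr_vid``); zero denominators yield a
missing rate, never zero.

Maturation classes: cat-1 infants (0-3 y, both sexes); cat-2 juveniles
(>3-6 y); cat-3 subadults (>6-8 y, both sexes) plus blackbacks (males
>8-12 y) and young nulliparous females (8 to <12 y); cat-4 adults (males
>12 y, parous females, nulliparous females >=12 y).  An individual crossing
a boundary within a season is resolved to the class holding the majority of
their tokens that season; a female giving birth within a season counts as
parous for that whole season.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

CLASSES = ("cat1_infant", "cat2_juvenile", "cat3_subadult_blackback_nulliparous", "cat4_adult")

_CLASS_ORDER = {name: i for i, name in enumerate(CLASSES)}


def maturation_class(age_years: float, sex: str, parous: bool = False) -> str:
    """Age/sex/parity rules mapping to one of the four maturation classes."""
    if age_years < 0:
        raise ValueError("age must be non-negative")
    if sex not in ("female", "male"):
        raise ValueError(f"unknown sex {sex!r}")
    if age_years <= 3:
        return CLASSES[0]
    if age_years <= 6:
        return CLASSES[1]
    if sex == "male":
        return CLASSES[2] if age_years <= 12 else CLASSES[3]
    if parous:
        return CLASSES[3]
    return CLASSES[2] if age_years < 12 else CLASSES[3]


def resolve_season_class(token_counts: Mapping[str, int]) -> str:
    """Majority-token rule for within-season boundary crossings.

    Ties are broken toward the more mature class, deterministically.
    """
    if not token_counts:
        raise ValueError("no candidate classes")
    return max(token_counts, key=lambda c: (token_counts[c], _CLASS_ORDER[c]))


@dataclass(frozen=True)
class MaturationAssignment:
    individual_id: str
    season_id: str
    maturation_class: str
    sex: str


def assign_maturation_classes(
    individuals: pd.DataFrame, effort: pd.DataFrame
) -> pd.DataFrame:
    """One maturation class per (individual, season), using the age at the
    season midpoint and the parity state at the season end."""
    seasons = effort.drop_duplicates(subset=["season_id"])[
        ["season_id", "season_start", "season_end"]
    ]
    rows = []
    for _, ind in individuals.iterrows():
        birth = pd.Timestamp(ind["birth_date"])
        parity_dates = [
            pd.Timestamp(d) for d in str(ind["parity_dates"]).split(";") if d
        ]
        present = set(
            effort.loc[effort["individual_id"] == ind["individual_id"], "season_id"]
        )
        for _, season in seasons.iterrows():
            if season["season_id"] not in present:
                continue
            start = pd.Timestamp(season["season_start"])
            end = pd.Timestamp(season["season_end"])
            midpoint = start + (end - start) / 2
            age = (midpoint - birth).days / 365.25
            if age < 0:
                continue  # not yet born that season
            parous = any(d <= end for d in parity_dates)
            rows.append(
                {
                    "individual_id": ind["individual_id"],
                    "season_id": season["season_id"],
                    "maturation_class": maturation_class(age, ind["sex"], parous),
                    "sex": ind["sex"],
                }
            )
    return pd.DataFrame(rows, columns=["individual_id", "season_id", "maturation_class", "sex"])


def compute_irs(tokens: pd.DataFrame, threshold: int = 1) -> pd.Series:
    """Distinct gesture actions used at least ``threshold`` times, per signaller."""
    counts = tokens.groupby(["signaller_id", "gesture_action"]).size()
    return (
        (counts >= threshold)
        .groupby("signaller_id")
        .sum()
        .astype(int)
        .rename(f"irs_{threshold}")
    )


def compute_igr(tokens: pd.DataFrame, effort: pd.DataFrame) -> pd.DataFrame:
    """Per-signaller gesturing rates.

    ``igr_obs`` divides by the follow hours of the signaller's group over the
    seasons in which they appear in the effort table; ``igr_vid`` divides by
    their summed video hours.  Zero denominators give NaN.
    """
    token_counts = tokens.groupby("signaller_id").size().rename("token_count")
    follow = (
        effort.groupby("individual_id")["follow_hours"].sum().rename("follow_hours")
    )
    video = effort.groupby("individual_id")["video_hours"].sum().rename("video_hours")
    frame = pd.concat([token_counts, follow, video], axis=1).fillna(
        {"token_count": 0}
    )
    frame = frame[frame.index.isin(effort["individual_id"])]
    frame["igr_obs"] = np.where(
        frame["follow_hours"] > 0, frame["token_count"] / frame["follow_hours"], np.nan
    )
    frame["igr_vid"] = np.where(
        frame["video_hours"] > 0, frame["token_count"] / frame["video_hours"], np.nan
    )
    frame.index.name = "individual_id"
    return frame[["token_count", "follow_hours", "video_hours", "igr_obs", "igr_vid"]]


def individual_summaries(tokens: pd.DataFrame, effort: pd.DataFrame) -> pd.DataFrame:
    """IRS_1, IRS_3, IGR_obs, IGR_vid and token counts per signaller."""
    irs1 = compute_irs(tokens, 1)
    irs3 = compute_irs(tokens, 3)
    igr = compute_igr(tokens, effort)
    frame = igr.join(irs1, how="left").join(irs3, how="left")
    frame[["irs_1", "irs_3"]] = frame[["irs_1", "irs_3"]].fillna(0).astype(int)
    frame["token_count"] = frame["token_count"].astype(int)
    return frame[["token_count", "irs_1", "irs_3", "igr_obs", "igr_vid", "follow_hours", "video_hours"]]


def summarize_by_class(
    tokens: pd.DataFrame,
    assignments: pd.DataFrame,
    effort: pd.DataFrame,
) -> pd.DataFrame:
    """Mean/sd/range of IRS and IGR per maturation class and sex.

    An individual contributes one data point per class they occupy across
    seasons; within a season they sit in exactly one class.  Each data point
    is computed from the individual's tokens (and effort) in the seasons
    assigned to that class.
    """
    merged = tokens.merge(
        assignments,
        left_on=["signaller_id", "season_id"],
        right_on=["individual_id", "season_id"],
        how="inner",
    )
    effort_classed = effort.merge(
        assignments, on=["individual_id", "season_id"], how="inner"
    )
    rows = []
    memberships = assignments[
        assignments["individual_id"].isin(set(tokens["signaller_id"]))
    ][["individual_id", "maturation_class", "sex"]].drop_duplicates()
    for individual_id, cls, sex in memberships.itertuples(index=False):
        sub_tokens = merged[
            (merged["signaller_id"] == individual_id)
            & (merged["maturation_class"] == cls)
        ]
        sub_effort = effort_classed[
            (effort_classed["individual_id"] == individual_id)
            & (effort_classed["maturation_class"] == cls)
        ]
        irs1 = sub_tokens["gesture_action"].nunique()
        action_counts = sub_tokens.groupby("gesture_action").size()
        irs3 = int((action_counts >= 3).sum())
        follow = sub_effort["follow_hours"].sum()
        video = sub_effort["video_hours"].sum()
        rows.append(
            {
                "individual_id": individual_id,
                "maturation_class": cls,
                "sex": sex,
                "token_count": len(sub_tokens),
                "irs_1": irs1,
                "irs_3": irs3,
                "igr_obs": len(sub_tokens) / follow if follow > 0 else np.nan,
                "igr_vid": len(sub_tokens) / video if video > 0 else np.nan,
            }
        )
    points = pd.DataFrame(rows)
    if points.empty:
        return points
    grouped = points.groupby(["maturation_class", "sex"])
    summary = grouped.agg(
        n_data_points=("individual_id", "size"),
        irs_1_mean=("irs_1", "mean"),
        irs_1_sd=("irs_1", "std"),
        irs_1_min=("irs_1", "min"),
        irs_1_max=("irs_1", "max"),
        irs_3_mean=("irs_3", "mean"),
        irs_3_sd=("irs_3", "std"),
        igr_obs_mean=("igr_obs", "mean"),
        igr_obs_sd=("igr_obs", "std"),
        igr_vid_mean=("igr_vid", "mean"),
    ).reset_index()
    summary.attrs["data_points"] = points
    return summary
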
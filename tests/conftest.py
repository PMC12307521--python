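from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from morphrep import (
    GroupSeasonEffort,
    IndividualSpec,
    PlantedAction,
    PlantedComponent,
    SyntheticConfig,
    default_vocabulary,
    generate_dataset,
    reference_profile,
)
from morphrep.io import TOKEN_COLUMNS


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()


def make_tokens(actions, **overrides) -> pd.DataFrame:
    """Minimal valid token table with one row per entry of ``actions``.

    Column values can be overridden with a scalar or a per-row sequence.
    """
    n = len(actions)
    base = {
        "token_id": [f"T{i:04d}" for i in range(n)],
        "communication_id": [f"C{i:04d}" for i in range(n)],
        "signaller_id": ["ind1"] * n,
        "recipient_id": ["ind2"] * n,
        "gesture_action": list(actions),
        "body_part": ["hand"] * n,
        "contact_recipient": ["contact"] * n,
        "lateral_use": ["left"] * n,
        "repetition": ["single"] * n,
        "context_after": ["resting"] * n,
        "group_id": ["group_a"] * n,
        "season_id": ["S1"] * n,
        "order_index": list(range(1, n + 1)),
        "outcome": ["successful"] * n,
    }
    for key, value in overrides.items():
        base[key] = list(value) if not np.isscalar(value) else [value] * n
    return pd.DataFrame(base)[list(TOKEN_COLUMNS)]


def planted_action(
    name: str,
    share: float,
    configs: list[dict],
    weights: list[float] | None = None,
    epsilon: float = 0.0,
    **kwargs,
) -> PlantedAction:
    weights = weights or [1.0 / len(configs)] * len(configs)
    return PlantedAction(
        gesture_action=name,
        target_token_share=share,
        components=tuple(
            PlantedComponent(configuration=c, weight=w) for c, w in zip(configs, weights)
        ),
        noise_epsilon=epsilon,
        **kwargs,
    )


def small_population() -> tuple[IndividualSpec, ...]:
    return (
        IndividualSpec("ind1", "male", 25.0, "group_a", video_hours=20.0),
        IndividualSpec("ind2", "female", 20.0, "group_a", parity_ages=(15.0,), video_hours=15.0),
        IndividualSpec("ind3", "male", 5.0, "group_a", video_hours=10.0),
        IndividualSpec("ind4", "female", 22.0, "group_b", parity_ages=(16.0,), video_hours=12.0),
        IndividualSpec("ind5", "male", 9.0, "group_b", video_hours=9.0),
        IndividualSpec("ind6", "female", 2.0, "group_b", video_hours=5.0),
    )


def small_effort() -> tuple[GroupSeasonEffort, ...]:
    return (
        GroupSeasonEffort("group_a", "S1", 40.0, "2020-06-01", "2020-08-31"),
        GroupSeasonEffort("group_a", "S2", 35.0, "2021-06-01", "2021-08-31"),
        GroupSeasonEffort("group_b", "S1", 30.0, "2020-06-01", "2020-08-31"),
        GroupSeasonEffort("group_b", "S2", 25.0, "2021-06-01", "2021-08-31"),
    )


def small_config(seed: int = 0, n_tokens: int = 300, epsilon: float = 0.0) -> SyntheticConfig:
    actions = (
        planted_action(
            "Alpha",
            0.4,
            [
                {"body_part": "hand", "contact_recipient": "contact",
                 "lateral_use": "left", "repetition": "single"},
                {"body_part": "foot", "contact_recipient": "no_contact",
                 "lateral_use": "right", "repetition": "repeated"},
            ],
            epsilon=epsilon,
        ),
        planted_action(
            "Beta",
            0.3,
            [
                {"body_part": "arm", "contact_recipient": "contact",
                 "lateral_use": "both", "repetition": "single"},
            ],
        ),
        planted_action(
            "Gamma",
            0.2,
            [
                {"body_part": "head", "contact_recipient": "no_contact",
                 "lateral_use": "left", "repetition": "repeated"},
                {"body_part": "mouth", "contact_recipient": "contact",
                 "lateral_use": "right", "repetition": "single"},
                {"body_part": "torso", "contact_recipient": "no_contact",
                 "lateral_use": "both", "repetition": "single"},
            ],
            epsilon=epsilon,
        ),
        planted_action(
            "Delta",
            0.08,
            [
                {"body_part": "fingers", "contact_recipient": "contact",
                 "lateral_use": "left", "repetition": "single"},
            ],
            is_new=True,
        ),
        planted_action(
            "Epsilon",
            0.02,
            [
                {"body_part": "leg", "contact_recipient": "no_contact",
                 "lateral_use": "right", "repetition": "single"},
            ],
        ),
    )
    return SyntheticConfig(
        n_tokens=n_tokens,
        actions=actions,
        population=small_population(),
        effort=small_effort(),
        context_probs={"resting": 0.5, "playing": 0.3, "grooming": 0.15, "unknown": 0.05},
        n_communications=max(2, n_tokens // 2),
        unclear_rate=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def profile_dataset():
    return generate_dataset(reference_profile(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config(seed=3))
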
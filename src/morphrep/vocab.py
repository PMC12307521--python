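"""Closed vocabularies for gesture modifiers and the per-action applicability map.

Modifier levels are a declared, closed set per modifier.  Two literal level
strings are reserved across all modifiers: ``"unclear"`` (the coder could not
determine the level) and ``"not_applicable"`` (the modifier is not meaningful
for that gesture action).  Tokens carrying ``"unclear"`` on an applicable
modifier are excluded from morph detection upstream of the latent-class fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

MODIFIERS: tuple[str, ...] = (
    "body_part",
    "contact_recipient",
    "lateral_use",
    "repetition",
)

UNCLEAR = "unclear"
NOT_APPLICABLE = "not_applicable"
RESERVED_LEVELS = frozenset({UNCLEAR, NOT_APPLICABLE})

OUTCOMES: tuple[str, ...] = ("successful", "unsuccessful", "unknown")

#: context label reserved for communications whose signaller context could
#: not be estimated; kept out of the <1% pooling rule.
UNKNOWN_CONTEXT = "unknown"


@dataclass(frozen=True)
class ModifierVocabulary:
    """Closed level sets per modifier plus an optional applicability map.

    Parameters
    ----------
    levels
        Mapping from modifier name to the tuple of admissible substantive
        levels (the reserved literals are always admissible in data files and
        need not be listed).
    applicability
        Optional mapping from gesture action to the tuple of modifiers that
        are meaningful for it.  Actions absent from the map are treated as
        having all four modifiers applicable.
    gesture_actions
        Optional closed set of gesture-action labels.  When ``None`` the
        action vocabulary is open and any label is accepted.
    """

    levels: Mapping[str, tuple[str, ...]]
    applicability: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    gesture_actions: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for modifier in MODIFIERS:
            if modifier not in self.levels:
                raise ValueError(f"vocabulary missing modifier {modifier!r}")
            overlap = RESERVED_LEVELS.intersection(self.levels[modifier])
            if overlap:
                raise ValueError(
                    f"modifier {modifier!r} declares reserved level(s) {sorted(overlap)}"
                )

    def is_valid_level(self, modifier: str, level: str) -> bool:
        if level in RESERVED_LEVELS:
            return True
        return level in self.levels[modifier]

    def is_valid_action(self, action: str) -> bool:
        return self.gesture_actions is None or action in self.gesture_actions

    def applicable_modifiers(self, action: str) -> tuple[str, ...]:
        return tuple(self.applicability.get(action, MODIFIERS))


DEFAULT_LEVELS: dict[str, tuple[str, ...]] = {
    "body_part": (
        "hand",
        "foot",
        "arm",
        "leg",
        "head",
        "mouth",
        "torso",
        "fingers",
    ),
    "contact_recipient": ("contact", "no_contact"),
    "lateral_use": ("left", "right", "both"),
    "repetition": ("single", "repeated"),
}


def default_vocabulary(
    applicability: Mapping[str, Sequence[str]] | None = None,
    gesture_actions: Sequence[str] | None = None,
) -> ModifierVocabulary:
    """Vocabulary with the stock level sets, optionally closed over actions."""
    app = {a: tuple(m) for a, m in (applicability or {}).items()}
    acts = tuple(gesture_actions) if gesture_actions is not None else None
    return ModifierVocabulary(levels=dict(DEFAULT_LEVELS), applicability=app, gesture_actions=acts)
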
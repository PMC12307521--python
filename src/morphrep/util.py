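"""Small numeric helpers shared across modules."""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np


def round_half_away(value: float, decimals: int = 0) -> float:
    """Round half away from zero (matching typical table presentation).

    ``round_half_away(2.5) == 3``, ``round_half_away(-2.5) == -3``.
    """
    factor = 10**decimals
    scaled = value * factor
    rounded = math.floor(abs(scaled) + 0.5) * (1 if scaled >= 0 else -1)
    out = rounded / factor
    return out if decimals > 0 else float(int(out))


def largest_remainder(weights: Sequence[float], total: int) -> np.ndarray:
    """Allocate ``total`` integer units proportionally to ``weights``.

    Uses the largest-remainder (Hamilton) rule: floor the exact quotas, then
    hand out the remaining units in order of descending fractional part
    (ties broken by position, for determinism).
    """
    weights = np.asarray(weights, dtype=float)
    if (weights < 0).any():
        raise ValueError("weights must be non-negative")
    if total < 0:
        raise ValueError("total must be non-negative")
    if weights.sum() == 0:
        if total:
            raise ValueError("cannot allocate a positive total over zero weights")
        return np.zeros(len(weights), dtype=int)
    quotas = weights / weights.sum() * total
    base = np.floor(quotas).astype(int)
    remainder = total - int(base.sum())
    if remainder:
        order = np.lexsort((np.arange(len(weights)), -(quotas - base)))
        base[order[:remainder]] += 1
    return base
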
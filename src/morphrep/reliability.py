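"""Inter-rater reliability: proportional subsampling and agreement statistics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .util import largest_remainder

DEFAULT_FRACTION = 0.05


def proportional_subsample(
    tokens: pd.DataFrame,
    fraction: float = DEFAULT_FRACTION,
    seed: int | None = None,
) -> pd.DataFrame:
    """Random subset with per-action sample sizes proportional to each
    action's representation (largest-remainder rounding of the quotas)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_target = int(round(fraction * len(tokens)))
    counts = tokens["gesture_action"].value_counts().sort_index()
    allocation = largest_remainder(counts.to_numpy(), n_target)
    rng = np.random.default_rng(seed)
    picks = []
    for action, n_take in zip(counts.index, allocation):
        if n_take == 0:
            continue
        pool = tokens.index[tokens["gesture_action"] == action].to_numpy()
        picks.append(rng.choice(pool, size=n_take, replace=False))
    chosen = np.concatenate(picks) if picks else np.array([], dtype=int)
    return tokens.loc[np.sort(chosen)]


@dataclass
class AgreementResult:
    variable: str
    n_items: int
    percentage_agreement: float  # in [0, 100]
    kappa: float | None  # None when chance agreement is 1 (single shared category)


def agreement_stats(
    labels_rater1: Sequence[str],
    labels_rater2: Sequence[str],
    variable: str = "",
) -> AgreementResult:
    """Percentage agreement and unweighted Cohen's kappa.

    kappa = (p_o - p_e) / (1 - p_e) with p_e the product-of-marginals chance
    agreement; undefined (None) when p_e == 1.
    """
    a = pd.Series(list(labels_rater1))
    b = pd.Series(list(labels_rater2))
    if len(a) != len(b):
        raise ValueError(f"label sequences differ in length ({len(a)} vs {len(b)})")
    if len(a) == 0:
        raise ValueError("empty label sequences")
    n = len(a)
    p_o = float((a.to_numpy() == b.to_numpy()).mean())
    categories = sorted(set(a) | set(b))
    marg_a = a.value_counts(normalize=True)
    marg_b = b.value_counts(normalize=True)
    p_e = float(
        sum(marg_a.get(c, 0.0) * marg_b.get(c, 0.0) for c in categories)
    )
    kappa = None if abs(1.0 - p_e) < 1e-12 else (p_o - p_e) / (1.0 - p_e)
    return AgreementResult(
        variable=variable,
        n_items=n,
        percentage_agreement=100.0 * p_o,
        kappa=kappa,
    )


def agreement_table(
    rater1: pd.DataFrame, rater2: pd.DataFrame, variables: Sequence[str]
) -> pd.DataFrame:
    """Agreement statistics for several coded variables at once."""
    rows = []
    for variable in variables:
        result = agreement_stats(rater1[variable], rater2[variable], variable)
        rows.append(
            {
                "variable": result.variable,
                "n_items": result.n_items,
                "percentage_agreement": result.percentage_agreement,
                "kappa": result.kappa,
            }
        )
    return pd.DataFrame(rows)
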
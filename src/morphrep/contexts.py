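"""Signaller behavioural context at the end of each communication.

Counts are at the communication level (one context per communication), not
the token level.  Contexts contributing less than the pooling threshold of
the raw distribution are pooled into "Other"; communications with unknown
context are reported separately and never pooled.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .vocab import UNKNOWN_CONTEXT

POOL_LABEL = "Other"
POOL_THRESHOLD_PCT = 1.0


class ContextConflictError(ValueError):
    """A communication carries more than one context value."""


@dataclass
class ContextDistribution:
    table: pd.DataFrame  # context, n_communications, pct (raw, unpooled)
    pooled: pd.DataFrame  # after the <threshold pooling rule
    n_communications: int


def context_distribution(
    tokens: pd.DataFrame, pool_threshold_pct: float = POOL_THRESHOLD_PCT
) -> ContextDistribution:
    """Distribution of communication-final signaller context."""
    per_comm = tokens.groupby("communication_id")["context_after"].agg(["nunique", "first"])
    conflicts = per_comm.index[per_comm["nunique"] > 1].tolist()
    if conflicts:
        raise ContextConflictError(
            f"communications with conflicting context: {conflicts[:5]}"
            + ("..." if len(conflicts) > 5 else "")
        )
    counts = per_comm["first"].value_counts()
    n = int(counts.sum())
    raw = (
        counts.rename_axis("context")
        .reset_index(name="n_communications")
        .assign(pct=lambda f: 100.0 * f["n_communications"] / n)
    )
    pool_mask = (raw["pct"] < pool_threshold_pct) & (raw["context"] != UNKNOWN_CONTEXT)
    kept = raw[~pool_mask].copy()
    if pool_mask.any():
        pooled_row = pd.DataFrame(
            {
                "context": [POOL_LABEL],
                "n_communications": [int(raw.loc[pool_mask, "n_communications"].sum())],
                "pct": [float(raw.loc[pool_mask, "pct"].sum())],
            }
        )
        kept = pd.concat([kept, pooled_row], ignore_index=True)
    kept = kept.sort_values(
        ["n_communications", "context"], ascending=[False, True]
    ).reset_index(drop=True)
    return ContextDistribution(table=raw, pooled=kept, n_communications=n)
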
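"""Small-cell suppression for exportable aggregates.

Export policy: an aggregate row may only leave the enclave if it combines
data from at least ``min_participants`` distinct participants (default 20).
Suppression is by distinct participants, not event rows.  Aggregates that
have no participant dimension (e.g. per-vocabulary value counts) are exempt
but must be flagged as such in report metadata — suppression never silently
passes over a table that *should* carry participant counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import ProfileConfig, DEFAULT_CONFIG


@dataclass
class SuppressionOutcome:
    """Accounting for one suppression pass: every input row is accounted for."""

    rows_in: int
    rows_out: int
    rows_suppressed: int
    threshold: int

    def __post_init__(self):
        if self.rows_out + self.rows_suppressed != self.rows_in:
            raise ValueError("suppression accounting does not balance")


def suppress_small_cells(
    records: pd.DataFrame,
    config: ProfileConfig = DEFAULT_CONFIG,
    participant_column: str = "participant_count",
) -> tuple[pd.DataFrame, SuppressionOutcome]:
    """Drop aggregate rows representing fewer than the threshold participants.

    Raises if the participant-count column is missing or has missing values:
    a table that cannot prove its cell sizes must not be exported.
    """
    if participant_column not in records.columns:
        raise ValueError(f"suppression requires a '{participant_column}' column")
    counts = records[participant_column]
    if counts.isna().any():
        raise ValueError(f"'{participant_column}' has missing values; cannot certify cells")
    keep = counts >= config.min_participants
    out = records[keep].reset_index(drop=True)
    outcome = SuppressionOutcome(
        rows_in=len(records),
        rows_out=len(out),
        rows_suppressed=int((~keep).sum()),
        threshold=config.min_participants,
    )
    return out, outcome
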
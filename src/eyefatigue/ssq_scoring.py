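"""Simulator Sickness Questionnaire scoring.

Sixteen symptom items are rated 0-3; each item contributes with unit weight
to one or two of the nausea (N), oculomotor (O), and disorientation (D)
columns.  The total severity is the sum of the three column scores times
3.74 (the classic SSQ total).  Converted N/O/D sub-scales are out of scope;
column scores are exposed as raw weighted sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from eyefatigue.errors import ValidationError

#: Canonical item order of the questionnaire.
SSQ_ITEMS = (
    "general_discomfort",
    "fatigue",
    "headache",
    "eye_fatigue",
    "difficulty_focusing",
    "increased_salivation",
    "sweating",
    "nausea",
    "difficulty_concentrating",
    "fullness_of_head",
    "blurred_vision",
    "dizzy_eyes_open",
    "dizzy_eyes_closed",
    "vertigo",
    "stomach_awareness",
    "burping",
)

#: Unit-weight column membership (canonical N/O/D assignment).
SSQ_COLUMNS: dict[str, tuple[str, ...]] = {
    "N": (
        "general_discomfort",
        "increased_salivation",
        "sweating",
        "nausea",
        "difficulty_concentrating",
        "stomach_awareness",
        "burping",
    ),
    "O": (
        "general_discomfort",
        "fatigue",
        "headache",
        "eye_fatigue",
        "difficulty_focusing",
        "difficulty_concentrating",
        "blurred_vision",
    ),
    "D": (
        "difficulty_focusing",
        "nausea",
        "fullness_of_head",
        "blurred_vision",
        "dizzy_eyes_open",
        "dizzy_eyes_closed",
        "vertigo",
    ),
}

#: Scaling constant applied to the sum of the three column scores.
TOTAL_SCALE = 3.74

# 16 x 3 zero/one weight matrix in (N, O, D) column order
_WEIGHTS = np.array(
    [[1.0 if item in SSQ_COLUMNS[c] else 0.0 for c in ("N", "O", "D")] for item in SSQ_ITEMS]
)


@dataclass(frozen=True)
class SSQScore:
    """Column scores (raw weighted sums) and the scaled total."""

    col_N: float
    col_O: float
    col_D: float
    total: float


def _validate(response: Sequence[int]) -> np.ndarray:
    arr = np.asarray(response)
    if arr.shape != (len(SSQ_ITEMS),):
        raise ValidationError(
            f"SSQ response must have exactly {len(SSQ_ITEMS)} items, got shape {arr.shape}"
        )
    for idx, v in enumerate(arr):
        if v not in (0, 1, 2, 3):
            raise ValidationError(
                f"SSQ item {idx} ({SSQ_ITEMS[idx]}) has score {v!r}, expected 0..3"
            )
    return arr.astype(float)


def score_ssq(response: Sequence[int]) -> SSQScore:
    """Score one 16-item response.

    Column scores are the weighted sums down the N/O/D columns; the total is
    their sum scaled by 3.74.
    """
    arr = _validate(response)
    n, o, d = arr @ _WEIGHTS
    return SSQScore(col_N=float(n), col_O=float(o), col_D=float(d), total=float((n + o + d) * TOTAL_SCALE))


def score_ssq_table(responses: pd.DataFrame) -> pd.DataFrame:
    """Score a table with ``subject``, ``epoch`` and ``item_1..item_16`` columns."""
    item_cols = [f"item_{i}" for i in range(1, len(SSQ_ITEMS) + 1)]
    missing = [c for c in ("subject", "epoch", *item_cols) if c not in responses.columns]
    if missing:
        raise ValidationError(f"SSQ table missing columns: {missing}")
    rows = []
    for _, row in responses.iterrows():
        s = score_ssq([int(row[c]) for c in item_cols])
        rows.append(
            {
                "subject": row["subject"],
                "epoch": row["epoch"],
                "col_N": s.col_N,
                "col_O": s.col_O,
                "col_D": s.col_D,
                "total": s.total,
            }
        )
    return pd.DataFrame(rows)
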
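"""Creativity scoring by rater consensus and inter-rater agreement.

Each divergent-thinking response is scored 0/1 independently by exactly
three raters; a response earns a point when at least two raters award it.
Participant creativity totals sum response points.  Agreement between rater
pairs is Cohen's kappa on their binary decision vectors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["read_rater_table", "consensus_scores", "cohen_kappa"]

RATER_COLUMNS = ("id", "response", "rater", "awarded")


def read_rater_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str, "response": str, "rater": str})
    missing = [c for c in RATER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rater table {path} missing column(s) {missing}")
    if not df["awarded"].isin((0, 1)).all():
        raise ValueError("awarded column must be binary 0/1")
    return df[list(RATER_COLUMNS)]


def consensus_scores(table: pd.DataFrame) -> pd.Series:
    """Per-participant creativity totals under two-of-three majority consensus.

    Raises if any response does not have exactly 3 rater rows.  The result
    is invariant to rater order and response order.
    """
    counts = table.groupby(["id", "response"])["rater"].count()
    bad = counts[counts != 3]
    if not bad.empty:
        key = bad.index[0]
        raise ValueError(
            f"response {key[1]!r} of participant {key[0]!r} has "
            f"{int(bad.iloc[0])} rater rows, expected 3"
        )
    points = (table.groupby(["id", "response"])["awarded"].sum() >= 2).astype(int)
    totals = points.groupby("id").sum()
    totals.name = "creativity"
    return totals


def cohen_kappa(a, b) -> float:
    """Cohen's kappa between two equal-length binary rating vectors.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e from the
    marginal rating proportions.  When p_e = 1 (both raters constant) the
    convention kappa = 1 if the raters agree everywhere, else 0, applies.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("inputs must be equal-length 1-d vectors")
    p_o = float(np.mean(a == b))
    pa1, pb1 = float(np.mean(a)), float(np.mean(b))
    p_e = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)
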
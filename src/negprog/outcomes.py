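"""Outcome definitions used as classification labels.

Two binary endpoints at the 9-month follow-up:

* **Moderate/severe negative symptoms** — any of the SIPS negative-symptom
  items N1 (social anhedonia), N2 (avolition), N3 (expression of emotion),
  N4 (experience of emotions and self) or N6 (occupational functioning)
  rated >= 3.  N5 (ideational richness) is deliberately excluded from both
  predictors and labels.
* **Impaired functioning** — a Global Functioning (Social or Role) score of
  7 or fewer points; more than 7 counts as adequate.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

#: SIPS negative items entering predictors and labels (N5 excluded).
SIPS_N_ITEMS: tuple[str, ...] = ("N1", "N2", "N3", "N4", "N6")

#: Minimum item rating counting as moderate/severe.
MODERATE_THRESHOLD: int = 3

#: Maximum Global Functioning score counting as impaired.
GF_IMPAIRED_MAX: int = 7

NEGSYM_LABEL = "negsym_bad"
GF_SOCIAL_LABEL = "gf_social_impaired"
GF_ROLE_LABEL = "gf_role_impaired"


def label_negative_symptoms(items_t1: Sequence[int]) -> int:
    """Label a subject from the five follow-up SIPS-N item ratings.

    Parameters
    ----------
    items_t1
        Ratings for N1, N2, N3, N4, N6 (in that order), each an integer
        in 0..6.  Exactly five values; N5 must not be passed.

    Returns
    -------
    int
        1 if any item is rated >= 3 (moderate/severe), else 0.
    """
    items = list(items_t1)
    if len(items) != len(SIPS_N_ITEMS):
        raise ValueError(
            f"expected {len(SIPS_N_ITEMS)} item ratings (N1,N2,N3,N4,N6), got {len(items)}"
        )
    for name, v in zip(SIPS_N_ITEMS, items):
        if not float(v).is_integer() or not 0 <= int(v) <= 6:
            raise ValueError(f"SIPS item {name} rating {v!r} outside the 0..6 scale")
    return int(max(int(v) for v in items) >= MODERATE_THRESHOLD)


def label_functioning(gf_score: int) -> int:
    """1 (impaired) iff the Global Functioning score is 7 or fewer points."""
    if not float(gf_score).is_integer() or not 1 <= int(gf_score) <= 10:
        raise ValueError(f"Global Functioning score {gf_score!r} outside the 1..10 scale")
    return int(int(gf_score) <= GF_IMPAIRED_MAX)


def add_outcome_labels(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a cohort table with the three binary label columns.

    Subjects with any missing follow-up item or GF score are dropped
    (complete-case labelling).
    """
    item_cols = [f"sips_{i.lower()}_t1" for i in SIPS_N_ITEMS]
    required = item_cols + ["gf_social_t1", "gf_role_t1"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise KeyError(f"cohort table lacks follow-up columns: {missing}")
    out = table.dropna(subset=required).copy()
    items = out[item_cols].to_numpy()
    out[NEGSYM_LABEL] = (items.max(axis=1) >= MODERATE_THRESHOLD).astype(int)
    out[GF_SOCIAL_LABEL] = (out["gf_social_t1"].to_numpy() <= GF_IMPAIRED_MAX).astype(int)
    out[GF_ROLE_LABEL] = (out["gf_role_t1"].to_numpy() <= GF_IMPAIRED_MAX).astype(int)
    return out
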
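"""Cross-validation-ratio (CVR) feature-importance profiles.

Linear model weights vary across cross-validation folds; a feature matters
reliably when its mean fold weight is large relative to its fold-to-fold
standard error: ``CVR = mean(w) / SE(w)``, with each fold's weight vector
first normalized to unit Euclidean norm so that fold-specific scaling of the
decision function cannot inflate the profile.  A negative CVR means reduced
values of the predictor are associated with increased risk; a positive CVR
means the reverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CVRProfile:
    """Per-feature mean weight, standard error, CVR and |CVR| rank."""

    table: pd.DataFrame  # columns: feature, mean_w, se_w, cvr, rank, degenerate

    def top(self, n: int = 10) -> pd.DataFrame:
        ranked = self.table[~self.table["degenerate"]]
        return ranked.sort_values("rank").head(n).reset_index(drop=True)


def cvr_profile(
    weight_vectors: np.ndarray,
    feature_names: tuple[str, ...] | None = None,
    normalize: bool = True,
) -> CVRProfile:
    """CVR profile from K fold-wise weight vectors over F features.

    Each vector is normalized to unit L2 norm (disable with
    ``normalize=False`` if the vectors are already comparable); per feature,
    SE is the sample standard deviation (divisor K-1) over folds divided by
    sqrt(K).  Features with zero SE are flagged as degenerate (CVR set to
    NaN) and excluded from the ranking.
    """
    W = np.asarray(weight_vectors, dtype=float)
    if W.ndim != 2:
        raise ValueError("weight_vectors must be a K x F matrix")
    k, f = W.shape
    if k < 2:
        raise ValueError(f"CVR requires at least 2 fold weight vectors, got {k}")
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(f))
    if len(feature_names) != f:
        raise ValueError("feature_names length does not match the weight vectors")

    if normalize:
        norms = np.linalg.norm(W, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("cannot unit-normalize an all-zero weight vector")
        W = W / norms

    mean_w = W.mean(axis=0)
    se_w = W.std(axis=0, ddof=1) / np.sqrt(k)
    degenerate = se_w == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cvr = np.where(degenerate, np.nan, mean_w / np.where(degenerate, 1.0, se_w))

    table = pd.DataFrame(
        {
            "feature": list(feature_names),
            "mean_w": mean_w,
            "se_w": se_w,
            "cvr": cvr,
            "degenerate": degenerate,
        }
    )
    order = table.loc[~degenerate, "cvr"].abs().sort_values(ascending=False).index
    table["rank"] = pd.Series(
        np.arange(1, len(order) + 1), index=order, dtype="float"
    ).reindex(table.index)
    return CVRProfile(table=table)
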
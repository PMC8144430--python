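"""Predictor-matrix assembly: feature views, ICV normalization, fold-safe scaling.

Two feature views exist: the five baseline SIPS negative items (``sips_n``)
and the 68 ROI gyrification values (``gyrification``).  Gyrification is
normalized for intracranial volume by proportional division against the
*training* cohort's mean ICV; z-standardization parameters are likewise
estimated on training partitions only, so no test-set statistic ever leaks
into preprocessing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import ROI_COLUMNS
from .outcomes import SIPS_N_ITEMS

SIPS_N_VIEW = "sips_n"
GYRIFICATION_VIEW = "gyrification"
VIEWS = (SIPS_N_VIEW, GYRIFICATION_VIEW)

SIPS_N_COLUMNS: tuple[str, ...] = tuple(f"sips_{i.lower()}_t0" for i in SIPS_N_ITEMS)


@dataclass
class FeatureMatrix:
    """Subjects x features matrix with aligned names and ids."""

    matrix: np.ndarray
    feature_names: tuple[str, ...]
    subject_ids: tuple[str, ...]
    view: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        expected = {SIPS_N_VIEW: len(SIPS_N_COLUMNS), GYRIFICATION_VIEW: len(ROI_COLUMNS)}
        if self.view in expected and self.matrix.shape[1] != expected[self.view]:
            raise ValueError(
                f"view {self.view!r} requires {expected[self.view]} columns, "
                f"got {self.matrix.shape[1]}"
            )
        if self.matrix.shape[0] != len(self.subject_ids):
            raise ValueError("rows do not align with subject_ids")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite entries")


def view_columns(view: str) -> tuple[str, ...]:
    if view == SIPS_N_VIEW:
        return SIPS_N_COLUMNS
    if view == GYRIFICATION_VIEW:
        return tuple(ROI_COLUMNS)
    raise ValueError(f"unknown feature view {view!r}; expected one of {VIEWS}")


def build_features(table: pd.DataFrame, view: str) -> FeatureMatrix:
    """Extract the predictor matrix of ``view`` from a cohort table."""
    cols = view_columns(view)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"cohort table lacks feature columns for view {view!r}: {missing}")
    return FeatureMatrix(
        matrix=table[list(cols)].to_numpy(dtype=float),
        feature_names=cols,
        subject_ids=tuple(table["subject_id"].astype(str)),
        view=view,
    )


def normalize_by_icv(
    roi_values: np.ndarray, icv: np.ndarray | float, reference_icv: float
) -> np.ndarray:
    """Proportionally rescale ROI values to a reference intracranial volume.

    ``normalized = roi * reference_icv / icv`` — gyrification correlates with
    brain volume, so each subject's values are rescaled to the training
    cohort's mean ICV (``reference_icv``).
    """
    icv_arr = np.asarray(icv, dtype=float)
    if np.any(icv_arr <= 0):
        raise ValueError("icv must be strictly positive")
    if not reference_icv > 0:
        raise ValueError("reference_icv must be strictly positive")
    values = np.asarray(roi_values, dtype=float)
    factor = reference_icv / icv_arr
    if values.ndim == 2 and icv_arr.ndim == 1:
        return values * factor[:, None]
    return values * factor


@dataclass
class ScalerParams:
    """Per-feature location/scale estimated on a training partition.

    Population-SD convention (divisor n).  Zero-variance features are flagged
    and scaled by 1 rather than dividing by zero.
    """

    loc: np.ndarray
    scale: np.ndarray
    degenerate: np.ndarray  # boolean mask of zero-variance features


def fit_scaler(train: np.ndarray) -> ScalerParams:
    X = np.asarray(train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("scaler requires a 2-D training matrix with >= 2 rows")
    loc = X.mean(axis=0)
    scale = X.std(axis=0)  # ddof=0
    degenerate = scale == 0.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance feature(s); scaled by 1",
            RuntimeWarning,
            stacklevel=2,
        )
        scale = np.where(degenerate, 1.0, scale)
    return ScalerParams(loc=loc, scale=scale, degenerate=degenerate)


def apply_scaler(params: ScalerParams, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return (X - params.loc) / params.scale
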
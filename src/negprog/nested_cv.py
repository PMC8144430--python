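"""Nested cross-validation with leave-site-out outer folds.

The outer loop holds out each recruitment site once (probing geographic
generalizability); the inner loop is stratified k-fold cross-validation with
r repetitions (defaults k=5, r=10) on the outer-training subjects only, used
to pick the regularization strength of an L2-regularized linear classifier
(logistic loss by default, hinge loss optional).  All inner-loop models at
the winning hyperparameter are retained as ensemble members, each carrying
its own preprocessing (training-fold ICV reference and z-scaler); held-out
subjects receive the mean member decision score, with predicted label
``score > 0``.  A stacking model combines the out-of-site decision scores of
base models as meta-features under the same nested scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import LinearSVC

from .features import (
    GYRIFICATION_VIEW,
    FeatureMatrix,
    ScalerParams,
    apply_scaler,
    build_features,
    fit_scaler,
    normalize_by_icv,
)

DEFAULT_GRID: tuple[float, ...] = tuple(np.logspace(-3, 3, 7))
LOSSES = ("logistic", "hinge")

STACKED_VIEW = "stacked"


class LeakageError(ValueError):
    """Raised when an operation would let test information into training."""


@dataclass
class CVScheme:
    """Leave-site-out outer partition plus inner-CV settings."""

    subject_ids: tuple[str, ...]
    sites: np.ndarray
    outer: list[tuple[np.ndarray, np.ndarray, str]]  # (train_idx, test_idx, test_site)
    inner_k: int = 5
    inner_r: int = 10
    seed: int = 0

    @property
    def site_of(self) -> dict[str, str]:
        return dict(zip(self.subject_ids, self.sites))


def make_lso_scheme(
    cohort: pd.DataFrame,
    y: np.ndarray | None = None,
    inner_k: int = 5,
    inner_r: int = 10,
    seed: int = 0,
) -> CVScheme:
    """One outer fold per site; inner folds are defined later on each
    outer-training set.  Every outer training partition must contain both
    outcome classes."""
    if "site_id" not in cohort.columns:
        raise KeyError("cohort table lacks a 'site_id' column")
    sites = cohort["site_id"].to_numpy()
    unique_sites = sorted(pd.unique(sites))
    if len(unique_sites) < 2:
        raise ValueError("leave-site-out requires at least 2 sites")
    if y is None and "negsym_bad" in cohort.columns:
        y = cohort["negsym_bad"].to_numpy()
    outer = []
    for site in unique_sites:
        test_idx = np.flatnonzero(sites == site)
        train_idx = np.flatnonzero(sites != site)
        if y is not None and len(np.unique(np.asarray(y)[train_idx])) < 2:
            raise ValueError(
                f"outer training set for held-out site {site!r} contains a single class"
            )
        outer.append((train_idx, test_idx, site))
    return CVScheme(
        subject_ids=tuple(cohort["subject_id"].astype(str)),
        sites=sites,
        outer=outer,
        inner_k=inner_k,
        inner_r=inner_r,
        seed=seed,
    )


@dataclass
class Member:
    """One linear decision function with its private preprocessing."""

    w: np.ndarray
    intercept: float
    scaler: ScalerParams | None
    reference_icv: float | None
    c: float

    def decision(self, X: np.ndarray, icv: np.ndarray | None) -> np.ndarray:
        if self.reference_icv is not None:
            if icv is None:
                raise ValueError("member expects ICV values for normalization")
            X = normalize_by_icv(X, icv, self.reference_icv)
        if self.scaler is not None:
            X = apply_scaler(self.scaler, X)
        return X @ self.w + self.intercept


@dataclass
class FoldEnsemble:
    """All retained inner-loop models of one outer fold."""

    test_site: str
    members: list[Member]
    winning_c: float
    inner_bac: dict[float, float]  # mean inner BAC per grid value
    feature_names: tuple[str, ...]
    loss: str

    def decision(self, X: np.ndarray, icv: np.ndarray | None) -> np.ndarray:
        scores = np.stack([m.decision(X, icv) for m in self.members])
        return scores.mean(axis=0)


@dataclass
class TrainedModel:
    """Per-outer-fold ensembles plus the pooled out-of-site decision scores."""

    view: str
    fold_ensembles: list[FoldEnsemble]
    scores: pd.DataFrame  # subject_id, score, pred, fold
    subject_ids: tuple[str, ...]
    loss: str = "logistic"
    extras: dict = field(default_factory=dict)

    def weight_matrix(self) -> np.ndarray:
        """All members' weight vectors stacked (K x F), for CVR profiles."""
        return np.stack([m.w for fe in self.fold_ensembles for m in fe.members])


def _inverse_prevalence_weights(y: np.ndarray) -> np.ndarray:
    n = y.size
    w = np.empty(n, dtype=float)
    for cls in (0, 1):
        mask = y == cls
        w[mask] = n / (2.0 * mask.sum())
    return w


def _fit_linear(X: np.ndarray, y: np.ndarray, c: float, loss: str,
                sample_weight: np.ndarray | None) -> tuple[np.ndarray, float]:
    if loss == "logistic":
        model = LogisticRegression(C=c, solver="lbfgs", max_iter=2000)
    elif loss == "hinge":
        model = LinearSVC(C=c, loss="hinge", max_iter=20000)
    else:
        raise ValueError(f"loss must be one of {LOSSES}, got {loss!r}")
    model.fit(X, y, sample_weight=sample_weight)
    return model.coef_[0].copy(), float(model.intercept_[0])


def _inner_splits(y_tr: np.ndarray, k: int, r: int, seed: int):
    """Stratified inner splits; re-drawn (new seed) if a split's training part
    is single-class."""
    for attempt in range(10):
        rskf = RepeatedStratifiedKFold(n_splits=k, n_repeats=r, random_state=seed + attempt)
        splits = list(rskf.split(np.zeros_like(y_tr), y_tr))
        if all(len(np.unique(y_tr[tr])) == 2 for tr, _ in splits):
            return splits
    raise ValueError("could not draw inner splits with both classes in every training part")


def train_nested(
    features: FeatureMatrix,
    y: np.ndarray,
    scheme: CVScheme,
    grid: tuple[float, ...] = DEFAULT_GRID,
    *,
    loss: str = "logistic",
    icv: np.ndarray | None = None,
    balance_classes: bool = True,
    ensemble_rule: str = "inner_members",
) -> TrainedModel:
    """Run the full nested scheme on one feature view.

    For each outer fold the inner CV selects the grid value maximizing mean
    inner balanced accuracy; depending on ``ensemble_rule`` either all
    inner-loop models at the winning value are retained (default) or a single
    model is refit on the whole outer-training set.  Out-of-site scores for
    the held-out site are the mean member decision values.
    """
    if len(grid) == 0:
        raise ValueError("hyperparameter grid must be non-empty")
    X = features.matrix
    y = np.asarray(y).astype(int)
    if X.shape[0] != y.size:
        raise ValueError("features and labels are misaligned")
    if tuple(features.subject_ids) != tuple(scheme.subject_ids):
        raise ValueError("feature matrix subjects do not match the CV scheme")

    fold_ensembles: list[FoldEnsemble] = []
    rows: list[pd.DataFrame] = []
    for fold_idx, (train_idx, test_idx, test_site) in enumerate(scheme.outer):
        y_tr = y[train_idx]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(f"outer training set for {test_site!r} is single-class")
        fold_seed = int(np.random.SeedSequence([scheme.seed, fold_idx]).generate_state(1)[0]
                        % (2**31 - 1))
        splits = _inner_splits(y_tr, scheme.inner_k, scheme.inner_r, fold_seed)

        # Preprocess once per inner split (shared across the grid).
        prepared = []
        for tr, va in splits:
            g_tr, g_va = train_idx[tr], train_idx[va]
            ref = float(np.mean(icv[g_tr])) if icv is not None else None
            X_tr, X_va = X[g_tr], X[g_va]
            if ref is not None:
                X_tr = normalize_by_icv(X_tr, icv[g_tr], ref)
                X_va = normalize_by_icv(X_va, icv[g_va], ref)
            scaler = fit_scaler(X_tr)
            prepared.append(
                (apply_scaler(scaler, X_tr), apply_scaler(scaler, X_va),
                 y_tr[tr], y_tr[va], scaler, ref)
            )

        mean_bac: dict[float, float] = {}
        models_per_c: dict[float, list[Member]] = {c: [] for c in grid}
        for c in grid:
            bacs = []
            for X_tr, X_va, yy_tr, yy_va, scaler, ref in prepared:
                sw = _inverse_prevalence_weights(yy_tr) if balance_classes else None
                w, b = _fit_linear(X_tr, yy_tr, c, loss, sw)
                score_va = X_va @ w + b
                bacs.append(balanced_accuracy_score(yy_va, (score_va > 0).astype(int)))
                models_per_c[c].append(
                    Member(w=w, intercept=b, scaler=scaler, reference_icv=ref, c=c)
                )
            mean_bac[c] = float(np.mean(bacs))
        winning_c = max(grid, key=lambda c: mean_bac[c])

        if ensemble_rule == "inner_members":
            members = models_per_c[winning_c]
        elif ensemble_rule == "refit":
            ref = float(np.mean(icv[train_idx])) if icv is not None else None
            X_full = X[train_idx]
            if ref is not None:
                X_full = normalize_by_icv(X_full, icv[train_idx], ref)
            scaler = fit_scaler(X_full)
            sw = _inverse_prevalence_weights(y_tr) if balance_classes else None
            w, b = _fit_linear(apply_scaler(scaler, X_full), y_tr, winning_c, loss, sw)
            members = [Member(w=w, intercept=b, scaler=scaler, reference_icv=ref, c=winning_c)]
        else:
            raise ValueError(f"unknown ensemble_rule {ensemble_rule!r}")

        ensemble = FoldEnsemble(
            test_site=test_site,
            members=members,
            winning_c=float(winning_c),
            inner_bac=mean_bac,
            feature_names=features.feature_names,
            loss=loss,
        )
        fold_ensembles.append(ensemble)
        test_scores = ensemble.decision(X[test_idx], icv[test_idx] if icv is not None else None)
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": [scheme.subject_ids[i] for i in test_idx],
                    "score": test_scores,
                    "pred": (test_scores > 0).astype(int),
                    "fold": test_site,
                    "_row": test_idx,
                }
            )
        )
    scores = (
        pd.concat(rows).sort_values("_row").drop(columns="_row").reset_index(drop=True)
    )
    return TrainedModel(
        view=features.view,
        fold_ensembles=fold_ensembles,
        scores=scores,
        subject_ids=scheme.subject_ids,
        loss=loss,
    )


def fit_view(
    table: pd.DataFrame,
    y: np.ndarray,
    scheme: CVScheme,
    view: str,
    grid: tuple[float, ...] = DEFAULT_GRID,
    **kwargs,
) -> TrainedModel:
    """Convenience wrapper: assemble the view's features (with ICV for the
    gyrification view) and run :func:`train_nested`."""
    features = build_features(table, view)
    icv = table["icv"].to_numpy(dtype=float) if view == GYRIFICATION_VIEW else None
    return train_nested(features, y, scheme, grid, icv=icv, **kwargs)


def _check_out_of_fold(scores: pd.DataFrame, scheme: CVScheme) -> None:
    site_of = scheme.site_of
    merged = scores.set_index("subject_id")
    for sid in scheme.subject_ids:
        if sid not in merged.index:
            raise LeakageError(f"subject {sid!r} has no out-of-site base score")
        if merged.loc[sid, "fold"] != site_of[sid]:
            raise LeakageError(
                f"base score for subject {sid!r} is not out-of-site "
                f"(fold {merged.loc[sid, 'fold']!r} vs site {site_of[sid]!r})"
            )


def train_stacker(
    base_models: list[TrainedModel],
    y: np.ndarray,
    scheme: CVScheme,
    grid: tuple[float, ...] = DEFAULT_GRID,
    **kwargs,
) -> TrainedModel:
    """Stacking model: meta-features are the base models' out-of-site decision
    scores; the meta-learner is the same linear family under the same nested
    scheme.  Raises :class:`LeakageError` if any base score is in-sample."""
    if len(base_models) < 1:
        raise ValueError("stacking requires at least one base model")
    cols = []
    for bm in base_models:
        _check_out_of_fold(bm.scores, scheme)
        s = bm.scores.set_index("subject_id")["score"]
        cols.append(s.reindex(list(scheme.subject_ids)).to_numpy())
    meta = FeatureMatrix(
        matrix=np.column_stack(cols),
        feature_names=tuple(f"score_{bm.view}" for bm in base_models),
        subject_ids=scheme.subject_ids,
        view=STACKED_VIEW,
    )
    model = train_nested(meta, y, scheme, grid, icv=None, **kwargs)
    model.extras["base_views"] = [bm.view for bm in base_models]
    return model


def apply_external(
    model: TrainedModel,
    external: pd.DataFrame,
    *,
    evaluation: bool = True,
) -> pd.DataFrame:
    """Score an external cohort with the grand ensemble (mean over all
    members of all outer folds, each with its own stored preprocessing).

    In evaluation mode, scoring subjects that appear in the training cohort
    is refused to guard against accidental in-sample evaluation.
    """
    features = build_features(external, model.view)
    if evaluation:
        overlap = set(features.subject_ids) & set(model.subject_ids)
        if overlap:
            raise LeakageError(
                f"external cohort shares {len(overlap)} subject(s) with the training "
                "cohort; refusing to score in evaluation mode"
            )
    icv = (
        external["icv"].to_numpy(dtype=float)
        if model.view == GYRIFICATION_VIEW
        else None
    )
    member_scores = [
        m.decision(features.matrix, icv)
        for fe in model.fold_ensembles
        for m in fe.members
    ]
    scores = np.mean(member_scores, axis=0)
    return pd.DataFrame(
        {
            "subject_id": list(features.subject_ids),
            "score": scores,
            "pred": (scores > 0).astype(int),
            "fold": "external",
        }
    )


def apply_stacker_external(
    stack_model: TrainedModel,
    base_models: list[TrainedModel],
    external: pd.DataFrame,
    *,
    evaluation: bool = True,
) -> pd.DataFrame:
    """Score an external cohort with the stacked model: base grand ensembles
    produce the meta-features, then the stack's grand ensemble scores them."""
    base_scores = [
        apply_external(bm, external, evaluation=evaluation) for bm in base_models
    ]
    meta = np.column_stack([bs["score"].to_numpy() for bs in base_scores])
    member_scores = [
        m.decision(meta, None)
        for fe in stack_model.fold_ensembles
        for m in fe.members
    ]
    scores = np.mean(member_scores, axis=0)
    return pd.DataFrame(
        {
            "subject_id": base_scores[0]["subject_id"],
            "score": scores,
            "pred": (scores > 0).astype(int),
            "fold": "external",
        }
    )
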
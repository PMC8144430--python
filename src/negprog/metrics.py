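"""Classification metrics and the posterior distribution of balanced accuracy.

The positive class is the bad outcome (moderate/severe negative symptoms).
Point metrics come straight from the pooled out-of-site confusion counts;
significance of a model is assessed through a Bayesian posterior over the
balanced accuracy: sensitivity and specificity receive independent Beta
posteriors (conjugate to the binomial confusion counts), BAC is their
average, and a model counts as better than chance when at least 95% of the
posterior mass lies above BAC = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.stats import beta as beta_dist
from sklearn.metrics import roc_auc_score

SIGNIFICANCE_MASS = 0.95


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"count {name} must be a non-negative integer, got {v!r}")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        yt = np.asarray(y_true).astype(int)
        yp = np.asarray(y_pred).astype(int)
        if yt.shape != yp.shape:
            raise ValueError("y_true and y_pred are misaligned")
        return cls(
            tp=int(np.sum((yt == 1) & (yp == 1))),
            fp=int(np.sum((yt == 0) & (yp == 1))),
            tn=int(np.sum((yt == 0) & (yp == 0))),
            fn=int(np.sum((yt == 1) & (yp == 0))),
        )


@dataclass
class PosteriorBAC:
    mean: float
    ci_low: float
    ci_high: float
    mass_above_chance: float
    method: str
    prior: tuple[float, float]

    @property
    def significant(self) -> bool:
        return self.mass_above_chance >= SIGNIFICANCE_MASS


@dataclass
class PerformanceReport:
    """Confusion counts, point metrics, AUC and the posterior-BAC summary."""

    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    bac: float
    auc: float | None = None
    posterior: PosteriorBAC | None = None
    flags: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool | None:
        return None if self.posterior is None else self.posterior.significant

    def to_dict(self) -> dict:
        d = {
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "tn": self.counts.tn,
            "fn": self.counts.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "bac": self.bac,
            "auc": self.auc,
        }
        if self.posterior is not None:
            d.update(
                posterior_mean=self.posterior.mean,
                ci_low=self.posterior.ci_low,
                ci_high=self.posterior.ci_high,
                mass_above_chance=self.posterior.mass_above_chance,
                significant=self.posterior.significant,
            )
        if self.flags:
            d["flags"] = dict(self.flags)
        return d


def point_metrics(counts: ConfusionCounts) -> PerformanceReport:
    """Sensitivity, specificity, PPV, NPV and balanced accuracy from counts.

    Requires both classes present.  PPV/NPV are ``None`` (flagged) when the
    corresponding prediction margin is empty.
    """
    if counts.positives == 0:
        raise ValueError("no positive-class subjects (TP+FN = 0)")
    if counts.negatives == 0:
        raise ValueError("no negative-class subjects (TN+FP = 0)")
    se = counts.tp / counts.positives
    sp = counts.tn / counts.negatives
    flags: dict = {}
    pred_pos = counts.tp + counts.fp
    pred_neg = counts.tn + counts.fn
    ppv = counts.tp / pred_pos if pred_pos else None
    npv = counts.tn / pred_neg if pred_neg else None
    if ppv is None:
        flags["ppv_undefined"] = "no positive predictions"
    if npv is None:
        flags["npv_undefined"] = "no negative predictions"
    return PerformanceReport(
        counts=counts, sensitivity=se, specificity=sp, ppv=ppv, npv=npv,
        bac=(se + sp) / 2.0, flags=flags,
    )


def auc(scores, y) -> float:
    """Area under the ROC curve in its rank-statistic (Mann-Whitney) form;
    tied scores contribute 1/2 per positive-negative pair."""
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def posterior_bac(
    counts: ConfusionCounts,
    prior: tuple[float, float] = (1.0, 1.0),
    method: str = "grid_convolution",
    n_draws: int = 100_000,
    seed: int = 0,
    grid_size: int = 4001,
) -> PosteriorBAC:
    """Posterior of BAC = (sensitivity + specificity)/2.

    ``sensitivity ~ Beta(TP+a, FN+b)`` and ``specificity ~ Beta(TN+a, FP+b)``
    independently, with prior (a, b).  The default evaluates the density of
    their average by numerical convolution on a uniform grid; ``monte_carlo``
    draws from both Betas instead.
    """
    a, b = prior
    if not (a > 0 and b > 0):
        raise ValueError(f"Beta prior parameters must be positive, got {prior!r}")
    a_se, b_se = counts.tp + a, counts.fn + b
    a_sp, b_sp = counts.tn + a, counts.fp + b

    if method == "grid_convolution":
        x = np.linspace(0.0, 1.0, grid_size)
        dx = x[1] - x[0]
        p_se = beta_dist.pdf(x, a_se, b_se) * dx
        p_sp = beta_dist.pdf(x, a_sp, b_sp) * dx
        p_se /= p_se.sum()
        p_sp /= p_sp.sum()
        mass = fftconvolve(p_se, p_sp)  # support 0..2, spacing dx
        mass = np.clip(mass, 0.0, None)
        mass /= mass.sum()
        bac_grid = np.arange(mass.size) * dx / 2.0  # sum/2
        mean = float(np.sum(bac_grid * mass))
        cdf = np.cumsum(mass)
        ci_low = float(np.interp(0.025, cdf, bac_grid))
        ci_high = float(np.interp(0.975, cdf, bac_grid))
        above = float(mass[bac_grid > 0.5].sum())
    elif method == "monte_carlo":
        rng = np.random.default_rng(seed)
        draws = (rng.beta(a_se, b_se, n_draws) + rng.beta(a_sp, b_sp, n_draws)) / 2.0
        mean = float(draws.mean())
        ci_low, ci_high = (float(q) for q in np.quantile(draws, [0.025, 0.975]))
        above = float(np.mean(draws > 0.5))
    else:
        raise ValueError(f"method must be 'grid_convolution' or 'monte_carlo', got {method!r}")
    return PosteriorBAC(
        mean=mean, ci_low=ci_low, ci_high=ci_high,
        mass_above_chance=above, method=method, prior=(float(a), float(b)),
    )


def evaluate_scores(
    scores: pd.DataFrame,
    y,
    prior: tuple[float, float] = (1.0, 1.0),
    method: str = "grid_convolution",
    seed: int = 0,
) -> PerformanceReport:
    """Full report (point metrics + AUC + posterior BAC) from out-of-site
    decision scores against labels aligned by position."""
    y = np.asarray(y).astype(int)
    counts = ConfusionCounts.from_predictions(y, scores["pred"].to_numpy())
    report = point_metrics(counts)
    report.auc = auc(scores["score"].to_numpy(), y)
    report.posterior = posterior_bac(counts, prior=prior, method=method, seed=seed)
    return report
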
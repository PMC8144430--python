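"""Multi-site synthetic cohorts with the statistical structure the pipeline assumes.

The real study populations (clinical high-risk, recent-onset psychosis,
recent-onset depression; seven European recruitment sites) are not publicly
deposited, so every downstream stage is exercised on generated cohorts that
reproduce the *structure* of those data: ordinal SIPS negative-symptom items
at two timepoints, 68 atlas-ROI gyrification values coupled to intracranial
volume, per-site batch offsets, Global Functioning scores, and a binary
follow-up outcome whose prevalence is calibrated to a target rate.

Generative model
----------------
A single standard-normal latent severity ``z`` per subject drives everything:

* baseline items: ``v = lam*z + sqrt(1-lam^2)*eps`` cut into 0..6 by an
  equal-width grid;
* follow-up severity ``s = (clinical_effect*z + e) / sqrt(1+clinical_effect^2)``,
  follow-up items cut by a grid whose "score >= 3" threshold is solved
  numerically so that ``P(any item >= 3)`` equals ``target_prevalence``;
* the binary outcome is *computed from the follow-up items via the labelling
  rule*, never sampled directly, so labels and items are always consistent;
* planted signal ROIs receive a mean shift of ``roi_effect`` within-class
  standard deviations between outcome classes (per-ROI sign recorded in the
  returned metadata); all ROIs receive additive per-(site, ROI) offsets with
  standard deviation ``site_sd`` and are scaled by the subject's ICV so that
  ICV normalization downstream is meaningful;
* GF Social/Role scores derive from the same follow-up severity with
  independent noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .atlas import ROI_COLUMNS
from .outcomes import MODERATE_THRESHOLD, SIPS_N_ITEMS

GROUPS = ("CHR", "ROP", "ROD")

#: Empirical moderate/severe-outcome prevalence per diagnostic group.
GROUP_PREVALENCE = {"CHR": 0.40, "ROP": 0.59, "ROD": 0.32}
#: Cohort sizes of the emulated study samples.
GROUP_TOTAL_N = {"CHR": 94, "ROP": 96, "ROD": 97}

ICV_MEAN = 1.5e6  # mm^3
ICV_CV = 0.08
ITEM_LOADING = 0.8   # latent loading shared by the ordinal items
ITEM_STEP = 0.6      # equal-width cut spacing on the continuous item score
BASELINE_ANCHOR = 0.5  # "score >= 3" cut for baseline items
ROI_NOISE_SD = 0.1   # within-class subject-level ROI standard deviation
GF_SLOPE = 1.2
GF_NOISE = 0.8
GF_ANCHOR = 8.0


def _split_total(total: int, n_sites: int) -> tuple[int, ...]:
    base, extra = divmod(total, n_sites)
    return tuple(base + (1 if i < extra else 0) for i in range(n_sites))


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic multi-site cohort.

    ``clinical_effect`` is the (unstandardized) regression weight of baseline
    latent severity on follow-up severity; ``roi_effect`` the standardized
    between-class mean shift planted in each signal ROI (magnitude; per-ROI
    signs are drawn and reported in the generator metadata); ``site_sd`` the
    standard deviation of additive per-(site, ROI) offsets in ROI units.
    """

    n_sites: int = 7
    n_per_site: int | Sequence[int] = dataclasses.field(default=None)  # type: ignore[assignment]
    group: str = "CHR"
    target_prevalence: float = 0.40
    clinical_effect: float = 0.6
    n_signal_rois: int = 8
    roi_effect: float = 0.8
    site_sd: float = 0.02
    seed: int = 0
    #: optionally pin the planted ROI names/signs (e.g. to share the signal
    #: structure with another cohort); drawn at random when None
    signal_rois: tuple[str, ...] | None = None
    signal_signs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not (isinstance(self.n_sites, (int, np.integer)) and self.n_sites >= 1):
            raise ValueError(f"n_sites must be a positive integer, got {self.n_sites!r}")
        if self.n_per_site is None:
            object.__setattr__(
                self, "n_per_site", _split_total(GROUP_TOTAL_N.get(self.group, 94), self.n_sites)
            )
        counts = self.site_sizes()
        if any(c < 1 for c in counts):
            raise ValueError(f"n_per_site entries must be >= 1, got {counts!r}")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError(
                f"target_prevalence must lie strictly in (0, 1), got {self.target_prevalence!r}"
            )
        if not 0 <= self.n_signal_rois <= len(ROI_COLUMNS):
            raise ValueError(
                f"n_signal_rois must be in 0..{len(ROI_COLUMNS)}, got {self.n_signal_rois!r}"
            )
        if self.site_sd < 0:
            raise ValueError(f"site_sd must be >= 0, got {self.site_sd!r}")
        if not np.isfinite(self.clinical_effect) or not np.isfinite(self.roi_effect):
            raise ValueError("clinical_effect and roi_effect must be finite")
        if self.signal_rois is not None:
            unknown = set(self.signal_rois) - set(ROI_COLUMNS)
            if unknown:
                raise ValueError(f"signal_rois not in the atlas: {sorted(unknown)}")
            if len(self.signal_rois) != self.n_signal_rois:
                raise ValueError("signal_rois length must equal n_signal_rois")
        if self.signal_signs is not None:
            if self.signal_rois is None or len(self.signal_signs) != len(self.signal_rois):
                raise ValueError("signal_signs requires signal_rois of equal length")
            if not set(self.signal_signs) <= {-1.0, 1.0}:
                raise ValueError("signal_signs entries must be -1.0 or 1.0")

    def site_sizes(self) -> tuple[int, ...]:
        if isinstance(self.n_per_site, (int, np.integer)):
            return (int(self.n_per_site),) * self.n_sites
        counts = tuple(int(c) for c in self.n_per_site)
        if len(counts) != self.n_sites:
            raise ValueError(
                f"n_per_site has {len(counts)} entries for n_sites={self.n_sites}"
            )
        return counts

    @classmethod
    def for_group(cls, group: str, **overrides) -> "CohortConfig":
        """Preset matching the emulated study sample of a diagnostic group."""
        if group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
        kwargs = dict(group=group, target_prevalence=GROUP_PREVALENCE[group])
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class SyntheticCohort:
    """A generated cohort table plus the generator's ground-truth metadata."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _solve_outcome_threshold(prevalence: float, n_items: int = len(SIPS_N_ITEMS)) -> float:
    """Cut location t such that P(max_j v_j >= t) = prevalence.

    Items ``v_j = lam*s + sqrt(1-lam^2)*eps_j`` share the standardized severity
    ``s ~ N(0,1)``; the marginal exceedance probability is computed by
    Gauss-Hermite quadrature and inverted with Brent's method.
    """
    lam = ITEM_LOADING
    sig = np.sqrt(1.0 - lam**2)
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    w = weights / np.sqrt(2.0 * np.pi)

    def exceed(t: float) -> float:
        return 1.0 - float(np.sum(w * norm.cdf((t - lam * nodes) / sig) ** n_items))

    return float(brentq(lambda t: exceed(t) - prevalence, -8.0, 10.0, xtol=1e-10))


def _ordinal_items(latent: np.ndarray, anchor: float, rng: np.random.Generator,
                   n_items: int = len(SIPS_N_ITEMS)) -> np.ndarray:
    """Cut correlated continuous item scores into 0..6 on an equal-width grid.

    The grid is anchored so that the cut between scores 2 and 3 sits at
    ``anchor``: a continuous score of at least ``anchor`` maps to >= 3.
    """
    lam = ITEM_LOADING
    sig = np.sqrt(1.0 - lam**2)
    v = lam * latent[:, None] + sig * rng.standard_normal((latent.size, n_items))
    # 6 cuts -> 7 ordinal levels; cuts[2] is the 2->3 boundary = anchor
    cuts = anchor + ITEM_STEP * np.arange(-2, 4)
    return np.digitize(v, cuts)


def _roi_baselines(rng: np.random.Generator) -> np.ndarray:
    # Plausible per-ROI gyrification levels; the absolute scale is immaterial
    # to the pipeline (features are z-scored within training folds).
    return rng.uniform(2.0, 3.5, size=len(ROI_COLUMNS))


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a multi-site cohort table under ``config``.

    Returns the table together with metadata naming the planted signal ROIs
    and their signed standardized effects, so recovery tests need no
    re-inference.
    """
    rng = np.random.default_rng(config.seed)
    counts = config.site_sizes()
    n = int(sum(counts))
    sites = np.repeat([f"site{i + 1:02d}" for i in range(config.n_sites)], counts)

    z = rng.standard_normal(n)  # baseline latent severity
    ce = config.clinical_effect
    s = (ce * z + rng.standard_normal(n)) / np.sqrt(1.0 + ce**2)

    items_t0 = _ordinal_items(z, BASELINE_ANCHOR, rng)
    n5_t0 = _ordinal_items(z, BASELINE_ANCHOR, rng, n_items=1)[:, 0]
    t1_anchor = _solve_outcome_threshold(config.target_prevalence)
    items_t1 = _ordinal_items(s, t1_anchor, rng)
    outcome = (items_t1.max(axis=1) >= MODERATE_THRESHOLD).astype(int)

    # ROI block: baseline + site offsets + subject noise + planted class shifts
    baselines = _roi_baselines(rng)
    site_offsets = rng.normal(0.0, config.site_sd, size=(config.n_sites, len(ROI_COLUMNS)))
    site_index = np.repeat(np.arange(config.n_sites), counts)
    roi = (
        baselines[None, :]
        + site_offsets[site_index]
        + ROI_NOISE_SD * rng.standard_normal((n, len(ROI_COLUMNS)))
    )
    # draw the planted structure even when pinned, to keep the rng stream
    # (hence all other columns) comparable across configurations
    signal_idx = np.sort(rng.choice(len(ROI_COLUMNS), size=config.n_signal_rois, replace=False))
    signs = rng.choice([-1.0, 1.0], size=config.n_signal_rois)
    if config.signal_rois is not None:
        signal_idx = np.array([ROI_COLUMNS.index(r) for r in config.signal_rois], dtype=int)
        if config.signal_signs is not None:
            signs = np.asarray(config.signal_signs, dtype=float)
    for j, sign in zip(signal_idx, signs):
        roi[:, j] += sign * config.roi_effect * ROI_NOISE_SD * outcome

    icv = ICV_MEAN * rng.lognormal(
        mean=-0.5 * np.log(1 + ICV_CV**2), sigma=np.sqrt(np.log(1 + ICV_CV**2)), size=n
    )
    roi_observed = roi * (icv / ICV_MEAN)[:, None]

    gf_latent = GF_ANCHOR - GF_SLOPE * s[:, None] + GF_NOISE * rng.standard_normal((n, 2))
    gf = np.clip(np.rint(gf_latent), 1, 10).astype(int)

    data: dict[str, np.ndarray] = {
        "subject_id": np.array([f"{config.group}-{i + 1:04d}" for i in range(n)]),
        "site_id": sites,
        "group": np.repeat(config.group, n),
    }
    for k, item in enumerate(SIPS_N_ITEMS):
        data[f"sips_{item.lower()}_t0"] = items_t0[:, k]
    data["sips_n5_t0"] = n5_t0
    for k, item in enumerate(SIPS_N_ITEMS):
        data[f"sips_{item.lower()}_t1"] = items_t1[:, k]
    for j, col in enumerate(ROI_COLUMNS):
        data[col] = roi_observed[:, j]
    data["icv"] = icv
    data["gf_social_t1"] = gf[:, 0]
    data["gf_role_t1"] = gf[:, 1]

    table = pd.DataFrame(data)
    metadata = {
        "group": config.group,
        "seed": config.seed,
        "target_prevalence": config.target_prevalence,
        "realized_prevalence": float(outcome.mean()),
        "signal_rois": [ROI_COLUMNS[j] for j in signal_idx],
        "signal_signs": {ROI_COLUMNS[j]: float(sg) for j, sg in zip(signal_idx, signs)},
        "signal_effects": {
            ROI_COLUMNS[j]: float(sg * config.roi_effect) for j, sg in zip(signal_idx, signs)
        },
        "outcome_threshold": t1_anchor,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
    }
    return SyntheticCohort(table=table, metadata=metadata)


def generate_null_cohort(config: CohortConfig) -> SyntheticCohort:
    """Same marginals as :func:`generate_cohort` but all feature-outcome
    effects forced to zero; site effects retained."""
    null_config = dataclasses.replace(config, clinical_effect=0.0, roi_effect=0.0)
    cohort = generate_cohort(null_config)
    cohort.metadata["null"] = True
    return cohort
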
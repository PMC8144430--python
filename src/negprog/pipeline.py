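"""End-to-end orchestration: simulate/load -> label -> train -> evaluate ->
importance -> stratify -> generalize, with all artifacts written to disk.

A run is fully determined by its :class:`RunConfig` (including the global
seed); every numeric in the emitted reports is recomputable from the emitted
intermediate artifacts (out-of-site scores and labels).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cohort_io
from .features import GYRIFICATION_VIEW, SIPS_N_VIEW
from .importance import CVRProfile, cvr_profile
from .metrics import PerformanceReport, evaluate_scores
from .nested_cv import (
    DEFAULT_GRID,
    TrainedModel,
    apply_external,
    apply_stacker_external,
    fit_view,
    make_lso_scheme,
    train_stacker,
)
from .outcomes import GF_ROLE_LABEL, GF_SOCIAL_LABEL, NEGSYM_LABEL, add_outcome_labels
from .stratification import DiagnosticTest, StratificationTree, build_tree, empirical_branch_rates
from .synthetic import CohortConfig, generate_cohort

logger = logging.getLogger("negprog")

MODEL_NAMES = ("sips_n", "gyrification", "combined")


@dataclass
class RunConfig:
    """Everything a reproducible run needs."""

    output_dir: str = "negprog_run"
    cohort_path: str | None = None            # read this table ...
    synthetic: dict = field(default_factory=dict)  # ... or generate one
    external_paths: dict = field(default_factory=dict)  # name -> path
    loss: str = "logistic"
    grid: tuple[float, ...] = DEFAULT_GRID
    inner_k: int = 5
    inner_r: int = 10
    prior: tuple[float, float] = (1.0, 1.0)
    posterior_method: str = "grid_convolution"
    rr: float | None = None                   # intervention risk ratio for NNT
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = (
            yaml.safe_load(path.read_text())
            if path.suffix.lower() in (".yml", ".yaml")
            else json.loads(path.read_text())
        )
        cfg = cls(**raw)
        cfg.grid = tuple(float(c) for c in cfg.grid)
        cfg.prior = tuple(float(p) for p in cfg.prior)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = list(self.grid)
        d["prior"] = list(self.prior)
        return d


@dataclass
class ReportBundle:
    cohort: pd.DataFrame
    models: dict[str, TrainedModel]
    reports: dict[str, PerformanceReport]
    cvr: dict[str, CVRProfile]
    tree: StratificationTree | None
    empirical_rates: pd.DataFrame | None
    generalization: dict[str, PerformanceReport]
    output_dir: Path


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def run_full_analysis(config: RunConfig) -> ReportBundle:
    """Execute the full analysis described by ``config``.

    Trains the SIPS-N, gyrification and stacked (combined) models under
    leave-site-out nested CV, evaluates all three against the
    negative-symptom outcome, computes CVR profiles for the base models,
    builds the sequential risk-stratification tree from the base models'
    realized sensitivity/specificity, and evaluates generalization to the
    functional (GF) outcomes and to any configured external cohorts.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_times: dict[str, float] = {}

    def stage(name: str):
        logger.info("stage %s", name)
        stage_times[name] = time.perf_counter()

    def stage_done(name: str):
        stage_times[name] = time.perf_counter() - stage_times[name]
        logger.info("stage %s done in %.2fs", name, stage_times[name])

    try:
        stage("cohort")
        if config.cohort_path is not None:
            cohort = cohort_io.read_cohort(config.cohort_path)
        else:
            syn = dict(config.synthetic)
            syn.setdefault("seed", config.seed)
            generated = generate_cohort(CohortConfig(**syn))
            cohort = generated.table
            cohort_io.write_cohort(cohort, out / "cohort.csv", metadata=generated.metadata)
        cohort = add_outcome_labels(cohort)
        y = cohort[NEGSYM_LABEL].to_numpy()
        stage_done("cohort")

        stage("train")
        scheme = make_lso_scheme(
            cohort, y, inner_k=config.inner_k, inner_r=config.inner_r, seed=config.seed
        )
        sips = fit_view(cohort, y, scheme, SIPS_N_VIEW, grid=config.grid, loss=config.loss)
        gyri = fit_view(cohort, y, scheme, GYRIFICATION_VIEW, grid=config.grid, loss=config.loss)
        stack = train_stacker([sips, gyri], y, scheme, grid=config.grid, loss=config.loss)
        models = {"sips_n": sips, "gyrification": gyri, "combined": stack}
        for name, model in models.items():
            model.scores.to_csv(out / f"scores_{name}.csv", index=False)
        stage_done("train")

        stage("evaluate")
        reports = {
            name: evaluate_scores(
                model.scores, y, prior=config.prior,
                method=config.posterior_method, seed=config.seed,
            )
            for name, model in models.items()
        }
        _dump_json({k: r.to_dict() for k, r in reports.items()}, out / "reports.json")
        stage_done("evaluate")

        stage("importance")
        cvr = {
            name: cvr_profile(models[name].weight_matrix(),
                              models[name].fold_ensembles[0].feature_names)
            for name in ("sips_n", "gyrification")
        }
        for name, profile in cvr.items():
            profile.table.to_csv(out / f"cvr_{name}.tsv", sep="\t", index=False)
        stage_done("importance")

        stage("stratify")
        pretest = float(y.mean())
        tests = [
            DiagnosticTest("SIPS-N", reports["sips_n"].sensitivity,
                           reports["sips_n"].specificity),
            DiagnosticTest("gyrification", reports["gyrification"].sensitivity,
                           reports["gyrification"].specificity),
        ]
        tree = build_tree(pretest, tests, rr=config.rr)
        _dump_json(tree.to_dict(), out / "stratification_tree.json")
        scored = cohort.copy()
        scored["test_sips_n"] = models["sips_n"].scores["pred"].to_numpy()
        scored["test_gyrification"] = models["gyrification"].scores["pred"].to_numpy()
        empirical = empirical_branch_rates(
            scored, ["test_sips_n", "test_gyrification"], NEGSYM_LABEL
        )
        empirical.to_csv(out / "empirical_branch_rates.tsv", sep="\t", index=False)
        stage_done("stratify")

        stage("generalize")
        generalization: dict[str, PerformanceReport] = {}
        for gf_name, gf_col in (("gf_social", GF_SOCIAL_LABEL), ("gf_role", GF_ROLE_LABEL)):
            y_gf = cohort[gf_col].to_numpy()
            if len(np.unique(y_gf)) == 2:
                for name, model in models.items():
                    generalization[f"{gf_name}/{name}"] = evaluate_scores(
                        model.scores, y_gf, prior=config.prior,
                        method=config.posterior_method, seed=config.seed,
                    )
        for ext_name, ext_path in config.external_paths.items():
            ext = add_outcome_labels(cohort_io.read_cohort(ext_path))
            y_ext = ext[NEGSYM_LABEL].to_numpy()
            ext_scores = {
                "sips_n": apply_external(sips, ext),
                "gyrification": apply_external(gyri, ext),
                "combined": apply_stacker_external(stack, [sips, gyri], ext),
            }
            for name, sc in ext_scores.items():
                generalization[f"{ext_name}/{name}"] = evaluate_scores(
                    sc, y_ext, prior=config.prior,
                    method=config.posterior_method, seed=config.seed,
                )
        if generalization:
            _dump_json(
                {k: r.to_dict() for k, r in generalization.items()},
                out / "generalization.json",
            )
        stage_done("generalize")

        _dump_json(config.to_dict(), out / "config_snapshot.json")
        _dump_json({"stage_seconds": stage_times}, out / "run_log.json")
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise RuntimeError(f"pipeline failed in stage {list(stage_times)[-1]!r}: {exc}") from exc

    return ReportBundle(
        cohort=cohort,
        models=models,
        reports=reports,
        cvr=cvr,
        tree=tree,
        empirical_rates=empirical,
        generalization=generalization,
        output_dir=out,
    )


def table2_style(reports: dict[str, PerformanceReport]) -> pd.DataFrame:
    """Render reports in the classical column order (BAC, AUC, SE, SP, PPV,
    NPV), proportions at 3 decimals with integer-percent renderings."""
    rows = []
    for name, r in reports.items():
        row = {"model": name}
        for col, v in (
            ("BAC", r.bac), ("AUC", r.auc), ("SE", r.sensitivity),
            ("SP", r.specificity), ("PPV", r.ppv), ("NPV", r.npv),
        ):
            row[col] = None if v is None else round(float(v), 3)
            row[f"{col}_pct"] = None if v is None else int(round(100 * float(v)))
        if r.posterior is not None:
            row["CI_low_pct"] = int(round(100 * r.posterior.ci_low))
            row["CI_high_pct"] = int(round(100 * r.posterior.ci_high))
            row["significant"] = r.posterior.significant
        rows.append(row)
    return pd.DataFrame(rows)
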
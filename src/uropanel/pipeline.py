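"""End-to-end orchestration: exclusions -> screening -> single-marker ranking
-> LASSO ranking -> nested CV panel selection -> final evaluation.

The pipeline writes a report bundle (JSON + TSV) into an output directory,
together with a manifest recording the seed, package version, configuration
hash and per-stage wall time — enough to re-run the analysis bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import (
    CohortTable,
    DEFAULT_EXCLUSIONS,
    apply_exclusions,
    read_cohort,
    summarize_cohort,
    write_cohort,
)
from .lasso import rank_by_lasso
from .panel import NestedCvConfig, evaluate_panel, fit_panel, nested_cv_select
from .roc import roc_curve
from .screen import rank_single_markers, screen_markers, screen_table
from .simulate import generate_cohort, paperlike_scenario

log = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (YAML-serializable)."""

    seed: int
    out_dir: str
    input_path: str | None = None
    scenario: str | None = None  # "paperlike" or "paperlike-correlated"
    exclusions: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_EXCLUSIONS.items()})
    screening_correction: str = "bonferroni"
    rank_n_iter: int = 2000
    rank_frac: float = 0.8
    rank_with_replacement: bool = False
    lasso_n_iter: int = 2000
    lasso_n_folds: int = 10
    nested: dict = field(default_factory=dict)  # NestedCvConfig overrides
    evaluate_menopause: bool = True

    def validate(self) -> None:
        if self.seed is None:
            raise PipelineConfigError("seed is mandatory")
        if (self.input_path is None) == (self.scenario is None):
            raise PipelineConfigError("give exactly one of input_path or scenario")
        if self.input_path is not None and not Path(self.input_path).exists():
            raise PipelineConfigError(f"input file not found: {self.input_path}")
        if self.scenario is not None and self.scenario not in (
            "paperlike", "paperlike-correlated"
        ):
            raise PipelineConfigError(f"unknown scenario {self.scenario!r}")
        try:
            self.nested_config()
        except (TypeError, ValueError) as exc:
            raise PipelineConfigError(f"invalid nested CV settings: {exc}") from exc

    def nested_config(self) -> NestedCvConfig:
        kw = dict(self.nested)
        kw.setdefault("seed", self.seed)
        if "sizes" in kw:
            kw["sizes"] = tuple(kw["sizes"])
        if kw.get("pool") is not None:
            kw["pool"] = tuple(kw["pool"])
        return NestedCvConfig(**kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise PipelineConfigError(str(exc)) from exc
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _load_cohort(config: PipelineConfig) -> CohortTable:
    if config.input_path is not None:
        return read_cohort(config.input_path)
    scen = paperlike_scenario(
        seed=config.seed, correlated=config.scenario == "paperlike-correlated"
    )
    cohort, _truth = generate_cohort(scen)
    return cohort


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle; returns the manifest.

    Stage errors abort the run with the stage name in the raised exception;
    outputs of completed stages are left in place.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "uropanel_version": __version__,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stages": {},
        "outputs": [],
    }

    def _stage(name):
        log.info("stage: %s", name)
        return time.perf_counter()

    def _done(name, t0, *files):
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        manifest["outputs"] += [str(f) for f in files]

    try:
        t0 = _stage("load")
        cohort = _load_cohort(config)
        if config.scenario is not None:
            write_cohort(cohort, out / "cohort.tsv")
        (out / "cohort_summary.json").write_text(summarize_cohort(cohort).to_json())
        _done("load", t0, out / "cohort_summary.json")

        t0 = _stage("exclusions")
        rules = {k: tuple(v) for k, v in config.exclusions.items()}
        analyzed = apply_exclusions(cohort, rules)
        (out / "analyzed_summary.json").write_text(summarize_cohort(analyzed).to_json())
        _done("exclusions", t0, out / "analyzed_summary.json")

        t0 = _stage("screening")
        screening = screen_markers(analyzed, correction=config.screening_correction)
        screen_table(screening).to_csv(out / "screening.tsv", sep="\t", index=False)
        _done("screening", t0, out / "screening.tsv")

        t0 = _stage("single_marker_ranking")
        single = rank_single_markers(
            analyzed,
            n_iter=config.rank_n_iter,
            frac=config.rank_frac,
            seed=config.seed,
            with_replacement=config.rank_with_replacement,
        )
        single.round(3).to_csv(out / "single_marker_auc.tsv", sep="\t", index=False)
        _done("single_marker_ranking", t0, out / "single_marker_auc.tsv")

        t0 = _stage("lasso_ranking")
        importance = rank_by_lasso(
            analyzed,
            n_iter=config.lasso_n_iter,
            n_folds=config.lasso_n_folds,
            seed=config.seed,
        )
        importance.table.round(4).to_csv(out / "lasso_rank.tsv", sep="\t", index=False)
        importance.draws_long().round(4).to_csv(
            out / "lasso_coefficients.tsv", sep="\t", index=False
        )
        _done("lasso_ranking", t0, out / "lasso_rank.tsv", out / "lasso_coefficients.tsv")

        t0 = _stage("panel_selection")
        ncfg = config.nested_config()
        if ncfg.pool is None:
            ncfg.pool = tuple(importance.top(min(ncfg.pool_size, len(analyzed.markers))))
        result = nested_cv_select(analyzed, ncfg)
        result.selection.round(4).to_csv(out / "panel_selection.tsv", sep="\t", index=False)
        _done("panel_selection", t0, out / "panel_selection.tsv")

        t0 = _stage("evaluation")
        evaluations = {}
        files = []
        for size, model in result.best_models.items():
            ev = evaluate_panel(model, analyzed)
            key = f"size{size}"
            evaluations[key] = ev.to_dict()
            evaluations[key]["heldout_mean_auc"] = round(result.heldout_mean_auc[size], 3)
            prob, keep = model.predict_proba(analyzed)
            curve = roc_curve(prob, analyzed.labels()[keep])
            f = out / f"roc_panel_{size}.tsv"
            curve.to_tsv(f)
            files.append(f)
        if config.evaluate_menopause:
            largest = max(result.best_models)
            cov_model = fit_panel(
                analyzed, result.best_models[largest].markers, include_menopause=True
            )
            evaluations["with_menopause"] = evaluate_panel(cov_model, analyzed).to_dict()
        (out / "panel_evaluation.json").write_text(json.dumps(evaluations, indent=2))
        _done("evaluation", t0, out / "panel_evaluation.json", *files)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {_current_stage(manifest)}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _current_stage(manifest: dict) -> str:
    order = ("load", "exclusions", "screening", "single_marker_ranking",
             "lasso_ranking", "panel_selection", "evaluation")
    done = set(manifest["stages"])
    for name in order:
        if name not in done:
            return name
    return "finalize"
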
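"""Single-config orchestration of the full analysis.

``run_all`` executes generate/load -> model-suite evaluation -> domain
importance -> SHAP summaries from one :class:`RunConfig`, writing every
result family plus a reproducibility manifest (config echo, seeds, library
versions, wall clock). The same splits and seeds flow through every stage,
so coalition marginals and metric rows are computed on identical test rows.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import __version__
from .data_model import (
    CohortTable,
    DomainMap,
    SplitSpec,
    load_cohort,
    split_cohort,
    write_cohort,
    write_domain_map,
)
from .domain_importance import run_domain_analysis
from .model_zoo import ModelSpec, evaluate_suite, fit_model
from .shap_summary import (
    age_stratified_shap,
    compute_shap,
    mean_abs_shap,
)
from .synthetic_cohort import CohortSpec, generate_cohort, write_ground_truth

logger = logging.getLogger("riskdomains")

__all__ = ["RunConfig", "run_all", "load_run_config"]


class StageError(RuntimeError):
    """A pipeline stage failed; earlier outputs are preserved on disk."""


@dataclass
class RunConfig:
    """Everything one analysis run needs, loadable from YAML.

    Exactly one of ``cohort_csv`` (+ ``domain_map``) or ``synthesis`` must
    be provided.
    """

    output_dir: str
    cohort_csv: str | None = None
    domain_map: str | None = None
    synthesis: Mapping[str, Any] | None = None
    split: Mapping[str, Any] = field(default_factory=dict)
    models: Sequence[Any] = field(default_factory=lambda: ["lightgbm", "benchmark"])
    seeds: Sequence[int] = field(default_factory=lambda: [0])
    domain_metric: str = "pr_auc"
    domain_model: str = "lightgbm"
    weighting: str = "unweighted_mean"
    shap: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        has_csv = self.cohort_csv is not None
        has_syn = self.synthesis is not None
        if has_csv == has_syn:
            raise ValueError("config must set exactly one of cohort_csv / synthesis")
        if has_csv and self.domain_map is None:
            raise ValueError("cohort_csv requires a domain_map path")
        if not list(self.seeds):
            raise ValueError("seeds must be non-empty")

    def model_specs(self) -> list[ModelSpec]:
        specs = []
        for entry in self.models:
            if isinstance(entry, str):
                specs.append(ModelSpec(name=entry))
            else:
                specs.append(
                    ModelSpec(name=entry["name"], hyperparams=entry.get("hyperparams", {}))
                )
        return specs

    def split_spec(self) -> SplitSpec:
        return SplitSpec(
            train_fraction=float(self.split.get("train_fraction", 0.7)),
            stratified=bool(self.split.get("stratified", True)),
            seed=int(self.split.get("seed", list(self.seeds)[0])),
        )


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return RunConfig(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.1f s", name, time.time() - t0)
            return out

        return wrapped

    return deco


@_stage("input")
def _resolve_input(config: RunConfig, outdir: Path) -> tuple[CohortTable, DomainMap]:
    if config.cohort_csv is not None:
        return load_cohort(config.cohort_csv, config.domain_map)
    spec = CohortSpec(**dict(config.synthesis))
    table, dm = generate_cohort(spec)
    write_cohort(table, outdir / "cohort.csv")
    write_domain_map(
        dm, outdir / "domain_map.yaml", age_col=table.age_col, gender_col=table.gender_col
    )
    write_ground_truth(spec, outdir / "ground_truth.json")
    return table, dm


@_stage("evaluate")
def _evaluate(config: RunConfig, table: CohortTable, outdir: Path):
    report = evaluate_suite(
        config.model_specs(), table, config.split_spec(), seeds=list(config.seeds)
    )
    report.to_csv(outdir / "metrics.csv")
    report.to_json(outdir / "metrics.json")
    return report

@_stage("domains")
def _domains(config: RunConfig, table: CohortTable, dm: DomainMap, outdir: Path):
    importance, ledgers = run_domain_analysis(
        table,
        dm,
        model_spec=ModelSpec(name=config.domain_model),
        split_spec=config.split_spec(),
        seeds=list(config.seeds),
        metric_name=config.domain_metric,
        weighting=config.weighting,
    )
    importance.to_csv(outdir / "domain_importance.csv")
    for seed, ledger in zip(config.seeds, ledgers):
        ledger.to_json(outdir / f"coalition_ledger_seed{seed}.json")
    return importance


@_stage("shap")
def _shap(config: RunConfig, table: CohortTable, outdir: Path):
    opts = dict(config.shap)
    model_name = opts.get("model", "lightgbm")
    threshold = float(opts.get("threshold", 0.1))
    scale = opts.get("scale", "log_odds")
    seed = int(list(config.seeds)[0])
    train, _ = split_cohort(table, replace(config.split_spec(), seed=seed))
    fitted = fit_model(ModelSpec(name=model_name, seed=seed), train)
    # attributions over the full cohort (train + test)
    mat = compute_shap(fitted, table, scale=scale, seed=seed)
    summary = mean_abs_shap(mat, threshold=threshold)
    summary.to_csv(outdir / "shap_summary.csv")
    bins = opts.get("bins")
    strat = age_stratified_shap(
        mat, table, bins=[tuple(b) for b in bins] if bins else None
    )
    strat.table.to_csv(outdir / "shap_age_stratified.csv")
    # individual-level attributions are intentionally not written out
    return summary, strat


def run_all(config: RunConfig) -> dict[str, Any]:
    """Run every stage and write the output bundle; returns the in-memory
    results keyed by stage."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    table, dm = _resolve_input(config, outdir)
    dm.check_against(table)
    results: dict[str, Any] = {"cohort": table, "domain_map": dm}
    results["metrics"] = _evaluate(config, table, outdir)
    results["domain_importance"] = _domains(config, table, dm, outdir)
    results["shap"] = _shap(config, table, outdir)
    manifest = {
        "config": _config_echo(config),
        "seeds": list(config.seeds),
        "versions": _versions(),
        "wall_clock_s": round(time.time() - t0, 2),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results


def _config_echo(config: RunConfig) -> dict:
    return {
        "output_dir": config.output_dir,
        "cohort_csv": config.cohort_csv,
        "domain_map": config.domain_map,
        "synthesis": dict(config.synthesis) if config.synthesis else None,
        "split": dict(config.split),
        "models": list(config.models),
        "seeds": list(config.seeds),
        "domain_metric": config.domain_metric,
        "domain_model": config.domain_model,
        "weighting": config.weighting,
        "shap": dict(config.shap),
    }


def _versions() -> dict[str, str]:
    import lightgbm
    import numpy
    import pandas
    import sklearn
    import xgboost

    return {
        "riskdomains": __version__,
        "python": platform.python_version(),
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
        "lightgbm": lightgbm.__version__,
        "xgboost": xgboost.__version__,
    }
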
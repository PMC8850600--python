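"""End-to-end orchestration: simulate → featurize → train → evaluate →
ethogram → forecast → PCA, with a JSON run manifest for provenance.

Every stage writes flat CSV/JSON artifacts into a numbered subfolder of the
run directory, so any stage can be re-run or inspected independently.  All
randomness traces to the named seeds in the manifest; re-running with an
identical config reproduces identical metric reports.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behaviors import BEHAVIORS
from .classify import (
    ClassifierConfig,
    SplitSpec,
    evaluate_classifier,
    predict,
    split_dataset,
    train_classifier,
)
from .ethogram import min_per_hour_to_h_per_day, time_budget
from .features import build_feature_table
from .forecast import (
    evaluate_forecast_by_group,
    fit_mlr,
    predict_iadg,
    summarize_iadg,
)
from .metrics import EvalSummary, confusion_matrix, overall_metrics
from .multivariate import group_separation, run_pca, two_component_variability
from .sensor_io import (
    align_labels,
    segment_all,
    write_observations_csv,
    write_records_csv,
)
from .synthetic_herd import StudyBundle, StudyScenario, generate_study

log = logging.getLogger("grazemetrics")

STAGES = ("simulate", "featurize", "train", "evaluate", "ethogram", "forecast", "pca")
STAGE_DEPENDENCIES = {
    "featurize": ("simulate",),
    "train": ("featurize",),
    "evaluate": ("train",),
    "ethogram": ("train",),
    "forecast": ("train",),
    "pca": ("forecast",),
}


@dataclass
class RunConfig:
    """One reproducible pipeline run."""

    scenario: StudyScenario = field(default_factory=StudyScenario)
    out_dir: str | Path = "runs/default"
    seed_simulation: int = 1
    seed_split: int = 2
    seed_training: int = 3
    stages: tuple[str, ...] = STAGES
    models: tuple[str, ...] = ("forest", "convnet", "lda")
    n_trees: int = 500
    max_gap_s: float = 60.0
    alignment_policy: str = "forward_fill"
    label_source: str = "scans"  # "scans" (realistic) or "timeline" (oracle)
    max_training_rows: int | None = 60_000
    best_model: str = "forest"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {', '.join(sorted(unknown))}")
        for stage in self.stages:
            for dep in STAGE_DEPENDENCIES.get(stage, ()):
                if dep not in self.stages:
                    raise ValueError(
                        f"stage {stage!r} requires {dep!r} to be enabled"
                    )


def modeling_table(
    bundle: StudyBundle,
    label_source: str = "scans",
    max_gap_s: float = 60.0,
    alignment_policy: str = "forward_fill",
) -> pd.DataFrame:
    """Labeled feature table from a study bundle.

    ``label_source="scans"`` aligns the 10-min scan observations onto the
    records (the realistic path); ``"timeline"`` labels every record from
    the generator's ground-truth timeline.
    """
    records = bundle.records.copy()
    if label_source == "timeline":
        records["behavior"] = bundle.true_record_labels().to_numpy()
    elif label_source == "scans":
        records = align_labels(records, bundle.observations, policy=alignment_policy)
    else:
        raise ValueError(f"unknown label_source {label_source!r}")
    segments = segment_all(records, max_gap_s=max_gap_s)
    groups = {a.animal_id: a.genetic_group for a in bundle.animals}
    return build_feature_table(segments, genetic_group_of=groups, modeling=True)


def run_behavior_experiment(
    bundle: StudyBundle,
    configs: dict[str, ClassifierConfig],
    split_seed: int = 0,
    label_source: str = "timeline",
    max_rows: int | None = 60_000,
) -> dict[str, EvalSummary]:
    """Split once, then train and score every classifier configuration."""
    table = modeling_table(bundle, label_source=label_source)
    if max_rows is not None and len(table) > max_rows:
        table = table.sample(n=max_rows, random_state=split_seed).reset_index(drop=True)
    train, validation = split_dataset(table, SplitSpec(seed=split_seed))
    out = {}
    for name, config in configs.items():
        summary, _ = evaluate_classifier(train, validation, config)
        out[name] = summary
    return out


def _stage_dir(root: Path, index: int, name: str) -> Path:
    d = root / f"{index:02d}_{name}"
    d.mkdir(parents=True, exist_ok=True)
    return d


def run_pipeline(config: RunConfig) -> dict:
    """Execute every enabled stage in order and return the run manifest."""
    root = Path(config.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "versions": _library_versions(),
        "seeds": {
            "simulation": config.seed_simulation,
            "split": config.seed_split,
            "training": config.seed_training,
        },
        "config": _config_echo(config),
        "stages": {},
    }
    state: dict = {}
    for i, stage in enumerate(STAGES, start=1):
        if stage not in config.stages:
            continue
        log.info("[%s] starting", stage)
        try:
            report = _STAGE_FUNCS[stage](config, state, _stage_dir(root, i, stage))
        except Exception:
            (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
            log.error("[%s] failed; partial outputs retained", stage)
            raise
        manifest["stages"][stage] = report
        log.info("[%s] done", stage)
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _library_versions() -> dict[str, str]:
    import sklearn
    import statsmodels

    return {
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _config_echo(config: RunConfig) -> dict:
    return {
        "stages": list(config.stages),
        "models": list(config.models),
        "n_trees": config.n_trees,
        "max_gap_s": config.max_gap_s,
        "alignment_policy": config.alignment_policy,
        "label_source": config.label_source,
        "max_training_rows": config.max_training_rows,
        "best_model": config.best_model,
        "n_animals": len(config.scenario.schedule.animals),
        "day_span": config.scenario.schedule.day_span,
        "n_periods": config.scenario.n_periods,
        "dropout_rate": config.scenario.dropout_rate,
    }


def _stage_simulate(config: RunConfig, state: dict, out: Path) -> dict:
    bundle = generate_study(config.scenario, config.seed_simulation)
    state["bundle"] = bundle
    write_records_csv(bundle.records, out / "records.csv")
    write_observations_csv(bundle.observations, out / "observations.csv")
    bundle.covariates.to_csv(out / "covariates.csv", index=False)
    bundle.performance.to_csv(out / "weights.csv", index=False)
    return {
        "n_animals": len(bundle.animals),
        "n_records": len(bundle.records),
        "n_observations": len(bundle.observations),
        "n_animal_periods": len(bundle.performance),
    }


def _stage_featurize(config: RunConfig, state: dict, out: Path) -> dict:
    bundle: StudyBundle = state["bundle"]
    table = modeling_table(
        bundle,
        label_source=config.label_source,
        max_gap_s=config.max_gap_s,
        alignment_policy=config.alignment_policy,
    )
    n_total = len(bundle.records)
    if config.max_training_rows is not None and len(table) > config.max_training_rows:
        table = table.sample(
            n=config.max_training_rows, random_state=config.seed_split
        ).reset_index(drop=True)
    state["features"] = table
    table.to_csv(out / "features.csv", index=False)
    return {
        "n_records_in": n_total,
        "n_modeling_rows": len(table),
        "n_filtered": n_total - len(table),
    }


def _stage_train(config: RunConfig, state: dict, out: Path) -> dict:
    table = state["features"]
    train, validation = split_dataset(table, SplitSpec(seed=config.seed_split))
    state["train"], state["validation"] = train, validation
    report = {"n_train": len(train), "n_validation": len(validation), "models": {}}
    state["summaries"] = {}
    state["classifiers"] = {}
    for kind in config.models:
        cfg = ClassifierConfig(kind=kind, n_trees=config.n_trees, seed=config.seed_training)
        clf = train_classifier(train, cfg)
        pred = predict(clf, validation)
        state["classifiers"][kind] = clf
        pd.DataFrame(
            {"observed": validation["behavior"].to_numpy(), "predicted": pred}
        ).to_csv(out / f"predictions_{kind}.csv", index=False)
        state["summaries"][kind] = overall_metrics(
            confusion_matrix(validation["behavior"].to_numpy(dtype=object), pred)
        )
        report["models"][kind] = {"n_features": len(clf.feature_columns)}
    return report


def _stage_evaluate(config: RunConfig, state: dict, out: Path) -> dict:
    reports = {kind: s.to_dict() for kind, s in state["summaries"].items()}
    (out / "evaluation.json").write_text(json.dumps(reports, indent=2, sort_keys=True))
    return reports


def _stage_ethogram(config: RunConfig, state: dict, out: Path) -> dict:
    bundle: StudyBundle = state["bundle"]
    budgets = time_budget(bundle.observations, grouping="overall")
    by_group = time_budget(
        bundle.observations.merge(
            pd.DataFrame(
                {
                    "animal_id": [a.animal_id for a in bundle.animals],
                    "genetic_group": [a.genetic_group for a in bundle.animals],
                }
            ),
            on="animal_id",
        ),
        grouping="genetic_group",
    )
    # intake frequency per animal from the best model's predicted labels
    clf = state["classifiers"][config.best_model]
    table = state["features"].copy()
    table["predicted"] = predict(clf, table)
    intake = {}
    for animal_id, sub in table.groupby("animal_id"):
        n_intake = int(sub["predicted"].isin({"grazing", "eating"}).sum())
        # rows may be a subsample; scale counts by the sampled fraction of 6-s slots
        mph = (n_intake / len(sub)) * 60.0
        intake[str(animal_id)] = {
            "minutes_per_hour": float(mph),
            "hours_per_day": min_per_hour_to_h_per_day(min(mph, 60.0)),
        }
    state["intake_predicted"] = {k: v["minutes_per_hour"] for k, v in intake.items()}
    report = {
        "time_budget_overall": budgets[0].percentages,
        "time_budget_by_group": {b.scope: b.percentages for b in by_group},
        "intake_by_animal": intake,
        "intake_mean_min_per_h": float(
            np.mean([v["minutes_per_hour"] for v in intake.values()])
        ),
    }
    (out / "ethogram.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _stage_forecast(config: RunConfig, state: dict, out: Path) -> dict:
    bundle: StudyBundle = state["bundle"]
    perf = bundle.performance.copy()
    predicted_base = state.get("intake_predicted", {})
    if predicted_base:
        perf["intake_frequency"] = (
            perf["animal_id"].map(predicted_base).fillna(perf["intake_frequency"])
            + perf["intake_period_offset"]
        )
    train, validation = split_dataset(
        perf, SplitSpec(seed=config.seed_split, strategy="random")
    )
    model = fit_mlr(train)
    validation = validation.copy()
    validation["iadg_predicted"] = predict_iadg(model, validation)
    evals = evaluate_forecast_by_group(validation)
    vmax, vmin, vmean = summarize_iadg(perf["iadg_observed"])
    pmax, pmin, pmean = summarize_iadg(validation["iadg_predicted"])
    state["forecast_validation"] = validation
    report = {
        "coefficients": {str(k): float(v) for k, v in model.params.items()},
        "evaluation": {
            scope: {"pearson_r": e.pearson_r, "mse": e.mse, "n": e.n}
            for scope, e in evals.items()
        },
        "iadg_observed_summary": {"max": vmax, "min": vmin, "mean": vmean},
        "iadg_predicted_summary": {"max": pmax, "min": pmin, "mean": pmean},
    }
    (out / "forecast.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _stage_pca(config: RunConfig, state: dict, out: Path) -> dict:
    bundle: StudyBundle = state["bundle"]
    result = run_pca(bundle.performance)
    silhouette = group_separation(
        result.scores, bundle.performance["genetic_group"].to_numpy()
    )
    report = {
        "variance_explained_pct": [float(v) for v in result.variance_explained_pct],
        "two_component_pct": two_component_variability(result),
        "group_silhouette": silhouette,
        "variable_importance_pc1": {
            str(k): float(v)
            for k, v in result.variable_importance_pct["PC1"].items()
        },
        "encoding": "genetic_group as reference-coded indicators",
    }
    (out / "pca.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "featurize": _stage_featurize,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
    "ethogram": _stage_ethogram,
    "forecast": _stage_forecast,
    "pca": _stage_pca,
}
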
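"""End-to-end orchestration: simulate -> QC/denoise -> FC -> evaluate -> attribute.

All randomness is funnelled through named seeds recorded in the run manifest;
re-running with an identical config reproduces identical manifests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import attribution as attr_mod
from .connectivity import SeedSpec, extract_roi_features, make_sphere_mask, seed_fc_map
from .io import array_hash, records_to_table
from .model_eval import (
    CVResult,
    LinearModel,
    clinical_baseline_features,
    cross_validate,
    default_model_factory,
)
from .preprocess import QCThresholds, preprocess_subject
from .synthetic import (
    SimConfig,
    iter_cohort,
    make_atlas,
    make_qc_fixture_cohort39,
)

__all__ = ["PipelineConfig", "FCDataset", "build_fc_dataset", "evaluate_dataset",
           "attribute_dataset", "run_pipeline", "run_qc_cohort39"]


@dataclass(frozen=True)
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    seed_roi: SeedSpec = field(default_factory=SeedSpec)
    regions: Optional[tuple[int, ...]] = None  # a-priori region labels; None = all
    model: str = "l1"  # l1 | clinical
    n_responders: int = 17
    n_nonresponders: int = 17
    cv_iterations: int = 5
    cv_folds: int = 10
    cv_seed: int = 0
    top_k_fraction: float = 0.1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in raw.get("sim", {}).items()})
        qc = QCThresholds(**raw.get("qc", {}))
        seed_raw = raw.get("seed", {})
        seed_roi = SeedSpec(
            center_mni_mm=tuple(seed_raw.get("center_mni_mm", (-48.0, 0.0, 0.0))),
            radius_mm=seed_raw.get("radius_mm", 15.0),
        )
        keys = {f.name for f in dataclasses.fields(cls)} - {"sim", "qc", "seed_roi"}
        extra = {k: v for k, v in raw.items() if k in keys}
        if "regions" in extra and extra["regions"] is not None:
            extra["regions"] = tuple(extra["regions"])
        return cls(sim=sim, qc=qc, seed_roi=seed_roi, **extra)


@dataclass
class FCDataset:
    """Feature matrix + labels + bookkeeping from the FC stages."""

    X: np.ndarray
    y: np.ndarray
    feature_template: object  # FeatureVector of the first retained subject
    records: list
    excluded: list[dict]
    atlas: object


def build_fc_dataset(config: PipelineConfig) -> FCDataset:
    """Simulate the cohort and run QC, denoising and seed-FC feature
    extraction; excluded subjects are dropped with their reason logged."""
    atlas = make_atlas(config.sim)
    sphere = make_sphere_mask(config.seed_roi, config.sim.grid_dims, config.sim.affine)
    regions = (
        list(config.regions) if config.regions is not None else atlas.region_labels
    )

    rows, labels, records, excluded = [], [], [], []
    template = None
    for record, sim in iter_cohort(
        config.n_responders, config.n_nonresponders, config.sim, atlas=atlas
    ):
        clean, report, censor = preprocess_subject(
            sim.bold, sim.tissue_masks["wm"], sim.tissue_masks["csf"], config.qc
        )
        if clean is None:
            excluded.append(
                {"subject_id": record.subject_id,
                 "reason": report.exclusion_reason.value}
            )
            continue
        fc = seed_fc_map(clean, sphere, censor_mask=censor, seed=config.seed_roi)
        fv = extract_roi_features(fc, atlas, regions)
        if template is None:
            template = fv
        rows.append(fv.values)
        labels.append(int(record.is_responder))
        records.append(record)
    if not rows:
        raise RuntimeError("all subjects excluded by QC")
    return FCDataset(
        X=np.vstack(rows),
        y=np.asarray(labels),
        feature_template=template,
        records=records,
        excluded=excluded,
        atlas=atlas,
    )


def evaluate_dataset(config: PipelineConfig, dataset: FCDataset) -> CVResult:
    if config.cv_folds > len(dataset.y):
        raise ValueError(
            f"cv_folds={config.cv_folds} exceeds retained cohort size "
            f"{len(dataset.y)}"
        )
    if config.model == "clinical":
        X = clinical_baseline_features(dataset.records).to_numpy()
    elif config.model == "l1":
        X = dataset.X
    else:
        raise ValueError(f"unknown model choice {config.model!r}")
    return cross_validate(
        default_model_factory(),
        X,
        dataset.y,
        n_iterations=config.cv_iterations,
        n_folds=config.cv_folds,
        seed=config.cv_seed,
        keep_models=True,
    )


def _pipeline_to_linear(model) -> tuple[LinearModel, np.ndarray]:
    """Convert the fitted (scaler, L1-logistic) pipeline to original-unit
    weights; the training-fold mean (the scaler's mean) is the attribution
    background."""
    scaler = model.named_steps["scale"]
    clf = model.named_steps["clf"]
    w = clf.coef_.ravel() / scaler.scale_
    b = float(clf.intercept_[0] - (clf.coef_.ravel() * scaler.mean_ / scaler.scale_).sum())
    return LinearModel(weights=w, intercept=b), scaler.mean_.copy()


def attribute_dataset(
    config: PipelineConfig, dataset: FCDataset, cv_result: CVResult
) -> pd.DataFrame:
    """Fold-averaged linear-Shapley attribution and regional percentages.

    Per fold the test subjects' attributions are computed against the
    training-fold mean background; mean |attribution| per voxel is averaged
    over all test predictions, the top-K voxels selected and tallied per
    region.
    """
    if cv_result.models is None:
        raise ValueError("cross_validate must be run with keep_models=True")
    n, p = dataset.X.shape
    abs_sum = np.zeros(p)
    count = 0
    for model, train_idx, test_idx in cv_result.models:
        linear, background = _pipeline_to_linear(model)
        shap = attr_mod.linear_shap(linear, dataset.X[test_idx], background)
        abs_sum += np.abs(shap.values).sum(axis=0)
        count += len(test_idx)
    pooled = attr_mod.ShapMatrix(
        values=(abs_sum / count)[None, :], background_mean=np.zeros(p)
    )
    k = max(1, int(round(config.top_k_fraction * p)))
    top, _ = attr_mod.top_k_voxels(pooled, k=k)
    contribs = attr_mod.region_contributions(
        top, dataset.feature_template, names=dataset.atlas.names
    )
    return attr_mod.contributions_table(contribs)


def run_qc_cohort39(seed: int, qc: Optional[QCThresholds] = None,
                    config: Optional[SimConfig] = None) -> dict:
    """QC accounting on the 39-subject fixture (study-flow-chart style)."""
    from .preprocess import apply_exclusion_rule, detect_outlier_volumes, make_qc_report

    qc = qc or QCThresholds()
    exclusions = []
    retained = []
    for record, bold, registration_ok in make_qc_fixture_cohort39(seed, config=config):
        censor = detect_outlier_volumes(bold, qc)
        report = apply_exclusion_rule(make_qc_report(censor), registration_ok, qc)
        if report.excluded:
            exclusions.append(
                {"subject_id": record.subject_id,
                 "reason": report.exclusion_reason.value,
                 "censored_fraction": report.censored_fraction}
            )
        else:
            retained.append(record.subject_id)
    return {"n_input": 39, "n_retained": len(retained),
            "exclusions": exclusions, "retained": retained}


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute all stages and return (and optionally write) the run manifest."""
    dataset = build_fc_dataset(config)
    cv_result = evaluate_dataset(config, dataset)
    summary = cv_result.summary()
    contribs = (
        attribute_dataset(config, dataset, cv_result) if config.model == "l1" else None
    )

    manifest = {
        "config": json.loads(json.dumps(config.to_dict(), default=str)),
        "seeds": {"sim": config.sim.seed, "cv": config.cv_seed},
        "n_subjects_retained": int(len(dataset.y)),
        "exclusions": dataset.excluded,
        "hashes": {
            "features": array_hash(dataset.X),
            "labels": array_hash(dataset.y),
            "clinical_table": array_hash(
                records_to_table(dataset.records).to_csv(sep="\t", index=False)
            ),
            "cv_predictions": array_hash(
                np.concatenate([f.y_pred for f in cv_result.folds])
            ),
        },
        "metrics": {
            name: {"mean": float(summary["mean"][name]), "se": float(summary["se"][name])}
            for name in summary.index
        },
    }
    if contribs is not None:
        manifest["hashes"]["region_contributions"] = array_hash(
            contribs.to_csv(sep="\t", index=False)
        )
        manifest["top_regions"] = contribs.head(5).to_dict(orient="records")

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        records_to_table(dataset.records).to_csv(
            out / "clinical.tsv", sep="\t", index=False
        )
        summary.to_csv(out / "cv_summary.tsv", sep="\t")
        if contribs is not None:
            contribs.to_csv(out / "region_contributions.tsv", sep="\t", index=False)
    return manifest
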
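"""End-to-end experiment orchestration.

Ties the stages together: synthesize (or load) labeled scenes, segment
each fruit, sample the stalk/middle/tip ROI triplet, extract the three
descriptors, train the 3 x 3 descriptor/classifier grid and report a
confusion matrix, per-class recall and overall accuracy per combination
— the structure of the study's result tables.  Every artifact is a pure
function of the configuration and its seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classifiers as clf
from . import features as feat
from .evaluation import EvalReport, evaluate, repeated_cv
from .roi import sample_rois
from .segmentation import iou, segment
from .synthetic import (
    DEFAULT_APPEARANCE,
    STAGES,
    LabeledScene,
    SceneConfig,
    StageAppearanceSpec,
    generate_dataset,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


def _from_mapping(cls, data: dict, context: str):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {context} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of one experiment run."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    appearance: dict[str, StageAppearanceSpec] = field(
        default_factory=lambda: dict(DEFAULT_APPEARANCE)
    )
    n_train_per_stage: int = 50
    n_test_per_stage: int = 30
    opening_radius: int = 10
    roi_variant: str = "span"
    roi_strict: bool = False
    roi_min_coverage: float = 0.0
    descriptors: tuple[str, ...] = ("color", "texture", "shape")
    classifiers: tuple[str, ...] = ("nb", "lda", "svm")
    texture_normalize: bool = True
    svm_C: float = 1.0
    lda_variance_target: float = 0.90
    cv_folds: int = 10
    cv_repeats: int = 20
    run_cv: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "scene" in data:
            data["scene"] = _from_mapping(SceneConfig, data["scene"], "scene")
        if "appearance" in data:
            data["appearance"] = {
                stage: _from_mapping(
                    StageAppearanceSpec, {"stage": stage, **spec}, f"appearance[{stage}]"
                )
                for stage, spec in data["appearance"].items()
            }
        for key in ("descriptors", "classifiers"):
            if key in data:
                data[key] = tuple(data[key])
        return _from_mapping(cls, data, "pipeline")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["appearance"] = {
            stage: dataclasses.asdict(spec) for stage, spec in self.appearance.items()
        }
        d["descriptors"] = list(self.descriptors)
        d["classifiers"] = list(self.classifiers)
        return d


@dataclass(frozen=True)
class SceneRecord:
    """Per-scene products of the segmentation + ROI + feature stages."""

    label: str
    bounds_xyy: tuple[int, int, int]
    mask_iou: float
    features: dict[str, np.ndarray]


def process_scene(
    scene: LabeledScene, config: PipelineConfig, roi_seed: int
) -> SceneRecord:
    """Segment one scene, place the ROI triplet and extract descriptors."""
    mask, bounds = segment(scene.image, opening_radius=config.opening_radius)
    triplet = sample_rois(
        scene.image,
        bounds,
        mask=mask,
        seed=roi_seed,
        variant=config.roi_variant,
        strict=config.roi_strict,
        min_coverage=config.roi_min_coverage,
        source_label=scene.label,
    )
    features = {
        name: feat.FEATURE_EXTRACTORS[name](triplet).values
        for name in config.descriptors
    }
    return SceneRecord(
        label=scene.label,
        bounds_xyy=(bounds.x_ref, bounds.y_ref, bounds.y_ref_prime),
        mask_iou=iou(mask, scene.mask),
        features=features,
    )


def extract_feature_tables(
    scenes: list[LabeledScene], config: PipelineConfig, seed_offset: int = 0
) -> tuple[dict[str, np.ndarray], np.ndarray, list[SceneRecord]]:
    """Feature matrix per descriptor plus the label vector for a scene list."""
    records = []
    for i, scene in enumerate(scenes):
        t0 = time.perf_counter()
        rec = process_scene(scene, config, roi_seed=config.seed + seed_offset + i)
        logger.debug(
            "scene %d (%s): IoU=%.3f, %.0f ms",
            i, scene.label, rec.mask_iou, 1e3 * (time.perf_counter() - t0),
        )
        if rec.mask_iou < 0.9:
            logger.warning("scene %d (%s): mask IoU %.3f below 0.90", i, scene.label, rec.mask_iou)
        records.append(rec)
    labels = np.asarray([r.label for r in records])
    tables = {
        name: np.vstack([r.features[name] for r in records])
        for name in config.descriptors
    }
    return tables, labels, records


def _fit_kwargs(config: PipelineConfig, name: str) -> dict:
    if name == "svm":
        return {"C": config.svm_C}
    if name == "lda":
        return {"variance_target": config.lda_variance_target}
    return {}


def run_experiment(config: PipelineConfig) -> dict:
    """Full synthetic experiment over the descriptor x classifier grid.

    Returns a bundle with one :class:`EvalReport` per combination, the
    per-scene segmentation IoUs and the resolved configuration.
    """
    logger.info("generating %d train + %d test scenes per stage",
                config.n_train_per_stage, config.n_test_per_stage)
    train_scenes = generate_dataset(
        config.scene, config.n_train_per_stage, seed=config.seed,
        appearance=config.appearance,
    )
    test_scenes = generate_dataset(
        config.scene, config.n_test_per_stage, seed=config.seed + 100_003,
        appearance=config.appearance,
    )
    train_X, train_y, train_rec = extract_feature_tables(train_scenes, config)
    test_X, test_y, test_rec = extract_feature_tables(
        test_scenes, config, seed_offset=1_000_000
    )

    reports: dict[tuple[str, str], EvalReport] = {}
    for d_name in config.descriptors:
        for c_name in config.classifiers:
            t0 = time.perf_counter()
            model = clf.fit(c_name, train_X[d_name], train_y, **_fit_kwargs(config, c_name))
            y_pred = clf.predict(model, test_X[d_name])
            report = evaluate(test_y, y_pred, class_labels=STAGES)
            if config.run_cv:
                kwargs = _fit_kwargs(config, c_name)

                def fit_predict(Xtr, ytr, Xte, _c=c_name, _kw=kwargs):
                    return clf.predict(clf.fit(_c, Xtr, ytr, **_kw), Xte)

                cv_mean, cv_std = repeated_cv(
                    train_X[d_name], train_y, fit_predict,
                    k=config.cv_folds, repeats=config.cv_repeats, seed=config.seed,
                )
                report = dataclasses.replace(report, cv_mean=cv_mean, cv_std=cv_std)
            reports[(d_name, c_name)] = report
            logger.info(
                "%s + %s: OA=%.1f%% (%.1f s)",
                d_name, c_name, report.oa, time.perf_counter() - t0,
            )

    return {
        "config": config,
        "reports": reports,
        "train_iou": np.asarray([r.mask_iou for r in train_rec]),
        "test_iou": np.asarray([r.mask_iou for r in test_rec]),
        "train_labels": train_y,
        "test_labels": test_y,
    }


def summary_table(reports: dict[tuple[str, str], EvalReport]) -> str:
    """OA summary over the descriptor x classifier grid."""
    descriptors = sorted({d for d, _ in reports})
    names = sorted({c for _, c in reports})
    lines = ["\t".join(["descriptor", *names])]
    for d in descriptors:
        row = [d] + [f"{reports[(d, c)].oa:.1f}" for c in names]
        lines.append("\t".join(row))
    return "\n".join(lines)


def reports_to_json(bundle: dict) -> dict:
    """JSON-serializable view of a run_experiment bundle."""
    out = {
        "schema_version": SCHEMA_VERSION,
        "config": bundle["config"].to_dict(),
        "reports": {},
        "segmentation": {
            "train_iou_mean": float(bundle["train_iou"].mean()),
            "train_iou_min": float(bundle["train_iou"].min()),
            "test_iou_mean": float(bundle["test_iou"].mean()),
            "test_iou_min": float(bundle["test_iou"].min()),
        },
    }
    for (d, c), rep in bundle["reports"].items():
        entry = {
            "confusion": np.asarray(rep.confusion.counts).tolist(),
            "class_labels": list(rep.confusion.class_labels),
            "rr": [float(v) for v in rep.rr],
            "oa": float(rep.oa),
        }
        if rep.cv_mean is not None:
            entry["cv_mean"] = rep.cv_mean
            entry["cv_std"] = rep.cv_std
        out["reports"][f"{d}+{c}"] = entry
    return out


# ---------------------------------------------------------------------------
# model serialization (versioned JSON metadata + array payload)
# ---------------------------------------------------------------------------

def save_model(model, path: str | Path) -> None:
    """Serialize a fitted model to an .npz with a JSON metadata entry."""
    path = Path(path)
    meta = {"schema_version": SCHEMA_VERSION}
    arrays: dict[str, np.ndarray] = {}
    if isinstance(model, clf.GaussianNBModel):
        meta["kind"] = "nb"
        arrays = {
            "classes": model.classes, "priors": model.priors,
            "means": model.means, "variances": model.variances,
        }
    elif isinstance(model, clf.LDAModel):
        meta["kind"] = "lda"
        arrays = {
            "classes": model.classes,
            "std_mean": model.standardizer.mean, "std_scale": model.standardizer.scale,
            "projection": model.projection, "centroids": model.centroids,
            "eigenvalues": model.eigenvalues,
        }
        if model.pca_basis is not None:
            arrays["pca_mean"] = model.pca_mean
            arrays["pca_basis"] = model.pca_basis
    elif isinstance(model, clf.SVMModel):
        meta["kind"] = "svm"
        meta["C"] = model.C
        meta["n_machines"] = len(model.machines)
        meta["pairs"] = [[str(m.class_pos), str(m.class_neg)] for m in model.machines]
        meta["biases"] = [m.bias for m in model.machines]
        arrays = {
            "classes": model.classes,
            "std_mean": model.standardizer.mean, "std_scale": model.standardizer.scale,
        }
        for i, m in enumerate(model.machines):
            arrays[f"sv_{i}"] = m.support_vectors
            arrays[f"ay_{i}"] = m.support_alpha_y
            arrays[f"alphas_{i}"] = m.alphas
            arrays[f"labels_{i}"] = m.labels_pm
    else:
        raise TypeError(f"cannot serialize model of type {type(model)!r}")
    if arrays["classes"].dtype == object:  # e.g. labels read via pandas
        arrays["classes"] = arrays["classes"].astype(str)
    np.savez(path, _meta=np.array(json.dumps(meta)), **arrays)


def load_model(path: str | Path):
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["_meta"]))
        if meta.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema {meta.get('schema_version')!r}")
        kind = meta["kind"]
        if kind == "nb":
            return clf.GaussianNBModel(
                classes=data["classes"], priors=data["priors"],
                means=data["means"], variances=data["variances"],
            )
        std = clf.Standardizer(mean=data["std_mean"], scale=data["std_scale"])
        if kind == "lda":
            return clf.LDAModel(
                classes=data["classes"], standardizer=std,
                pca_mean=data["pca_mean"] if "pca_mean" in data else None,
                pca_basis=data["pca_basis"] if "pca_basis" in data else None,
                projection=data["projection"], centroids=data["centroids"],
                eigenvalues=data["eigenvalues"],
            )
        if kind == "svm":
            classes = data["classes"]
            machines = []
            for i, (pos, neg) in enumerate(meta["pairs"]):
                # restore original label dtype through the classes array
                cpos = classes[np.array([str(c) for c in classes]) == pos][0]
                cneg = classes[np.array([str(c) for c in classes]) == neg][0]
                machines.append(
                    clf.BinarySVM(
                        class_pos=cpos, class_neg=cneg,
                        support_vectors=data[f"sv_{i}"],
                        support_alpha_y=data[f"ay_{i}"],
                        bias=float(meta["biases"][i]),
                        alphas=data[f"alphas_{i}"],
                        labels_pm=data[f"labels_{i}"],
                    )
                )
            return clf.SVMModel(
                classes=classes, standardizer=std,
                machines=tuple(machines), C=float(meta["C"]),
            )
        raise ValueError(f"unknown model kind {kind!r}")
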
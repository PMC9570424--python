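"""End-to-end orchestration: simulate -> fit -> preprocess -> featurize ->
cluster -> patient-level risk evaluation.

The pipeline mirrors how the screening method is applied: an unsupervised
two-cluster model is trained on images from normal and malignant-group
patients, oriented by the normal group, then applied to a validation
cohort; each validation patient is scored by the percentage of qualified
images classified abnormal, and the scores are evaluated against the
patient-level reference standard with ROC/AUC and a Youden-optimal cutoff.

All randomness derives from one global seed through spawned substreams,
so a re-run with the same configuration reproduces every output.
"""
from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import cluster as cl
from . import risk
from .containers import AcquisitionConfig
from .features import (A2_COLORMAP, TM_COLORMAP, extract_features, fit_pca,
                       render_pseudocolor, stack_modalities, transform_pca)
from .fitting import FitConfig, fit_image
from .preprocess import (QCConfig, otsu_segment, peak_statistics, qc_qualify,
                         refine_mask, smooth_maps)
from .simulate import MALIGNANT_GROUPS, CohortSpec, iter_patients

__all__ = ["PipelineConfig", "validate_config", "load_config", "run_pipeline",
           "default_screening_config", "run_screening_trial"]

MODALITIES = ("tm", "a2", "tm&a2")


@dataclass
class PipelineConfig:
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    training: CohortSpec = field(default_factory=CohortSpec)
    validation: CohortSpec = field(default_factory=lambda: CohortSpec(
        patients_per_group={"CC": 3, "CINII/III": 2, "benign": 8,
                            "normal": 7}))
    fit: FitConfig = field(default_factory=FitConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    modality: str = "tm&a2"
    feature_backend: str = "deterministic_bank"
    pca_preserved_fraction: float = 0.30
    kmeans_n_init: int = 10
    mask_min_area_px: int = 100
    fit_method: str = "grid"
    seed: int = 0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_KNOWN_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}


def validate_config(config) -> list:
    """Collect every problem in a configuration (never fail on the first)."""
    if isinstance(config, PipelineConfig):
        cfg = config.to_dict()
    elif isinstance(config, dict):
        cfg = config
    else:
        raise TypeError("config must be a PipelineConfig or a dict")
    problems: list[str] = []
    for key in cfg:
        if key not in _KNOWN_KEYS and key != "clustering":
            problems.append(f"unknown configuration key {key!r}")
    frac = cfg.get("pca_preserved_fraction", 0.30)
    if not (isinstance(frac, (int, float)) and 0.0 < frac <= 1.0):
        problems.append(
            f"pca_preserved_fraction must lie in (0, 1], got {frac!r}")
    modality = cfg.get("modality", "tm&a2")
    if modality not in MODALITIES:
        problems.append(f"modality must be one of {MODALITIES}, got {modality!r}")
    backend = cfg.get("feature_backend", "deterministic_bank")
    if backend not in ("deterministic_bank", "cnn_alexnet"):
        problems.append(f"unknown feature_backend {backend!r}")
    k = cfg.get("clustering", {}).get("k", 2) if isinstance(
        cfg.get("clustering"), dict) else 2
    if k != 2:
        problems.append(
            f"cluster count is fixed at 2 by design, got k={k}")
    n_init = cfg.get("kmeans_n_init", 10)
    if not (isinstance(n_init, int) and n_init >= 1):
        problems.append(f"kmeans_n_init must be a positive integer, got {n_init!r}")
    for section in ("training", "validation"):
        sec = cfg.get(section)
        if isinstance(sec, dict) and sec.get("images_per_patient", 1) < 1:
            problems.append(f"{section}.images_per_patient must be >= 1")
    return problems


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file (flat per-stage sections)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"configuration file {path} is not a mapping")
    problems = validate_config(raw)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    kwargs = dict(raw)
    if "acquisition" in kwargs:
        kwargs["acquisition"] = AcquisitionConfig(**kwargs["acquisition"])
    for section in ("training", "validation"):
        if section in kwargs:
            sec = dict(kwargs[section])
            if "cells_per_image" in sec:
                sec["cells_per_image"] = tuple(sec["cells_per_image"])
            kwargs[section] = CohortSpec(**sec)
    if "fit" in kwargs:
        kwargs["fit"] = FitConfig(**kwargs["fit"])
    if "qc" in kwargs:
        kwargs["qc"] = QCConfig(**kwargs["qc"])
    kwargs.pop("clustering", None)
    return PipelineConfig(**kwargs)


def _sub_seed(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] % (2 ** 31))


def _image_features(rec, config: PipelineConfig, feature_seed: int):
    """Fit, segment, QC and featurize one acquisition.

    Returns (qualified, feature_vector or None, reasons, summary or None).
    """
    maps = fit_image(rec.image, config.fit, method=config.fit_method)
    try:
        fg = otsu_segment(maps.intensity)
    except ValueError:
        return False, None, ["segmentation failed: constant intensity"], None
    mask = refine_mask(fg, min_area_px=config.mask_min_area_px)
    qualified, reasons = qc_qualify(maps, mask, config.qc)
    if not qualified:
        return False, None, reasons, None
    maps = smooth_maps(maps, mask)
    summary = peak_statistics(maps, mask)
    tm_img = render_pseudocolor(maps.tm_ps, mask, TM_COLORMAP, "tm")
    a2_img = render_pseudocolor(maps.a2_frac * 100.0, mask, A2_COLORMAP, "a2")
    if config.modality == "tm":
        img = tm_img
    elif config.modality == "a2":
        img = a2_img
    else:
        img = stack_modalities(tm_img, a2_img)
    fv = extract_features(img, backend=config.feature_backend,
                          seed=feature_seed)
    return True, fv.values, [], summary


def _collect(cohort_spec: CohortSpec, config: PipelineConfig,
             feature_seed: int):
    """Process a cohort; returns per-image features with provenance."""
    rows = []
    X = []
    for patient in iter_patients(cohort_spec, config=config.acquisition):
        for rec in patient.images:
            ok, feats, reasons, summary = _image_features(
                rec, config, feature_seed)
            rows.append({
                "patient_id": patient.patient_id, "group": patient.group,
                "image_id": rec.image_id, "qualified": ok,
                "reasons": reasons, "truth_label": rec.truth_label,
                "peak_tm_ps": summary.peak_tm_ps if summary else np.nan,
                "peak_a2_pct": summary.peak_a2_pct if summary else np.nan,
            })
            if ok:
                X.append(feats)
    return rows, (np.vstack(X) if X else np.empty((0, 0)))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a manifest with per-stage records and results."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    root = np.random.SeedSequence(config.seed)
    train_seq, val_seq, km_seq, feat_seq = root.spawn(4)
    feature_seed = _sub_seed(feat_seq)
    train_spec = replace(config.training, seed=_sub_seed(train_seq))
    val_spec = replace(config.validation, seed=_sub_seed(val_seq))

    manifest = {"seed": config.seed, "modality": config.modality,
                "stages": []}

    def stage(name):
        entry = {"stage": name, "t0": time.time()}
        manifest["stages"].append(entry)
        return entry

    # --- training cohort: simulate + fit + preprocess + featurize
    e = stage("train_features")
    train_rows, X_train = _collect(train_spec, config, feature_seed)
    e["n_images"] = len(train_rows)
    e["n_qualified"] = int(sum(r["qualified"] for r in train_rows))
    e["wall_s"] = time.time() - e.pop("t0")
    if X_train.shape[0] < 2:
        raise RuntimeError("training stage produced fewer than 2 qualified "
                           "images; cannot fit the model")

    # --- PCA + k-means, oriented on the normal training group
    e = stage("train_model")
    pca = fit_pca(X_train, config.pca_preserved_fraction)
    Z_train = transform_pca(pca, X_train)
    model = cl.fit_kmeans(Z_train, k=2, seed=_sub_seed(km_seq),
                          n_init=config.kmeans_n_init)
    qualified_train = [r for r in train_rows if r["qualified"]]
    assignments = model.assign(Z_train)
    group_labels = ["normal" if r["group"] == "normal" else "malignant"
                    for r in qualified_train]
    model = cl.label_clusters(model, assignments, group_labels)
    normal_cluster = [c for c, l in model.label_map.items()
                      if l == cl.NORMAL][0]
    in_normal = assignments == normal_cluster
    truth_normal = np.array([r["truth_label"] == "normal"
                             for r in qualified_train])
    purity = float(truth_normal[in_normal].mean()) if in_normal.any() else np.nan
    train_pred = [model.label_map[int(c)] for c in assignments]
    train_acc = float(np.mean([p == r["truth_label"] for p, r in
                               zip(train_pred, qualified_train)]))
    e.update({"n_pca_components": pca.n_components,
              "normal_cluster_purity": purity,
              "train_image_accuracy": train_acc,
              "inertia": model.inertia})
    e["wall_s"] = time.time() - e.pop("t0")

    # --- validation cohort
    e = stage("validate")
    val_rows, X_val = _collect(val_spec, config, feature_seed)
    Z_val = transform_pca(pca, X_val) if X_val.size else X_val
    labels = cl.predict_labels(model, Z_val) if X_val.size else []
    it = iter(labels)
    for r in val_rows:
        r["pred_label"] = next(it) if r["qualified"] else None
    val_image_acc = float(np.mean([r["pred_label"] == r["truth_label"]
                                   for r in val_rows if r["qualified"]]))

    patient_scores, patient_truth, patient_ids = [], [], []
    unscorable = []
    for pid in dict.fromkeys(r["patient_id"] for r in val_rows):
        prows = [r for r in val_rows if r["patient_id"] == pid]
        labels_p = [r["pred_label"] for r in prows if r["qualified"]]
        if not labels_p:
            unscorable.append(pid)
            continue
        patient_ids.append(pid)
        patient_scores.append(risk.abnormal_fraction(labels_p))
        patient_truth.append(prows[0]["group"] in MALIGNANT_GROUPS)
    e.update({"n_images": len(val_rows),
              "n_qualified": int(sum(r["qualified"] for r in val_rows)),
              "unscorable_patients": unscorable,
              "val_image_accuracy": val_image_acc})
    e["wall_s"] = time.time() - e.pop("t0")

    # --- diagnostic evaluation
    e = stage("evaluate")
    roc = risk.roc_curve(np.array(patient_scores), np.array(patient_truth))
    cut = risk.youden_cutoff(roc)
    cm = risk.confusion(risk.classify_patients(patient_scores,
                                               cut.cutoff_pct),
                        np.array(patient_truth))
    se, sp = risk.sens_spec(cm)
    results = {
        "patient_auc": roc.auc,
        "cutoff_pct": cut.cutoff_pct,
        "sensitivity_pct": se,
        "specificity_pct": sp,
        "normal_cluster_purity": purity,
        "train_image_accuracy": train_acc,
        "val_image_accuracy": val_image_acc,
        "patients": [{"patient_id": i, "score_pct": s, "positive": bool(t)}
                     for i, s, t in zip(patient_ids, patient_scores,
                                        patient_truth)],
    }
    e["wall_s"] = time.time() - e.pop("t0")
    manifest["results"] = results

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cl.save_model(model, out / "model")
        (out / "results.json").write_text(json.dumps(results, indent=2))
        stripped = {**manifest, "stages": [
            {k: v for k, v in s.items()} for s in manifest["stages"]]}
        (out / "manifest.json").write_text(
            json.dumps(stripped, indent=2, default=str))
    return manifest


def default_screening_config(seed: int = 0, image_size_px: int = 128,
                             n_time_bins: int = 64,
                             modality: str = "tm&a2") -> PipelineConfig:
    """Desk-scale screening trial configuration.

    Training mirrors the study's training split (14 normal, 5 cancer and
    4 high-grade CIN patients, 10 images each); validation holds 20
    patients across the four groups.  128 x 128 pixels and 64 time bins
    keep a full multi-seed trial tractable on one CPU without changing the
    statistical structure the generator emulates.
    """
    acq = AcquisitionConfig(image_size_px=image_size_px,
                            n_time_bins=n_time_bins)
    # cell-area QC cutoff scales with the field-of-view area
    min_cell = max(100, int(round(500 * (image_size_px / 256) ** 2)))
    return PipelineConfig(
        acquisition=acq,
        training=CohortSpec(
            patients_per_group={"normal": 14, "CC": 5, "CINII/III": 4}),
        validation=CohortSpec(
            patients_per_group={"CC": 3, "CINII/III": 2, "benign": 8,
                                "normal": 7}),
        qc=QCConfig(min_cell_pixels=min_cell),
        modality=modality,
        seed=seed,
    )


def run_screening_trial(seed: int = 0, **kwargs) -> dict:
    """One synthetic screening run; returns the results block."""
    config = default_screening_config(seed=seed, **kwargs)
    return run_pipeline(config)["results"]
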
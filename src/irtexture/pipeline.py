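"""End-to-end run orchestration: simulate/load -> preprocess -> extract ->
rank -> classify -> report, driven by one YAML-serializable config.

A run writes ``features.csv``, ``ranking.csv``, ``diagnostics.csv``,
``comparison.csv``, ``report.json``, a resolved copy of its configuration
and a log with per-stage timings. A single global seed fans out to
per-stage substreams, so (config, seed) fully determines every output.
Feature values are serialized at 12 significant digits, which makes reruns
byte-identical.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import (
    ClassifyConfig,
    feature_diagnostics,
    group_comparison,
    loocv,
    split_eval,
)
from .features import ALL_FEATURES, FeatureConfig, extract_features
from .image import GrayImage, ParameterError, RegionMask, read_image
from .preprocess import PreprocessConfig, preprocess
from .selection import rank_features, select_top_k
from .synthetic import CohortSpec, SyntheticRecord, generate_cohort

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"


def default_config() -> dict:
    """Full default configuration; every section mirrors module defaults."""
    return {
        "seed": 0,
        "mode": "synthetic",  # or "directory"
        "input_dir": None,
        "synthetic": {
            "n_cases": 23,
            "n_controls": 18,
            "height": 256,
            "width": 256,
            "bit_depth": 8,
            "corr_length_control": 8.0,
            "corr_length_case": 2.0,
            "lesion_count": 30,
            "lesion_radius_range": [2.0, 6.0],
            "lesion_amplitude": 40.0,
            "vessel_count": 6,
            "vessel_width": 3.0,
            "vessel_contrast": 40.0,
            "disc_center_jitter": 10.0,
            "disc_radius": 30.0,
            "disc_brightness": 240.0,
            "noise_sd": 2.0,
            "null_cohort": False,
        },
        "preprocess": {
            "median_kernel": 3,
            "clahe_clip": 2.0,
            "clahe_tiles": [8, 8],
            "stretch_percentiles": [2.0, 98.0],
            "od_struct_radius": 5,
            "od_threshold_percentile": 95.0,
            "od_dilation": 3,
            "order": ["median", "clahe"],
            "mask_optic_disc": True,
        },
        "features": {
            "ng": 8,
            "distance": 1,
            "symmetric": True,
            "directions": [0, 45, 90, 135],
            "sum_variance_center": "sum_average",
        },
        "selection": {"k": 5, "nested": False},
        "classify": {
            "protocol": "loocv",  # or "split50"
            "classifier": "svm_linear",
            "svm_c": 1.0,
            "knn_k": 3,
            "nb_var_floor": 1e-9,
            "split_fraction": 0.5,
        },
    }


def _deep_update(base: dict, override: dict) -> dict:
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], val)
        else:
            base[key] = val
    return base


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults merged with an optional YAML file and explicit overrides."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ParameterError(f"config {path} is not a mapping")
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, overrides)
    return cfg


def cohort_spec_from_config(cfg: dict) -> CohortSpec:
    syn = cfg["synthetic"]
    return CohortSpec(
        n_cases=syn["n_cases"],
        n_controls=syn["n_controls"],
        height=syn["height"],
        width=syn["width"],
        bit_depth=syn["bit_depth"],
        corr_length_control=syn["corr_length_control"],
        corr_length_case=syn["corr_length_case"],
        lesion_count=syn["lesion_count"],
        lesion_radius_range=tuple(syn["lesion_radius_range"]),
        lesion_amplitude=syn["lesion_amplitude"],
        vessel_count=syn["vessel_count"],
        vessel_width=syn["vessel_width"],
        vessel_contrast=syn["vessel_contrast"],
        disc_center_jitter=syn["disc_center_jitter"],
        disc_radius=syn["disc_radius"],
        disc_brightness=syn["disc_brightness"],
        noise_sd=syn["noise_sd"],
        seed=cfg["seed"],
        null_cohort=syn["null_cohort"],
    )


def preprocess_config_from_config(cfg: dict) -> PreprocessConfig:
    pp = cfg["preprocess"]
    return PreprocessConfig(
        median_kernel=pp["median_kernel"],
        clahe_clip=pp["clahe_clip"],
        clahe_tiles=tuple(pp["clahe_tiles"]),
        stretch_percentiles=tuple(pp["stretch_percentiles"]),
        od_struct_radius=pp["od_struct_radius"],
        od_threshold_percentile=pp["od_threshold_percentile"],
        od_dilation=pp["od_dilation"],
        order=tuple(pp["order"]),
        mask_optic_disc=pp["mask_optic_disc"],
    )


def feature_config_from_config(cfg: dict) -> FeatureConfig:
    ft = cfg["features"]
    return FeatureConfig(
        ng=ft["ng"],
        distance=ft["distance"],
        symmetric=ft["symmetric"],
        directions=tuple(ft["directions"]),
        sum_variance_center=ft["sum_variance_center"],
    )


def classify_config_from_config(cfg: dict) -> ClassifyConfig:
    cl = cfg["classify"]
    return ClassifyConfig(
        svm_c=cl["svm_c"], knn_k=cl["knn_k"], nb_var_floor=cl["nb_var_floor"]
    )


def load_directory(input_dir: str | Path) -> list[SyntheticRecord]:
    """Load images + labels.csv from a directory into records."""
    input_dir = Path(input_dir)
    labels_path = input_dir / "labels.csv"
    if not labels_path.exists():
        raise ParameterError(f"missing labels table {labels_path}")
    labels = pd.read_csv(labels_path)
    records = []
    for _, row in labels.iterrows():
        image_id, label = str(row["image_id"]), str(row["label"])
        if label not in ("case", "control"):
            raise ParameterError(f"{image_id}: label {label!r} not in {{case, control}}")
        matches = sorted(
            p for ext in ("png", "tif", "tiff") for p in input_dir.glob(f"{image_id}.{ext}")
        )
        if not matches:
            raise ParameterError(f"no image file found for labelled id {image_id!r}")
        records.append(
            SyntheticRecord(image_id=image_id, image=read_image(matches[0]), label=label)
        )
    return records


def validate_inputs(input_dir: str | Path, labels: pd.DataFrame | None = None) -> list[str]:
    """Itemized validation issues for a directory-mode input (never raises)."""
    input_dir = Path(input_dir)
    issues: list[str] = []
    if labels is None:
        labels_path = input_dir / "labels.csv"
        if not labels_path.exists():
            return [f"missing labels table {labels_path}"]
        labels = pd.read_csv(labels_path)
    if not {"image_id", "label"} <= set(labels.columns):
        issues.append("labels table must have columns image_id,label")
        return issues
    for _, row in labels.iterrows():
        image_id, label = str(row["image_id"]), str(row["label"])
        if label not in ("case", "control"):
            hint = " (did you mean 'case'?)" if label.upper() in ("ME", "CASE") else ""
            issues.append(f"{image_id}: label {label!r} not in {{case, control}}{hint}")
        matches = sorted(
            p for ext in ("png", "tif", "tiff") for p in input_dir.glob(f"{image_id}.{ext}")
        )
        if not matches:
            issues.append(f"{image_id}: no image file found")
            continue
        try:
            read_image(matches[0])
        except ParameterError as exc:
            issues.append(f"{image_id}: not single-channel grayscale ({exc})")
        except Exception as exc:  # unreadable file
            issues.append(f"{image_id}: unreadable ({exc})")
    return issues


def build_feature_table(
    records: list[SyntheticRecord],
    pre_cfg: PreprocessConfig,
    feat_cfg: FeatureConfig,
) -> pd.DataFrame:
    """Preprocess every image and assemble the per-image feature table.

    Columns: image_id, label, direction-averaged features, then the
    per-direction block suffixed _0/_45/_90/_135, in deterministic order.
    """
    rows = []
    for rec in records:
        enhanced, mask = preprocess(rec.image, pre_cfg)
        fv = extract_features(enhanced, mask, feat_cfg)
        row = {"image_id": rec.image_id, "label": rec.label}
        row.update({name: fv.values[name] for name in ALL_FEATURES})
        row.update(fv.per_direction)
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(cfg: dict, outdir: str | Path) -> dict:
    """Execute the full analysis and write all run artifacts to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    timings: dict[str, float] = {}
    report: dict = {"seed": cfg["seed"]}

    def _stage(name):
        logger.info("stage %s starting", name)
        return time.perf_counter()

    def _done(name, t0):
        timings[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", name, timings[name])

    try:
        resolved = copy.deepcopy(cfg)
        (outdir / "config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))
        manifest.append("config.yaml")

        t0 = _stage("input")
        if cfg["mode"] == "synthetic":
            records = generate_cohort(cohort_spec_from_config(cfg))
        elif cfg["mode"] == "directory":
            if not cfg.get("input_dir"):
                raise ParameterError("directory mode requires input_dir")
            records = load_directory(cfg["input_dir"])
        else:
            raise ParameterError(f"unknown mode {cfg['mode']!r}")
        _done("input", t0)

        t0 = _stage("extract")
        table = build_feature_table(
            records, preprocess_config_from_config(cfg), feature_config_from_config(cfg)
        )
        table.to_csv(outdir / "features.csv", index=False, float_format=FLOAT_FORMAT)
        manifest.append("features.csv")
        _done("extract", t0)

        labels = table["label"].to_numpy()
        averaged = table[list(ALL_FEATURES)]

        t0 = _stage("rank")
        ranked = rank_features(averaged, labels)
        ranked.table.to_csv(outdir / "ranking.csv", index=False, float_format=FLOAT_FORMAT)
        manifest.append("ranking.csv")
        selected = select_top_k(ranked, min(cfg["selection"]["k"], len(ranked.names)))
        report["selected_features"] = selected
        report["excluded_features"] = ranked.excluded
        _done("rank", t0)

        t0 = _stage("diagnostics")
        diag = feature_diagnostics(averaged, labels)
        diag.to_csv(outdir / "diagnostics.csv", index=False, float_format=FLOAT_FORMAT)
        manifest.append("diagnostics.csv")
        comparison = group_comparison(averaged, labels)
        comparison.to_csv(outdir / "comparison.csv", index=False, float_format=FLOAT_FORMAT)
        manifest.append("comparison.csv")
        report["top_feature"] = {
            "feature": str(diag.iloc[0]["feature"]),
            "auc": float(diag.iloc[0]["auc"]),
            "youden_j": float(diag.iloc[0]["youden_j"]),
        }
        _done("diagnostics", t0)

        t0 = _stage("classify")
        cl_cfg = classify_config_from_config(cfg)
        kind = cfg["classify"]["classifier"]
        if cfg["classify"]["protocol"] == "loocv":
            nested_k = cfg["selection"]["k"] if cfg["selection"]["nested"] else None
            cls_table = averaged if cfg["selection"]["nested"] else table[selected]
            rep = loocv(cls_table, labels, kind, cl_cfg, nested_k=nested_k)
        else:
            rep = split_eval(
                table[selected], labels, kind,
                fraction=cfg["classify"]["split_fraction"], seed=cfg["seed"], cfg=cl_cfg,
            )
        report["classification"] = rep.to_dict()
        _done("classify", t0)

        report["timings_s"] = timings
        (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        manifest.append("report.json")
        (outdir / "MANIFEST").write_text("\n".join(manifest + ["status: complete"]) + "\n")
        return report
    except Exception as exc:
        (outdir / "MANIFEST").write_text(
            "\n".join(manifest + [f"status: INCOMPLETE ({exc})"]) + "\n"
        )
        raise
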
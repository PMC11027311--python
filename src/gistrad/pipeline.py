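"""End-to-end pipeline: simulate -> preprocess -> roi -> extract -> label
-> train -> scree -> report.

Each stage reads its inputs from and writes its artifacts into a single run
directory, so stages can be re-run or toggled individually; a config echo
(with hash and seed) is stamped into the run directory and re-running from
it reproduces every numeric output exactly. The global seed is fanned out to
the stages through ``numpy.random.SeedSequence([seed, stage_index])`` so
stage streams never collide.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import classify, labeling, preprocessing, roi, scree, synthetic
from .classify import ModelConfig
from .features import FeatureConfig, extract_features
from .synthetic import MODEL_CATEGORIES, SyntheticParams, TextureEffect

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "roi", "extract", "label", "train", "scree")

# per-stage indices for seed fan-out
_STAGE_INDEX = {name: i for i, name in enumerate(STAGES)}


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stage-local 31-bit seed from the run's global seed."""
    ss = np.random.SeedSequence([global_seed, _STAGE_INDEX[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    seed: int = 0
    stages: tuple[str, ...] = STAGES
    synthetic: SyntheticParams = field(default_factory=lambda: SyntheticParams(n_images=400))
    threshold: float = preprocessing.DEFAULT_THRESHOLD
    erosion_radius: int | None = None  # None -> scale 100 px by image height
    features: FeatureConfig = field(default_factory=FeatureConfig)
    model: ModelConfig = field(default_factory=ModelConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["threshold"] = float(self.threshold)
        d["synthetic"]["image_shape"] = list(self.synthetic.image_shape)
        d["features"]["distances"] = list(self.features.distances)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        syn = dict(d.get("synthetic", {}))
        if "image_shape" in syn:
            syn["image_shape"] = tuple(syn["image_shape"])
        if "texture_effect" in syn:
            syn["texture_effect"] = TextureEffect(**syn["texture_effect"])
        feat = dict(d.get("features", {}))
        if "distances" in feat:
            feat["distances"] = tuple(feat["distances"])
        return cls(
            seed=int(d.get("seed", 0)),
            stages=tuple(d.get("stages", STAGES)),
            synthetic=SyntheticParams(**syn),
            threshold=float(d.get("threshold", preprocessing.DEFAULT_THRESHOLD)),
            erosion_radius=d.get("erosion_radius"),
            features=FeatureConfig(**feat),
            model=ModelConfig(**d.get("model", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_mask(path: Path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, (mask.astype(np.uint8) * 255))


def _read_mask(path: Path) -> np.ndarray:
    return tifffile.imread(path) > 0


def run_simulate(config: RunConfig, run_dir: Path) -> None:
    params = dataclasses.replace(
        config.synthetic, seed=stage_seed(config.seed, "simulate")
    )
    images, panels, manifest = synthetic.generate_cohort(params)
    img_dir = run_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    for img in images:
        tifffile.imwrite(img_dir / f"{img.image_id}.tif", img.pixels)
    manifest["records"].to_csv(run_dir / "manifest.csv", index=False)
    synthetic.panels_to_frame(panels).to_csv(run_dir / "panels.csv", index=False)
    (run_dir / "synthetic_params.json").write_text(
        json.dumps(manifest["params"], indent=2, sort_keys=True)
    )


def _load_images(run_dir: Path) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    manifest = pd.read_csv(run_dir / "manifest.csv")
    pixels = {
        rec.image_id: tifffile.imread(run_dir / "images" / f"{rec.image_id}.tif")
        for rec in manifest.itertuples()
    }
    return manifest, pixels


def run_preprocess(config: RunConfig, run_dir: Path) -> None:
    manifest, pixels = _load_images(run_dir)
    mask_dir = run_dir / "masks"
    prep_dir = run_dir / "preprocessed"
    mask_dir.mkdir(exist_ok=True)
    prep_dir.mkdir(exist_ok=True)
    for rec in manifest.itertuples():
        img = synthetic.CohortImage(
            image_id=rec.image_id,
            pixels=pixels[rec.image_id],
            laterality=rec.laterality,
            category=rec.category,
            latent_gist=rec.latent_gist,
        )
        img = preprocessing.standardize_laterality(img)
        mask = preprocessing.threshold_mask(
            img.pixels, config.threshold, image_id=img.image_id
        )
        cropped, mask = preprocessing.crop_to_breast(img.pixels, mask)
        tifffile.imwrite(prep_dir / f"{img.image_id}.tif", cropped)
        _write_mask(mask_dir / f"{img.image_id}.tif", mask.mask)


def run_roi(config: RunConfig, run_dir: Path) -> None:
    roi_dir = run_dir / "rois"
    roi_dir.mkdir(exist_ok=True)
    for mask_path in sorted((run_dir / "masks").glob("*.tif")):
        mask = _read_mask(mask_path)
        radius = (
            config.erosion_radius
            if config.erosion_radius is not None
            else roi.scaled_radius(mask.shape[0])
        )
        roi_mask = roi.erode(mask, radius)
        _write_mask(roi_dir / mask_path.name, roi_mask.mask)


def run_extract(config: RunConfig, run_dir: Path) -> None:
    manifest = pd.read_csv(run_dir / "manifest.csv")
    rows = []
    for rec in manifest.itertuples():
        pixels = tifffile.imread(run_dir / "preprocessed" / f"{rec.image_id}.tif")
        roi_mask = _read_mask(run_dir / "rois" / f"{rec.image_id}.tif")
        feats = extract_features(pixels, roi_mask, config.features, image_id=rec.image_id)
        row = {"image_id": rec.image_id, "category": rec.category}
        row.update(feats.to_dict())
        rows.append(row)
    pd.DataFrame(rows).to_csv(run_dir / "features.csv", index=False)


def run_label(config: RunConfig, run_dir: Path) -> None:
    manifest = pd.read_csv(run_dir / "manifest.csv")
    panels = pd.read_csv(run_dir / "panels.csv")
    obs_cols = [c for c in panels.columns if c.startswith("observer_")]
    means = pd.Series(
        panels[obs_cols].mean(axis=1).to_numpy(), index=panels["image_id"]
    )
    labels = labeling.quartile_split(means)
    out = pd.DataFrame(
        {
            "image_id": panels["image_id"],
            "category": manifest.set_index("image_id")["category"]
            .reindex(panels["image_id"])
            .to_numpy(),
            "mean_score": means.to_numpy(),
            "label": labels.to_numpy(),
        }
    )
    out.to_csv(run_dir / "labels.csv", index=False)


def run_train(config: RunConfig, run_dir: Path) -> dict[str, dict]:
    features = pd.read_csv(run_dir / "features.csv").set_index("image_id")
    feature_cols = [c for c in features.columns if c != "category"]
    samples = pd.read_csv(run_dir / "labels.csv")
    datasets = labeling.build_category_datasets(samples, features[feature_cols])
    model_dir = run_dir / "models"
    model_dir.mkdir(exist_ok=True)
    model_cfg = dataclasses.replace(
        config.model, seed=stage_seed(config.seed, "train")
    )
    reports: dict[str, dict] = {}
    for name, (X, y) in datasets.items():
        counts = y.value_counts()
        if len(counts) < 2 or counts.min() < model_cfg.k_folds:
            logger.warning("skipping %s: insufficient data (%s)", name, counts.to_dict())
            reports[name] = {
                "category": name,
                "skipped": "insufficient data",
                "class_counts": counts.to_dict(),
            }
        else:
            report = classify.cross_validate(X, y, model_cfg, category=name)
            reports[name] = report.to_dict()
        (model_dir / f"{name}.json").write_text(
            json.dumps(reports[name], indent=2, sort_keys=True)
        )
    # combined importance table: rows = features, columns = models
    imp = {
        name: rep["importance"]
        for name, rep in reports.items()
        if "importance" in rep
    }
    if imp:
        pd.DataFrame(imp).rename_axis("feature").to_csv(run_dir / "importances.csv")
    return reports


def run_scree(config: RunConfig, run_dir: Path) -> None:
    path = run_dir / "importances.csv"
    if not path.exists():
        logger.warning("no importances.csv; scree stage skipped")
        return
    imp = pd.read_csv(path, index_col="feature")
    scree_dir = run_dir / "scree"
    scree_dir.mkdir(exist_ok=True)
    selections = {}
    for model in imp.columns:
        sel = scree.scree_select(imp[model])
        selections[model] = sel
        (scree_dir / f"{model}_selection.json").write_text(
            json.dumps(
                {
                    "model": model,
                    "cut_index": sel.cut_index,
                    "selected": list(sel.selected),
                    "families": sorted(sel.families),
                },
                indent=2,
            )
        )
    scree.cross_model_summary(selections).to_csv(
        scree_dir / "family_summary.csv", index=False
    )


def cohort_features(
    images,
    threshold: float = preprocessing.DEFAULT_THRESHOLD,
    erosion_radius: int | None = None,
    feature_config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """In-memory preprocess -> ROI -> feature chain for a list of images.

    Returns the 130-column feature table indexed by image id. Convenience
    for analyses that do not need on-disk artifacts; the staged pipeline
    produces identical numbers.
    """
    feature_config = feature_config or FeatureConfig()
    rows = {}
    for img in images:
        img = preprocessing.standardize_laterality(img)
        mask = preprocessing.threshold_mask(img.pixels, threshold, image_id=img.image_id)
        pixels, mask = preprocessing.crop_to_breast(img.pixels, mask)
        radius = (
            erosion_radius
            if erosion_radius is not None
            else roi.scaled_radius(pixels.shape[0])
        )
        roi_mask = roi.erode(mask, radius)
        rows[img.image_id] = extract_features(
            pixels, roi_mask, feature_config, image_id=img.image_id
        )
    return pd.DataFrame(rows).T.rename_axis("image_id")


_STAGE_FUNCS = {
    "simulate": run_simulate,
    "preprocess": run_preprocess,
    "roi": run_roi,
    "extract": run_extract,
    "label": run_label,
    "train": run_train,
    "scree": run_scree,
}


def run_pipeline(config: RunConfig, run_dir: str | Path) -> Path:
    """Execute the configured stages into ``run_dir`` and stamp the config."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    echo = config.to_dict()
    echo["config_hash"] = config.config_hash()
    with open(run_dir / "config.yaml", "w") as f:
        yaml.safe_dump(echo, f, sort_keys=True)
    for stage in STAGES:
        if stage not in config.stages:
            continue
        logger.info("stage %s", stage)
        try:
            _STAGE_FUNCS[stage](config, run_dir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return run_dir


def report(run_dir: str | Path) -> dict:
    """Summarize a completed run: per-category AUC with CI, scree selections
    and the cross-model family table. Raises listing any missing artifact."""
    run_dir = Path(run_dir)
    missing = [
        name
        for name in ("models", "scree", "labels.csv", "features.csv")
        if not (run_dir / name).exists()
    ]
    if missing:
        raise FileNotFoundError(f"incomplete run {run_dir}: missing {missing}")
    summary: dict = {"run_dir": str(run_dir), "models": {}}
    for name in MODEL_CATEGORIES:
        path = run_dir / "models" / f"{name}.json"
        if not path.exists():
            continue
        rep = json.loads(path.read_text())
        if "skipped" in rep:
            summary["models"][name] = {"skipped": rep["skipped"]}
            continue
        entry = {"auc": rep["auc"], "auc_ci": rep["auc_ci"]}
        sel_path = run_dir / "scree" / f"{name}_selection.json"
        if sel_path.exists():
            sel = json.loads(sel_path.read_text())
            entry["n_selected"] = len(sel["selected"])
            entry["families"] = sel["families"]
        summary["models"][name] = entry
    fam_path = run_dir / "scree" / "family_summary.csv"
    if fam_path.exists():
        summary["family_summary"] = pd.read_csv(fam_path).to_dict("records")
    return summary


def format_report(summary: dict) -> str:
    lines = [f"run: {summary['run_dir']}", "", "category          AUC  (95% CI)        scree"]
    for name, entry in summary["models"].items():
        if "skipped" in entry:
            lines.append(f"{name:<16} skipped: {entry['skipped']}")
            continue
        lo, hi = entry["auc_ci"]
        sel = entry.get("n_selected", "-")
        lines.append(f"{name:<16} {entry['auc']:.3f} ({lo:.3f}-{hi:.3f})   {sel}")
    if "family_summary" in summary:
        lines.append("")
        lines.append("feature families selected across models:")
        for rec in summary["family_summary"]:
            lines.append(f"  {rec['family']:<26} {rec['n_models']} models")
    return "\n".join(lines)
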
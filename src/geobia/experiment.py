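"""End-to-end factorial experiment on a synthetic scene.

Six arms mirror the study design: the super-objects (7 classes) are
segmented and classified with and without the Gabor texture band, and
the sub-objects (13 classes) with and without the Gabor band crossed
with and without the hierarchy attribute (the classified super-object
class attached to each sub-object by majority overlap).

Per arm: derived features -> (optional Gabor PC1) -> intensity image ->
two-level watershed/full-lambda segmentation -> object statistics ->
majority-overlap label transfer -> random forest with OOB evaluation ->
rasterized classification -> PR against truth and landscape metrics.
Everything is deterministic under the configured seeds.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import json

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import (
    LandscapeMetricsReport,
    extract_patches,
    landscape_metrics,
    pr_metric,
)
from .features import compute_ndvi, intensity_image, to_grayscale
from .gabor import apply_bank, build_bank, normalize_stack, stack_pca
from .objects import (
    UNCLASSIFIED,
    attach_super_class,
    compute_object_stats,
    majority_overlap_label,
)
from .raster import Raster
from .rf import RFConfig, importance_report, predict, predict_oob, train_evaluate
from .scene import SyntheticScene, default_appearance, default_scheme, generate_scene
from .segmentation import SegmentMap, build_hierarchy

__all__ = [
    "SegParams",
    "ExperimentConfig",
    "ArmResult",
    "run_factorial",
    "report",
]


@dataclass(frozen=True)
class SegParams:
    """Watershed scale and the two merge levels of one condition."""

    scale: float
    merge_sub: float
    merge_super: float


@dataclass(frozen=True)
class ExperimentConfig:
    """All knobs of one factorial run; fully determines the outputs."""

    width: int = 192
    height: int = 192
    n_patches: int = 40
    scene_seed: int = 0
    rf_seed: int = 0
    n_trees: int = 250
    seg_with_gabor: SegParams = field(
        default_factory=lambda: SegParams(30.0, 80.0, 90.0)
    )
    seg_without_gabor: SegParams = field(
        default_factory=lambda: SegParams(30.0, 80.0, 90.0)
    )
    gabor_wavelengths: tuple[float, ...] | None = None
    gabor_orientations: tuple[float, ...] | None = None
    pca_components: int = 1
    connectivity: int = 8
    honest_hierarchy: bool = False


@dataclass
class ArmResult:
    """One row of the factorial comparison."""

    arm: str
    level: str  # "super" or "sub"
    gabor: bool
    hierarchy: bool | None
    oob_error: float
    pr: float
    metrics: LandscapeMetricsReport
    importance: dict[str, list[tuple[str, float]]]
    n_segments: int
    n_trained: int


def _classified_raster(
    segments: SegmentMap, predictions: np.ndarray
) -> Raster:
    """Paint each segment with its predicted class code."""
    lut = np.concatenate([[UNCLASSIFIED], predictions]).astype(np.int64)
    return Raster(lut[segments.labels], cell_size=segments.cell_size)


def _gabor_pc1(scene: SyntheticScene, config: ExperimentConfig) -> Raster:
    gray = to_grayscale(scene.image)
    kwargs = {}
    if config.gabor_wavelengths is not None:
        kwargs["wavelengths"] = config.gabor_wavelengths
    if config.gabor_orientations is not None:
        kwargs["orientations_deg"] = config.gabor_orientations
    bank = build_bank(**kwargs)
    stack = normalize_stack(apply_bank(gray, bank))
    return stack_pca(stack, k=config.pca_components)[0]


def run_factorial(
    config: ExperimentConfig, scene: SyntheticScene | None = None
) -> list[ArmResult]:
    """Run all six arms; see the module docstring for the pipeline."""
    if scene is None:
        scene = generate_scene(
            default_scheme(),
            default_appearance(),
            width=config.width,
            height=config.height,
            n_patches=config.n_patches,
            seed=config.scene_seed,
        )
    ndvi = compute_ndvi(scene.image.nir, scene.image.red)
    chm = scene.chm
    rf_cfg = RFConfig(n_trees=config.n_trees, seed=config.rf_seed)
    results: list[ArmResult] = []

    for use_gabor in (False, True):
        seg = config.seg_with_gabor if use_gabor else config.seg_without_gabor
        merge_layers = [ndvi, chm]
        feature_layers = {
            "nir": scene.image.nir,
            "red": scene.image.red,
            "green": scene.image.green,
            "ndvi": ndvi,
            "chm": chm,
        }
        if use_gabor:
            pc1 = _gabor_pc1(scene, config)
            merge_layers = merge_layers + [pc1]
            feature_layers = {**feature_layers, "gabor_pc1": pc1}

        intensity = intensity_image(merge_layers, normalize=True)
        norm_layers = [
            intensity_image([l], normalize=True) for l in merge_layers
        ]
        sub_map, super_map = build_hierarchy(
            intensity,
            norm_layers,
            scale=seg.scale,
            merge_sub=seg.merge_sub,
            merge_super=seg.merge_super,
        )
        tag = "+G" if use_gabor else "-G"

        # ---- super-object arm -------------------------------------------
        super_table = compute_object_stats(super_map, feature_layers)
        super_labels = majority_overlap_label(super_map, scene.truth_super)
        trained = super_labels != UNCLASSIFIED
        super_rf = train_evaluate(
            super_table[trained.values], super_labels[trained], rf_cfg
        )
        if config.honest_hierarchy:
            super_pred_trained = predict_oob(super_rf)
            super_pred = np.full(super_map.n_segments, UNCLASSIFIED, np.int64)
            super_pred[trained.values] = super_pred_trained
        else:
            super_pred = predict(super_rf, super_table)
        classified_super = _classified_raster(super_map, super_pred)
        results.append(
            ArmResult(
                arm=f"super{tag}",
                level="super",
                gabor=use_gabor,
                hierarchy=None,
                oob_error=super_rf.oob_error,
                pr=pr_metric(classified_super, scene.truth_super),
                metrics=landscape_metrics(
                    extract_patches(classified_super, config.connectivity)
                ),
                importance=importance_report(super_rf, top_k=5),
                n_segments=super_map.n_segments,
                n_trained=int(trained.sum()),
            )
        )

        # ---- sub-object arms --------------------------------------------
        sub_table_base = compute_object_stats(sub_map, feature_layers)
        sub_labels = majority_overlap_label(sub_map, scene.truth_sub)
        sub_trained = sub_labels != UNCLASSIFIED
        for use_hier in (False, True):
            if use_hier:
                table = attach_super_class(
                    sub_map,
                    classified_super,
                    sub_table_base,
                    n_super_classes=len(scene.scheme.super_classes),
                )
            else:
                table = sub_table_base
            sub_rf = train_evaluate(
                table[sub_trained.values], sub_labels[sub_trained], rf_cfg
            )
            sub_pred = predict(sub_rf, table)
            classified_sub = _classified_raster(sub_map, sub_pred)
            results.append(
                ArmResult(
                    arm=f"sub{tag}{'+H' if use_hier else '-H'}",
                    level="sub",
                    gabor=use_gabor,
                    hierarchy=use_hier,
                    oob_error=sub_rf.oob_error,
                    pr=pr_metric(classified_sub, scene.truth_sub),
                    metrics=landscape_metrics(
                        extract_patches(classified_sub, config.connectivity)
                    ),
                    importance=importance_report(sub_rf, top_k=5),
                    n_segments=sub_map.n_segments,
                    n_trained=int(sub_trained.sum()),
                )
            )
    return results


def report(
    results: list[ArmResult],
    out: str | Path,
    config: ExperimentConfig | None = None,
) -> dict[str, Path]:
    """Write the three comparison tables and a run manifest.

    ``table_super.csv`` and ``table_sub.csv`` hold OOB error and PR per
    arm; ``table_metrics.csv`` holds the seven landscape-metric columns
    (NP, AREA_AM, AREA_SD, FRAC_AM, FRAC_SD, PARA_AM, PARA_SD) per arm.
    """
    if not results:
        raise ValueError("no arm results to report")
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)

    def rows(level: str) -> pd.DataFrame:
        recs = [
            {
                "arm": r.arm,
                "oob_error_pct": 100.0 * r.oob_error,
                "pr_pct": r.pr,
                "n_segments": r.n_segments,
            }
            for r in results
            if r.level == level
        ]
        return pd.DataFrame(recs)

    paths = {}
    paths["table_super"] = out / "table_super.csv"
    rows("super").to_csv(paths["table_super"], index=False)
    paths["table_sub"] = out / "table_sub.csv"
    rows("sub").to_csv(paths["table_sub"], index=False)

    metric_rows = pd.DataFrame(
        [{"arm": r.arm, **r.metrics.as_dict()} for r in results]
    ).set_index("arm")
    paths["table_metrics"] = out / "table_metrics.csv"
    metric_rows.to_csv(paths["table_metrics"])

    manifest = {
        "package_version": __version__,
        "config": asdict(config) if config is not None else None,
        "arms": [
            {
                "arm": r.arm,
                "oob_error": r.oob_error,
                "pr": r.pr,
                "n_segments": r.n_segments,
                "n_trained": r.n_trained,
                "metrics": r.metrics.as_dict(),
                "importance": r.importance,
            }
            for r in results
        ],
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
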
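"""End-to-end orchestration: cascade -> segmentation -> morphometry.

A :class:`PipelineConfig` captures every tunable of a run and round-trips
losslessly through YAML, so the JSON run manifest (config + seeds + counts)
is sufficient to reproduce a run exactly. Outputs are written
deterministically (patches sorted by global offset, fixed CSV column
order), so two runs on the same slide and config produce byte-identical
metric tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cascade_detection import CascadeConfig, get_detector_factory, run_cascade
from .nuclei_counting import NucleiParams, count_nuclei
from .segmentation import get_segmenter_factory, postprocess_masks, segment_patch
from .svat_morphometrics import CalibrationScale, compute_sv_metrics, to_micrometers
from .wsi_geometry import (
    PatchRecord,
    SlideImage,
    patch_filename,
    read_slide,
    write_mask_png,
    write_png,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "METRIC_COLUMNS", "METRICS_SCHEMA_VERSION"]

METRICS_SCHEMA_VERSION = 1

#: fixed, versioned column order of the metrics CSV (pixel units); the µm
#: columns are appended only when a calibration is supplied
METRIC_COLUMNS = [
    "patch_ref",
    "slide_id",
    "global_row",
    "global_col",
    "score",
    "sv_area",
    "w1_min_feret",
    "w2_midline",
    "w3_average",
    "bbox_height_h",
    "cap_count",
    "cap_total_area",
    "cap_mean_area",
    "nuclei_count",
    "units",
]

UM_COLUMNS = [
    "sv_area_um2",
    "w1_min_feret_um",
    "w2_midline_um",
    "w3_average_um",
    "bbox_height_h_um",
    "cap_total_area_um2",
    "cap_mean_area_um2",
    "px_per_um",
]


@dataclasses.dataclass
class PipelineConfig:
    """Everything a run needs; serializable to/from a single YAML mapping."""

    cascade: CascadeConfig = dataclasses.field(default_factory=CascadeConfig)
    detector: str = "baseline"
    detector_params_cochlea: dict = dataclasses.field(default_factory=dict)
    detector_params_sv: dict = dataclasses.field(default_factory=dict)
    segmenter: str = "baseline"
    segmenter_params: dict = dataclasses.field(default_factory=dict)
    nuclei_k: int = 3
    nuclei_seed: int = 0
    nuclei_area_bounds: tuple[float, float] = (10.0, 200.0)
    min_cap_area: float = 5.0
    px_per_um: float | None = None
    keep_largest_sv: bool = True
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["nuclei_area_bounds"] = list(self.nuclei_area_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cascade" in d and isinstance(d["cascade"], dict):
            d["cascade"] = CascadeConfig(**d["cascade"])
        if "nuclei_area_bounds" in d:
            d["nuclei_area_bounds"] = tuple(d["nuclei_area_bounds"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _build_metric_row(patch: PatchRecord, metrics, cal: CalibrationScale | None) -> dict:
    row = {
        "patch_ref": patch.identity,
        "slide_id": patch.source_slide_id,
        "global_row": patch.global_offset[0],
        "global_col": patch.global_offset[1],
        "score": patch.score if patch.score is not None else "",
    }
    for name in (
        "sv_area",
        "w1_min_feret",
        "w2_midline",
        "w3_average",
        "bbox_height_h",
        "cap_count",
        "cap_total_area",
        "cap_mean_area",
        "nuclei_count",
        "units",
    ):
        row[name] = getattr(metrics, name)
    if cal is not None:
        um = to_micrometers(metrics, cal)
        row.update(
            {
                "sv_area_um2": um.sv_area,
                "w1_min_feret_um": um.w1_min_feret,
                "w2_midline_um": um.w2_midline,
                "w3_average_um": um.w3_average,
                "bbox_height_h_um": um.bbox_height_h,
                "cap_total_area_um2": um.cap_total_area,
                "cap_mean_area_um2": um.cap_mean_area,
                "px_per_um": cal.px_per_um,
            }
        )
    return row


def run_pipeline(
    slide_path: str | Path | SlideImage,
    cfg: PipelineConfig,
    out_dir: str | Path,
    cochlea_detector=None,
    sv_detector=None,
    segmenter=None,
) -> pd.DataFrame:
    """Run cascade -> segmentation -> SVAT on one slide and write artifacts.

    ``cochlea_detector`` / ``sv_detector`` / ``segmenter`` override the named
    plug-ins from the config (used for oracle plug-ins in validation).
    Writes patches and masks as PNG, the metrics CSV, and a JSON run
    manifest; returns the metrics table. A blank slide yields an empty CSV
    and a manifest recording zero detections (success, not an error).
    """
    t0 = time.perf_counter()
    if isinstance(slide_path, SlideImage):
        slide = slide_path
        slide_name = slide.slide_id
    else:
        slide = read_slide(slide_path)
        slide_name = Path(slide_path).name
    out_dir = Path(out_dir)

    if cochlea_detector is None:
        factory = get_detector_factory(cfg.detector)
        cochlea_detector = factory(class_label="cochlea", **cfg.detector_params_cochlea)
    if sv_detector is None:
        factory = get_detector_factory(cfg.detector)
        sv_detector = factory(class_label="SV", **cfg.detector_params_sv)
    if segmenter is None:
        segmenter = get_segmenter_factory(cfg.segmenter)(**cfg.segmenter_params)
    cal = CalibrationScale(cfg.px_per_um, "config") if cfg.px_per_um else None

    out_dir.mkdir(parents=True, exist_ok=True)
    patches_dir = out_dir / "patches"
    masks_dir = out_dir / "masks"
    patches_dir.mkdir(exist_ok=True)
    masks_dir.mkdir(exist_ok=True)

    patches = run_cascade(slide, cochlea_detector, sv_detector, cfg.cascade)
    patches.sort(key=lambda p: p.global_offset)

    rows = []
    nuclei_params = NucleiParams(
        k=cfg.nuclei_k, seed=cfg.nuclei_seed, area_bounds=cfg.nuclei_area_bounds
    )
    for patch in patches:
        ms = segment_patch(patch, segmenter)
        ms = postprocess_masks(ms, keep_largest_sv=cfg.keep_largest_sv, min_cap_area=cfg.min_cap_area)
        if ms.sv_mask.any():
            nuclei = count_nuclei(patch.pixels, ms.sv_mask, nuclei_params)
            n_count = nuclei.nuclei_count
        else:
            n_count = 0.0
        metrics = compute_sv_metrics(
            ms.sv_mask,
            ms.cap_mask,
            nuclei_count=n_count,
            min_cap_area=cfg.min_cap_area,
            patch_ref=patch.identity,
        )
        rows.append(_build_metric_row(patch, metrics, cal))

        name = patch_filename(patch)
        write_png(patches_dir / name, patch.pixels)
        stem = name.removesuffix(".png")
        write_mask_png(masks_dir / f"{stem}_sv.png", ms.sv_mask)
        write_mask_png(masks_dir / f"{stem}_cap.png", ms.cap_mask)

    columns = METRIC_COLUMNS + (UM_COLUMNS if cal is not None else [])
    table = pd.DataFrame(rows, columns=columns)
    csv_path = out_dir / "metrics.csv"
    table.to_csv(csv_path, index=False)

    manifest = {
        "schema_version": METRICS_SCHEMA_VERSION,
        "svpath_version": __version__,
        "slide": slide_name,
        "slide_id": slide.slide_id,
        "config": cfg.to_dict(),
        "config_digest": cfg.digest(),
        "n_patches": len(patches),
        "seeds": {"nuclei": cfg.nuclei_seed},
        "runtime_s": round(time.perf_counter() - t0, 3),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info(
        "pipeline on %s: %d patches, %.1f s", slide.slide_id, len(patches), manifest["runtime_s"]
    )
    return table
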
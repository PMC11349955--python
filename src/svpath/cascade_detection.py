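"""Two-stage detection cascade: cochlea on the compressed slide, then the
stria vascularis (SV) on a compressed full-resolution region around the
cochlea, emitting 512 x 512 SV patches with exact global coordinates.

The cascade is detector-agnostic: anything satisfying
:class:`DetectorContract` (a trained object detector, a classical blob
detector, or a ground-truth oracle in tests) can fill either stage. Patches
are always cropped from the full-resolution raster — detection happens on
compressed copies, pixel extraction never does.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable, Sequence

import numpy as np
from skimage import measure

from .wsi_geometry import (
    BBox,
    PatchRecord,
    SlideImage,
    extract_centered_region,
    extract_patch,
    map_box,
    pad_to_square,
    resize_to,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DetectorContract",
    "CascadeConfig",
    "run_cascade",
    "baseline_blob_detector",
    "oracle_detector",
    "register_detector",
    "get_detector_factory",
]


@dataclasses.dataclass
class DetectorContract:
    """A named detector stage.

    ``detect`` receives a :class:`SlideImage` (the compressed frame the stage
    operates on) and returns scored boxes in that frame. Boxes below
    ``min_score`` are discarded by the contract wrapper, never emitted.
    """

    detect: Callable[[SlideImage], list[BBox]]
    class_label: str
    min_score: float = 0.25

    def __call__(self, frame: SlideImage) -> list[BBox]:
        boxes = []
        for box in self.detect(frame):
            if not isinstance(box, BBox):
                raise TypeError(f"detector returned {type(box).__name__}, expected BBox")
            if not box.within(frame.shape):
                raise ValueError(
                    f"detector box {box} lies outside raster {frame.shape}"
                )
            score = 1.0 if box.score is None else box.score
            if score >= self.min_score:
                boxes.append(box)
        boxes.sort(key=lambda b: (-(b.score if b.score is not None else 1.0), b.row_min, b.col_min))
        return boxes


@dataclasses.dataclass
class CascadeConfig:
    """Side lengths of every stage of the cascade, in pixels.

    Defaults match the full-scale flow (18,000 px square slide compressed to
    2,048 px; 9,000 px cochlea region; 512 px SV patches); tests scale all
    sides down proportionally.
    """

    square_side: int = 18_000
    compressed_side: int = 2_048
    region_side: int = 9_000
    patch_side: int = 512
    min_score_cochlea: float = 0.25
    min_score_sv: float = 0.25

    def __post_init__(self) -> None:
        if not self.compressed_side < self.square_side:
            raise ValueError("compressed_side must be smaller than square_side")
        if not self.patch_side < self.region_side:
            raise ValueError("patch_side must be smaller than region_side")


def run_cascade(
    slide: SlideImage,
    cochlea_detector: DetectorContract,
    sv_detector: DetectorContract,
    cfg: CascadeConfig,
) -> list[PatchRecord]:
    """Run the full two-stage cascade on one slide.

    Returns one :class:`PatchRecord` per detected SV, centered on the
    detected box center, cropped from the full-resolution raster. Zero
    cochlea detections yield an empty list (logged, not an error). When the
    first stage fires more than once, the highest-scoring cochlea box is
    used — slides contain one cochlea.
    """
    square = slide
    if not slide.is_square or slide.shape[0] != cfg.square_side:
        square = pad_to_square(slide, max(cfg.square_side, *slide.shape))
    compressed = resize_to(square, cfg.compressed_side)

    cochlea_detector = dataclasses.replace(cochlea_detector, min_score=cfg.min_score_cochlea)
    sv_detector = dataclasses.replace(sv_detector, min_score=cfg.min_score_sv)

    cochlea_boxes = cochlea_detector(compressed)
    if not cochlea_boxes:
        logger.info("no cochlea detected on slide %s; emitting no patches", slide.slide_id)
        return []
    if len(cochlea_boxes) > 1:
        logger.info(
            "slide %s: %d cochlea detections, keeping highest score",
            slide.slide_id,
            len(cochlea_boxes),
        )
    cochlea_full = map_box(cochlea_boxes[0], compressed, to_full=True)

    region = extract_centered_region(square, cochlea_full.center, cfg.region_side)
    region_compressed = resize_to(region, cfg.compressed_side)

    patches: list[PatchRecord] = []
    for sv_box in sv_detector(region_compressed):
        sv_full = map_box(sv_box, region_compressed, to_full=True)
        patch = extract_patch(
            square,
            sv_full.center,
            cfg.patch_side,
            structure_label="SV",
            score=sv_box.score,
        )
        patches.append(patch)
    logger.info("slide %s: %d SV patches emitted", slide.slide_id, len(patches))
    return patches


def baseline_blob_detector(
    class_label: str,
    intensity_threshold: float = 128.0,
    area_range: tuple[float, float] = (100.0, 1e9),
    min_score: float = 0.25,
) -> DetectorContract:
    """Classical stand-in detector: grayscale threshold, connected components,
    area filter. Score is ``min(1, area / area_max)``.

    Pixels darker than ``intensity_threshold`` (mean of RGB) are foreground;
    tissue is darker than the blank white slide background.
    """
    area_min, area_max = area_range
    if not area_min < area_max:
        raise ValueError(f"empty area range ({area_min}, {area_max})")

    def detect(frame: SlideImage) -> list[BBox]:
        gray = frame.pixels.mean(axis=2)
        fg = gray < intensity_threshold
        labels = measure.label(fg, connectivity=2)
        boxes = []
        for props in measure.regionprops(labels):
            if not (area_min <= props.area <= area_max):
                continue
            r0, c0, r1, c1 = props.bbox
            score = min(1.0, props.area / area_max)
            boxes.append(BBox(r0, c0, r1, c1, frame_id=frame.frame_id, score=score))
        return boxes

    return DetectorContract(detect=detect, class_label=class_label, min_score=min_score)


def oracle_detector(
    truth_boxes: Sequence[BBox],
    class_label: str,
) -> DetectorContract:
    """Detector that reads planted ground truth (full-resolution boxes) and
    reports them in whatever frame it is shown. Used to exercise the cascade
    geometry independently of any detection model."""

    def detect(frame: SlideImage) -> list[BBox]:
        out = []
        for box in truth_boxes:
            if box.frame_id != "full":
                raise ValueError("oracle truth boxes must be in the full-resolution frame")
            mapped = map_box(box, frame, to_full=False)
            out.append(dataclasses.replace(mapped, score=1.0))
        return out

    return DetectorContract(detect=detect, class_label=class_label, min_score=0.0)


_DETECTOR_FACTORIES: dict[str, Callable[..., DetectorContract]] = {
    "baseline": baseline_blob_detector,
}


def register_detector(name: str, factory: Callable[..., DetectorContract]) -> None:
    """Register a detector factory so it can be selected by name in configs."""
    _DETECTOR_FACTORIES[name] = factory


def get_detector_factory(name: str) -> Callable[..., DetectorContract]:
    try:
        return _DETECTOR_FACTORIES[name]
    except KeyError:
        raise KeyError(
            f"unknown detector {name!r}; registered: {sorted(_DETECTOR_FACTORIES)}"
        ) from None
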
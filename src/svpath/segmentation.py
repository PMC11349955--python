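"""Per-patch binary segmentation of the stria vascularis and its capillary
bed, behind a segmenter-agnostic contract.

A segmenter is any callable ``(RGB raster) -> (sv_mask, cap_mask)`` with the
patch's shape; a trained semantic-segmentation network can be registered by
name, and a classical color-threshold baseline is provided so the pipeline
runs end to end without weights.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable

import numpy as np
from scipy import ndimage
from skimage import color, measure, morphology

from .wsi_geometry import PatchRecord

logger = logging.getLogger(__name__)

__all__ = [
    "MaskSet",
    "segment_patch",
    "baseline_color_segmenter",
    "postprocess_masks",
    "register_segmenter",
    "get_segmenter_factory",
]


@dataclasses.dataclass
class MaskSet:
    """Paired binary masks {SV, capillary} for one patch.

    Capillary pixels outside the SV mask are tolerated (a warning is logged);
    anatomically the lumen network lies within the SV, but segmenters are not
    forced to agree.
    """

    sv_mask: np.ndarray
    cap_mask: np.ndarray
    patch_ref: str = ""

    def __post_init__(self) -> None:
        self.sv_mask = np.asarray(self.sv_mask).astype(bool)
        self.cap_mask = np.asarray(self.cap_mask).astype(bool)
        if self.sv_mask.shape != self.cap_mask.shape:
            raise ValueError(
                f"mask shapes differ: {self.sv_mask.shape} vs {self.cap_mask.shape}"
            )
        if self.sv_mask.ndim != 2:
            raise ValueError("masks must be 2-D binary rasters")
        outside = self.cap_mask & ~self.sv_mask
        if outside.any():
            logger.warning(
                "%d capillary pixels lie outside the SV mask (%s)",
                int(outside.sum()),
                self.patch_ref or "unnamed patch",
            )


def segment_patch(patch: PatchRecord, segmenter: Callable[[np.ndarray], tuple]) -> MaskSet:
    """Apply a segmenter to one patch and wrap the result in a MaskSet.

    Empty masks are legal output; a shape mismatch from the segmenter is a
    contract violation and is rejected. A segmenter with a truthy
    ``wants_patch`` attribute receives the full :class:`PatchRecord` (with
    its global offset) instead of the bare raster — the hook oracle
    segmenters use to look up planted truth.
    """
    if getattr(segmenter, "wants_patch", False):
        sv_mask, cap_mask = segmenter(patch)
    else:
        sv_mask, cap_mask = segmenter(patch.pixels)
    sv_mask = np.asarray(sv_mask)
    cap_mask = np.asarray(cap_mask)
    expected = patch.pixels.shape[:2]
    for name, m in (("sv", sv_mask), ("cap", cap_mask)):
        if m.shape != expected:
            raise ValueError(
                f"segmenter returned {name} mask of shape {m.shape}, patch is {expected}"
            )
    return MaskSet(sv_mask=sv_mask, cap_mask=cap_mask, patch_ref=patch.identity)


def baseline_color_segmenter(
    tissue_sat_min: float = 0.12,
    tissue_val_min: float = 0.15,
    lumen_val_min: float = 0.82,
    lumen_sat_max: float = 0.25,
    min_cap_area: float = 5.0,
    close_radius: int = 2,
) -> Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Classical H&E color-threshold segmenter.

    Eosin-stained tissue is saturated pink against a near-white background,
    so the SV is taken as the largest connected component of the saturated
    region (closed and hole-filled, which pulls the pale capillary lumina
    into the SV body). Capillary lumina are the bright, weakly saturated
    components enclosed by the SV mask, area-filtered.
    """

    def segment(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        hsv = color.rgb2hsv(pixels)
        sat, val = hsv[..., 1], hsv[..., 2]
        tissue = (sat >= tissue_sat_min) & (val >= tissue_val_min)
        # dark hematoxylin nuclei can fall below tissue_val_min; they are
        # interior to the band and recovered by hole filling
        tissue = tissue | (val < tissue_val_min)
        if close_radius > 0:
            tissue = ndimage.binary_closing(tissue, structure=morphology.disk(close_radius))
        tissue = ndimage.binary_fill_holes(tissue)
        sv_mask = _largest_component(tissue)

        bright = (val >= lumen_val_min) & (sat <= lumen_sat_max) & sv_mask
        labels = measure.label(bright, connectivity=2)
        cap_mask = np.zeros_like(sv_mask)
        for props in measure.regionprops(labels):
            if props.area >= min_cap_area:
                cap_mask[labels == props.label] = True
        return sv_mask, cap_mask

    return segment


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return np.zeros_like(mask, dtype=bool)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def postprocess_masks(ms: MaskSet, keep_largest_sv: bool = True, min_cap_area: float = 5.0) -> MaskSet:
    """Reduce the SV mask to its largest 8-connected component and drop
    capillary components smaller than ``min_cap_area``. Never adds pixels."""
    sv = ms.sv_mask
    if keep_largest_sv and sv.any():
        sv = _largest_component(sv)
    cap = ms.cap_mask
    if min_cap_area > 0 and cap.any():
        labels = measure.label(cap, connectivity=2)
        keep = np.zeros_like(cap)
        for props in measure.regionprops(labels):
            if props.area >= min_cap_area:
                keep[labels == props.label] = True
        cap = keep
    return MaskSet(sv_mask=sv, cap_mask=cap, patch_ref=ms.patch_ref)


_SEGMENTER_FACTORIES: dict[str, Callable[..., Callable]] = {
    "baseline": baseline_color_segmenter,
}


def register_segmenter(name: str, factory: Callable[..., Callable]) -> None:
    _SEGMENTER_FACTORIES[name] = factory


def get_segmenter_factory(name: str) -> Callable[..., Callable]:
    try:
        return _SEGMENTER_FACTORIES[name]
    except KeyError:
        raise KeyError(
            f"unknown segmenter {name!r}; registered: {sorted(_SEGMENTER_FACTORIES)}"
        ) from None
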
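"""Coordinate algebra and raster standardization for whole-slide images.

Whole temporal-bone slides are large flat TIFFs (order 13,000 x 16,000 px).
The detection cascade never runs on the full raster directly: slides are
padded to a square, downscaled, detected on, and detections are mapped back
to the full-resolution frame. This module owns that bookkeeping.

Conventions, enforced everywhere:

* coordinates are 0-based, (row, col) order;
* boxes are half-open: ``row_max``/``col_max`` are one past the last pixel;
* every raster lives in a named *frame*; a frame knows how to reach the
  full-resolution frame (multiply by ``scale_to_full``, then translate by
  ``global_offset``).
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from PIL import Image

FULL_FRAME = "full"

__all__ = [
    "FULL_FRAME",
    "SlideImage",
    "BBox",
    "PatchRecord",
    "pad_to_square",
    "resize_to",
    "map_box",
    "extract_centered_region",
    "extract_patch",
    "read_slide",
    "write_png",
    "read_mask_png",
    "write_mask_png",
    "patch_filename",
    "parse_patch_filename",
]


@dataclasses.dataclass
class SlideImage:
    """An RGB raster plus its provenance within the full-resolution frame.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 raster.
    frame_id
        Symbolic name of the coordinate frame of ``pixels``.
    orig_shape
        ``(H0, W0)`` of the raster before padding (meaningful for the padded
        full-resolution frame; equals ``pixels.shape[:2]`` otherwise).
    pad_offset
        ``(row, col)`` of the original image origin inside the padded raster.
        Padding is appended bottom/right only, so this is ``(0, 0)``.
    scale_to_full
        Multiply coordinates in this frame by this factor to obtain
        full-resolution distances. Exactly 1.0 for the full frame.
    global_offset
        ``(row, col)`` of this frame's origin in full-resolution coordinates.
    full_shape
        ``(H, W)`` of the full-resolution (padded) raster; used for clamping
        mapped coordinates.
    slide_id
        Identifier carried into patch provenance.
    """

    pixels: np.ndarray
    frame_id: str = FULL_FRAME
    orig_shape: tuple[int, int] | None = None
    pad_offset: tuple[int, int] = (0, 0)
    scale_to_full: float = 1.0
    global_offset: tuple[int, int] = (0, 0)
    full_shape: tuple[int, int] | None = None
    slide_id: str = "slide"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3), got {self.pixels.shape}")
        h, w = self.pixels.shape[:2]
        if h <= 0 or w <= 0:
            raise ValueError("pixel dimensions must be positive")
        if self.orig_shape is None:
            self.orig_shape = (h, w)
        if min(self.pad_offset) < 0:
            raise ValueError("pad_offset components must be >= 0")
        if self.scale_to_full <= 0:
            raise ValueError("scale_to_full must be positive")
        if self.full_shape is None:
            side_h = int(round(h * self.scale_to_full)) + self.global_offset[0]
            side_w = int(round(w * self.scale_to_full)) + self.global_offset[1]
            self.full_shape = (side_h, side_w)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def is_square(self) -> bool:
        h, w = self.shape
        return h == w


@dataclasses.dataclass(frozen=True)
class BBox:
    """Axis-aligned half-open box in a named frame, with an optional score."""

    row_min: int
    col_min: int
    row_max: int
    col_max: int
    frame_id: str = FULL_FRAME
    score: float | None = None

    def __post_init__(self) -> None:
        if not (self.row_min < self.row_max and self.col_min < self.col_max):
            raise ValueError(
                f"degenerate box rows [{self.row_min}, {self.row_max}) "
                f"cols [{self.col_min}, {self.col_max})"
            )
        if min(self.row_min, self.col_min) < 0:
            raise ValueError("box coordinates must be >= 0")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")

    @property
    def center(self) -> tuple[float, float]:
        return ((self.row_min + self.row_max) / 2.0, (self.col_min + self.col_max) / 2.0)

    @property
    def height(self) -> int:
        return self.row_max - self.row_min

    @property
    def width(self) -> int:
        return self.col_max - self.col_min

    @property
    def area(self) -> int:
        return self.height * self.width

    def within(self, shape: tuple[int, int]) -> bool:
        return self.row_max <= shape[0] and self.col_max <= shape[1]


@dataclasses.dataclass
class PatchRecord:
    """A square RGB patch with its offset in the full-resolution frame."""

    pixels: np.ndarray
    global_offset: tuple[int, int]
    source_slide_id: str
    structure_label: str = "SV"
    score: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        h, w = self.pixels.shape[:2]
        if h != w:
            raise ValueError(f"patch must be square, got {h} x {w}")

    @property
    def side(self) -> int:
        return self.pixels.shape[0]

    @property
    def identity(self) -> str:
        r, c = self.global_offset
        return f"{self.source_slide_id}_{self.structure_label}_r{r}_c{c}"


def pad_to_square(slide: SlideImage, target_side: int, fill: tuple[int, int, int] = (255, 255, 255)) -> SlideImage:
    """Pad a slide to ``target_side`` square with blank (white) borders.

    Pixels are appended on the bottom and right only, so the original origin
    is preserved and the pad offset stays (0, 0).
    """
    h, w = slide.shape
    if target_side < max(h, w):
        raise ValueError(
            f"target_side {target_side} is smaller than slide dimensions {h} x {w}"
        )
    out = np.empty((target_side, target_side, 3), dtype=np.uint8)
    out[:] = np.asarray(fill, dtype=np.uint8)
    out[:h, :w] = slide.pixels
    return SlideImage(
        pixels=out,
        frame_id=slide.frame_id,
        orig_shape=(h, w),
        pad_offset=(0, 0),
        scale_to_full=slide.scale_to_full,
        global_offset=slide.global_offset,
        full_shape=(target_side, target_side) if slide.frame_id == FULL_FRAME else slide.full_shape,
        slide_id=slide.slide_id,
    )


def resize_to(slide: SlideImage, out_side: int) -> SlideImage:
    """Resize a square slide to ``out_side``.

    Downscaling uses area averaging (anti-aliased box filter); upscaling uses
    bilinear interpolation. The returned frame's ``scale_to_full`` is the
    input's scale times ``side_in / out_side``.
    """
    if not slide.is_square:
        h, w = slide.shape
        raise ValueError(f"resize_to requires a square slide; got {h} x {w} (pad first)")
    side_in = slide.shape[0]
    if out_side <= 0:
        raise ValueError("out_side must be positive")
    if out_side == side_in:
        pixels = slide.pixels.copy()
    else:
        resample = Image.Resampling.BOX if out_side < side_in else Image.Resampling.BILINEAR
        img = Image.fromarray(slide.pixels)
        pixels = np.asarray(img.resize((out_side, out_side), resample=resample))
    return SlideImage(
        pixels=pixels,
        frame_id=f"{slide.frame_id}@{out_side}",
        orig_shape=(out_side, out_side),
        pad_offset=(0, 0),
        scale_to_full=slide.scale_to_full * (side_in / out_side),
        global_offset=slide.global_offset,
        full_shape=slide.full_shape,
        slide_id=slide.slide_id,
    )


def map_box(box: BBox, frame: SlideImage, to_full: bool = True) -> BBox:
    """Map a box between ``frame`` and the full-resolution frame.

    ``to_full=True``: the box lives in ``frame``; coordinates are multiplied
    by ``frame.scale_to_full``, translated by the frame's global offset,
    rounded to nearest integer and clamped to the full raster bounds.
    ``to_full=False`` applies the inverse (full -> frame).
    """
    if to_full:
        if box.frame_id != frame.frame_id:
            raise ValueError(
                f"box frame {box.frame_id!r} does not match source frame {frame.frame_id!r}"
            )
        s = frame.scale_to_full
        orow, ocol = frame.global_offset
        vals = [
            box.row_min * s + orow,
            box.col_min * s + ocol,
            box.row_max * s + orow,
            box.col_max * s + ocol,
        ]
        bound = frame.full_shape
        out_frame = FULL_FRAME
    else:
        if box.frame_id != FULL_FRAME:
            raise ValueError(
                f"box frame {box.frame_id!r} does not match source frame {FULL_FRAME!r}"
            )
        s = frame.scale_to_full
        orow, ocol = frame.global_offset
        vals = [
            (box.row_min - orow) / s,
            (box.col_min - ocol) / s,
            (box.row_max - orow) / s,
            (box.col_max - ocol) / s,
        ]
        bound = frame.shape
        out_frame = frame.frame_id
    r0, c0, r1, c1 = (int(round(v)) for v in vals)
    r0 = min(max(r0, 0), bound[0] - 1)
    c0 = min(max(c0, 0), bound[1] - 1)
    r1 = min(max(r1, r0 + 1), bound[0])
    c1 = min(max(c1, c0 + 1), bound[1])
    return BBox(r0, c0, r1, c1, frame_id=out_frame, score=box.score)


def _crop_window(center: tuple[float, float], side: int, shape: tuple[int, int]) -> tuple[int, int]:
    """Top-left corner of a ``side``-square window centered at ``center``,
    shifted (never shrunk) to stay inside ``shape``."""
    r0 = int(round(center[0])) - side // 2
    c0 = int(round(center[1])) - side // 2
    r0 = min(max(r0, 0), shape[0] - side)
    c0 = min(max(c0, 0), shape[1] - side)
    return r0, c0


def extract_centered_region(slide: SlideImage, center: tuple[float, float], side: int) -> SlideImage:
    """Crop an exact ``side x side`` region centered at ``center``.

    When the centered window would overrun an edge it is shifted to fit, so
    the output size is always exact and every pixel is real image data. The
    returned frame records its global offset in full-resolution coordinates.
    """
    h, w = slide.shape
    if side > min(h, w):
        raise ValueError(f"side {side} exceeds raster bounds {h} x {w}")
    if not (0 <= center[0] < h and 0 <= center[1] < w):
        raise ValueError(f"center {center} outside raster {h} x {w}")
    r0, c0 = _crop_window(center, side, (h, w))
    pixels = slide.pixels[r0 : r0 + side, c0 : c0 + side].copy()
    orow, ocol = slide.global_offset
    if slide.scale_to_full != 1.0:
        raise ValueError("extract_centered_region operates on full-resolution frames only")
    return SlideImage(
        pixels=pixels,
        frame_id=f"{slide.frame_id}+r{orow + r0}c{ocol + c0}",
        orig_shape=(side, side),
        pad_offset=(0, 0),
        scale_to_full=1.0,
        global_offset=(orow + r0, ocol + c0),
        full_shape=slide.full_shape,
        slide_id=slide.slide_id,
    )


def extract_patch(
    slide: SlideImage,
    center: tuple[float, float],
    side: int,
    structure_label: str = "SV",
    score: float | None = None,
) -> PatchRecord:
    """Extract a patch as a :class:`PatchRecord` with full-resolution offset."""
    region = extract_centered_region(slide, center, side)
    return PatchRecord(
        pixels=region.pixels,
        global_offset=region.global_offset,
        source_slide_id=slide.slide_id,
        structure_label=structure_label,
        score=score,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_slide(path: str | Path, slide_id: str | None = None) -> SlideImage:
    """Read a flat TIFF or PNG slide as an RGB :class:`SlideImage`.

    Multi-page TIFFs are tolerated; the first page is used. Grayscale input
    is broadcast to RGB; an alpha channel is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"slide not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            arr = tf.pages[0].asarray()
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return SlideImage(pixels=arr, slide_id=slide_id or path.stem)


def write_png(path: str | Path, pixels: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(pixels, dtype=np.uint8))


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG with values {0, 255}."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask_png(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def patch_filename(patch: PatchRecord) -> str:
    """``<slide_id>_<structure>_r<row>_c<col>.png`` with full-resolution offset."""
    return f"{patch.identity}.png"


_PATCH_RE = re.compile(r"^(?P<slide>.+)_(?P<structure>[^_]+)_r(?P<row>\d+)_c(?P<col>\d+)$")


def parse_patch_filename(name: str) -> dict:
    """Invert :func:`patch_filename` (stem or filename accepted)."""
    stem = Path(name).name
    for suffix in (".png", "_sv", "_cap", "_nuc"):
        stem = stem.removesuffix(suffix)
    m = _PATCH_RE.match(stem)
    if m is None:
        raise ValueError(f"not a patch filename: {name}")
    return {
        "slide_id": m.group("slide"),
        "structure_label": m.group("structure"),
        "global_offset": (int(m.group("row")), int(m.group("col"))),
    }
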
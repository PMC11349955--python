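"""Deterministic synthetic H&E-like fixtures with exact ground truth.

The generator emulates the appearance a temporal-bone patch presents to the
pipeline: an elongated eosin-pink band (the stria vascularis) of known
constant width on a near-white background, pale elliptical capillary lumina
inside the band, and dark hematoxylin-like nucleus disks. Every output
carries exact rasterized truth masks plus the analytic values they were
planted with, so detection geometry, segmentation, morphometry and counting
can all be validated without any slide data.

Geometry of the band: a quadratic Bezier centerline with a controlled bow
(sagitta) off its chord, swept with constant perpendicular width; the
resulting capsule has analytic area ``width * arc_length + pi (width/2)^2``.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.spatial import cKDTree

from .wsi_geometry import FULL_FRAME, BBox, SlideImage

__all__ = [
    "Palette",
    "FixtureSpec",
    "FixtureTruth",
    "make_sv_patch",
    "make_mini_wsi",
    "rasterize_disk",
    "rasterize_ellipse",
]


@dataclasses.dataclass(frozen=True)
class Palette:
    """Approximate H&E rendering colors (RGB, uint8). Configuration, not
    science: background near-white, tissue eosin-pink, lumen off-white,
    nuclei dark blue-purple."""

    background: tuple[int, int, int] = (246, 243, 246)
    tissue: tuple[int, int, int] = (228, 120, 165)
    lumen: tuple[int, int, int] = (242, 234, 238)
    nucleus: tuple[int, int, int] = (64, 44, 110)
    cochlea: tuple[int, int, int] = (130, 90, 140)


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic SV patch.

    ``band_curvature`` is the perpendicular bow (sagitta, px) of the
    centerline midpoint off the chord; the default keeps the band close
    enough to straight that the minimum Feret diameter tracks the planted
    width. ``noise_sd`` is per-channel Gaussian noise in 8-bit units.
    """

    patch_side: int = 512
    band_width: float = 40.0
    band_curvature: float = 1.0
    n_capillaries: int = 3
    capillary_radius_range: tuple[float, float] = (3.0, 6.0)
    n_nuclei: int = 40
    nucleus_radius: float = 4.0
    palette: Palette = Palette()
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.band_width < self.patch_side / 2:
            raise ValueError("band_width must be below patch_side / 2")
        if min(self.n_capillaries, self.n_nuclei) < 0:
            raise ValueError("counts must be >= 0")
        lo, hi = self.capillary_radius_range
        if not 0 < lo <= hi:
            raise ValueError("capillary_radius_range must be 0 < lo <= hi")


@dataclasses.dataclass
class FixtureTruth:
    """Exact rasterized masks plus the analytic values they were planted
    with (band capsule area, width, arc length, per-lumen areas, counts)."""

    sv_mask: np.ndarray
    cap_mask: np.ndarray
    nuclei_mask: np.ndarray
    analytic: dict


def rasterize_disk(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    """Pixel-center rasterization of a disk."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def rasterize_ellipse(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_major: float,
    semi_minor: float,
    angle: float,
) -> np.ndarray:
    """Pixel-center rasterization of a rotated ellipse; ``angle`` is the
    major-axis direction in radians measured in (row, col) space."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dr * math.cos(angle) + dc * math.sin(angle)
    v = -dr * math.sin(angle) + dc * math.cos(angle)
    return (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0


def _stamp_disk(mask: np.ndarray, center: tuple[float, float], radius: float) -> int:
    """OR a disk into ``mask`` computing only a local window; returns the
    disk's pixel count."""
    r0 = max(int(center[0] - radius) - 1, 0)
    r1 = min(int(center[0] + radius) + 2, mask.shape[0])
    c0 = max(int(center[1] - radius) - 1, 0)
    c1 = min(int(center[1] + radius) + 2, mask.shape[1])
    local = rasterize_disk((r1 - r0, c1 - c0), (center[0] - r0, center[1] - c0), radius)
    mask[r0:r1, c0:c1] |= local
    return int(local.sum())


def _stamp_ellipse(
    mask: np.ndarray,
    center: tuple[float, float],
    semi_major: float,
    semi_minor: float,
    angle: float,
) -> int:
    """OR a rotated ellipse into ``mask`` via a local window; returns its
    pixel count."""
    ext = semi_major + 1
    r0 = max(int(center[0] - ext) - 1, 0)
    r1 = min(int(center[0] + ext) + 2, mask.shape[0])
    c0 = max(int(center[1] - ext) - 1, 0)
    c1 = min(int(center[1] + ext) + 2, mask.shape[1])
    local = rasterize_ellipse(
        (r1 - r0, c1 - c0), (center[0] - r0, center[1] - c0), semi_major, semi_minor, angle
    )
    mask[r0:r1, c0:c1] |= local
    return int(local.sum())


def _bezier(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2


def _band_mask(shape: tuple[int, int], samples: np.ndarray, half_width: float) -> np.ndarray:
    """Pixels whose center lies within ``half_width`` of the sampled
    centerline (dense samples; KD-tree nearest distance)."""
    pad = int(math.ceil(half_width)) + 2
    r0 = max(int(samples[:, 0].min()) - pad, 0)
    r1 = min(int(samples[:, 0].max()) + pad + 1, shape[0])
    c0 = max(int(samples[:, 1].min()) - pad, 0)
    c1 = min(int(samples[:, 1].max()) + pad + 1, shape[1])
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    dist, _ = cKDTree(samples).query(pts, workers=1)
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = (dist <= half_width).reshape(rr.shape)
    return mask


def _arc_lengths(samples: np.ndarray) -> np.ndarray:
    seg = np.hypot(*(np.diff(samples, axis=0).T))
    return np.concatenate([[0.0], np.cumsum(seg)])


def make_sv_patch(spec: FixtureSpec) -> tuple[np.ndarray, FixtureTruth]:
    """Render one synthetic SV patch and its exact ground truth.

    The band is a constant-width capsule around a quadratic Bezier
    centerline; capillary lumina are disjoint ellipses centered on the
    centerline (major axis along the local tangent); nuclei are equal-radius
    disks at integer centers inside the band, avoiding the lumina and each
    other. Output is bit-reproducible from the spec (which includes the
    seed). Infeasible packing is rejected with the computed capacity.
    """
    rng = np.random.default_rng(spec.seed)
    side = spec.patch_side
    w = spec.band_width
    half = w / 2.0

    margin = side // 8
    cy = side / 2.0
    p0 = np.array([cy, float(margin)])
    p2 = np.array([cy, float(side - margin)])
    mid = (p0 + p2) / 2.0
    p1 = mid + np.array([-2.0 * spec.band_curvature, 0.0])
    n_samples = max(8 * side, 1024)
    samples = _bezier(p0, p1, p2, n_samples)
    arc = _arc_lengths(samples)
    arc_length = float(arc[-1])

    sv_mask = _band_mask((side, side), samples, half)
    analytic_band_area = w * arc_length + math.pi * half**2

    # --- capillary lumina: disjoint ellipses on the centerline ------------
    lo, hi = spec.capillary_radius_range
    b_cap = min(hi, half - 1.5)
    cap_mask = np.zeros((side, side), dtype=bool)
    cap_areas: list[int] = []
    cap_params: list[dict] = []
    if spec.n_capillaries > 0:
        if b_cap < 1.0:
            raise ValueError(
                f"band of width {w} cannot hold capillaries of radius >= {lo}"
            )
        majors = rng.uniform(lo, hi, size=spec.n_capillaries)
        minors = rng.uniform(min(lo, b_cap), b_cap, size=spec.n_capillaries)
        usable = arc_length * 0.7
        need = float(np.sum(2 * majors + 4))
        if need > usable:
            capacity = int(usable // (2 * hi + 4))
            raise ValueError(
                f"cannot pack {spec.n_capillaries} capillaries on the centerline; "
                f"capacity at this size is ~{capacity}"
            )
        # spread arc positions with gaps proportional to the required spans
        gaps = rng.uniform(0.0, 1.0, size=spec.n_capillaries + 1)
        gaps = gaps / gaps.sum() * (usable - need)
        pos = 0.15 * arc_length
        for i in range(spec.n_capillaries):
            pos += gaps[i] + majors[i] + 2
            idx = int(np.searchsorted(arc, pos))
            idx = min(idx, n_samples - 2)
            center = samples[idx]
            tangent = samples[idx + 1] - samples[idx]
            angle = math.atan2(tangent[1], tangent[0])
            ell = rasterize_ellipse((side, side), tuple(center), majors[i], minors[i], angle)
            cap_mask |= ell
            cap_areas.append(int(ell.sum()))
            cap_params.append(
                {"center": tuple(center), "a": float(majors[i]), "b": float(minors[i])}
            )
            pos += majors[i] + 2

    # --- nuclei: equal-radius disks at integer centers --------------------
    r_nuc = spec.nucleus_radius
    nuclei_mask = np.zeros((side, side), dtype=bool)
    nuclei_centers: list[tuple[int, int]] = []
    if spec.n_nuclei > 0:
        max_off = half - r_nuc - 1.0
        if max_off < 0:
            raise ValueError(f"nuclei of radius {r_nuc} do not fit in a band of width {w}")
        capacity = int(arc_length * 0.9 * (2 * max_off + 1) // (2 * r_nuc + 2) ** 2)
        if spec.n_nuclei > capacity:
            raise ValueError(
                f"cannot place {spec.n_nuclei} nuclei in the band; "
                f"estimated capacity is ~{capacity}"
            )
        attempts = 0
        max_attempts = 400 * spec.n_nuclei
        while len(nuclei_centers) < spec.n_nuclei:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    f"cannot place {spec.n_nuclei} nuclei in the band; "
                    f"estimated capacity is ~{capacity}"
                )
            pos = rng.uniform(0.05, 0.95) * arc_length
            idx = min(int(np.searchsorted(arc, pos)), n_samples - 2)
            base = samples[idx]
            tangent = samples[idx + 1] - samples[idx]
            tangent = tangent / np.hypot(*tangent)
            normal = np.array([-tangent[1], tangent[0]])
            off = rng.uniform(-max_off, max_off)
            center = np.rint(base + off * normal).astype(int)
            if not (0 <= center[0] < side and 0 <= center[1] < side):
                continue
            ok = all(
                (center[0] - c[0]) ** 2 + (center[1] - c[1]) ** 2 >= (2 * r_nuc + 2) ** 2
                for c in nuclei_centers
            )
            if ok:
                for cp in cap_params:
                    d = math.hypot(center[0] - cp["center"][0], center[1] - cp["center"][1])
                    if d < cp["a"] + r_nuc + 2:
                        ok = False
                        break
            if not ok:
                continue
            nuclei_centers.append((int(center[0]), int(center[1])))
        for c in nuclei_centers:
            nuclei_mask |= rasterize_disk((side, side), c, r_nuc)

    # --- render ------------------------------------------------------------
    pal = spec.palette
    patch = np.empty((side, side, 3), dtype=float)
    patch[:] = pal.background
    patch[sv_mask] = pal.tissue
    patch[cap_mask] = pal.lumen
    patch[nuclei_mask] = pal.nucleus
    if spec.noise_sd > 0:
        patch = patch + rng.normal(0.0, spec.noise_sd, size=patch.shape)
    patch = np.clip(np.rint(patch), 0, 255).astype(np.uint8)

    rows, cols = np.nonzero(sv_mask)
    analytic = {
        "band_width": w,
        "band_curvature": spec.band_curvature,
        "arc_length": arc_length,
        "band_area": analytic_band_area,
        "sv_bbox": (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1),
        "cap_count": len(cap_areas),
        "cap_areas": cap_areas,
        "cap_total_area": int(sum(cap_areas)),
        "cap_mean_area": (sum(cap_areas) / len(cap_areas)) if cap_areas else 0.0,
        "nuclei_count": len(nuclei_centers),
        "nuclei_centers": nuclei_centers,
        "nucleus_area": int(rasterize_disk((3 * int(r_nuc) + 3,) * 2, (1.5 * r_nuc, 1.5 * r_nuc), r_nuc).sum()) if spec.n_nuclei else 0,
    }
    truth = FixtureTruth(sv_mask=sv_mask, cap_mask=cap_mask, nuclei_mask=nuclei_mask, analytic=analytic)
    return patch, truth


def _even_bbox(mask: np.ndarray, shape: tuple[int, int]) -> BBox:
    """Bounding box of a mask, padded to even height/width so its center is
    an integer (keeps rounding in the detection cascade to <= 1 px)."""
    rows, cols = np.nonzero(mask)
    r0, r1 = int(rows.min()), int(rows.max()) + 1
    c0, c1 = int(cols.min()), int(cols.max()) + 1
    if (r1 - r0) % 2:
        r1 = r1 + 1 if r1 < shape[0] else r1
        r0 = r0 - 1 if (r1 - r0) % 2 else r0
    if (c1 - c0) % 2:
        c1 = c1 + 1 if c1 < shape[1] else c1
        c0 = c0 - 1 if (c1 - c0) % 2 else c0
    return BBox(r0, c0, r1, c1, frame_id=FULL_FRAME)


def make_mini_wsi(
    n_sv: int,
    slide_side: int = 4096,
    spec: FixtureSpec = FixtureSpec(),
) -> tuple[SlideImage, dict]:
    """A desk-scale stand-in for a whole slide: a dark cochlea-like annulus
    with ``n_sv`` straight SV bands near its rim, each holding two capillary
    lumina and a few nuclei.

    Returns the slide plus a truth record with full-resolution boxes
    (one cochlea box enclosing annulus and bands; one box and integer
    center per SV band), full-slide SV/capillary truth masks, and per-band
    analytic values.
    """
    if slide_side < 8 * spec.patch_side:
        raise ValueError(f"slide_side must be >= 8 * patch_side ({8 * spec.patch_side})")
    rng = np.random.default_rng(spec.seed)
    pal = spec.palette
    w = spec.band_width
    half = w / 2.0
    half_len = 64.0

    jitter = slide_side // 16
    center = np.array(
        [
            slide_side / 2 + rng.integers(-jitter, jitter + 1),
            slide_side / 2 + rng.integers(-jitter, jitter + 1),
        ],
        dtype=float,
    )
    r_outer = slide_side / 10.0
    r_inner = 0.6 * r_outer
    annulus = np.zeros((slide_side, slide_side), dtype=bool)
    a0 = max(int(center[0] - r_outer) - 2, 0)
    a1 = min(int(center[0] + r_outer) + 2, slide_side)
    b0 = max(int(center[1] - r_outer) - 2, 0)
    b1 = min(int(center[1] + r_outer) + 2, slide_side)
    rr, cc = np.ogrid[a0:a1, b0:b1]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    annulus[a0:a1, b0:b1] = (d2 <= r_outer**2) & (d2 >= r_inner**2)

    sv_full = np.zeros((slide_side, slide_side), dtype=bool)
    cap_full = np.zeros_like(sv_full)
    nuc_full = np.zeros_like(sv_full)
    sv_boxes: list[BBox] = []
    sv_records: list[dict] = []
    r_band = r_outer + 90.0
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n_sv:
        attempts += 1
        if attempts > 200 * max(n_sv, 1):
            raise ValueError(f"cannot place {n_sv} SV bands around the rim")
        theta = rng.uniform(0.0, 2.0 * math.pi)
        c = center + r_band * np.array([math.sin(theta), math.cos(theta)])
        pad = half_len + w + 8
        if not (pad < c[0] < slide_side - pad and pad < c[1] < slide_side - pad):
            continue
        if any(np.hypot(*(c - p)) < 2.2 * half_len for p in placed):
            continue
        placed.append(c)

    for c in placed:
        samples = np.stack(
            [
                np.full(512, c[0]),
                np.linspace(c[1] - half_len, c[1] + half_len, 512),
            ],
            axis=1,
        )
        band = _band_mask((slide_side, slide_side), samples, half)
        sv_full |= band
        lumen_areas = []
        for dx in (-30.0, 30.0):
            b = min(4.0, half - 1.5)
            if b < 1.0:
                continue
            area = _stamp_ellipse(cap_full, (c[0], c[1] + dx), 5.0, b, math.pi / 2)
            lumen_areas.append(area)
        max_off = half - spec.nucleus_radius - 1.0
        n_nuc = 0
        if max_off >= 0:
            for dx in np.linspace(-half_len + 10, half_len - 10, 8):
                cr = int(round(c[0] + rng.uniform(-max_off, max_off)))
                cl = int(round(c[1] + dx))
                if abs(dx + 30.0) < 10 or abs(dx - 30.0) < 10:
                    continue  # keep clear of the lumina
                _stamp_disk(nuc_full, (cr, cl), spec.nucleus_radius)
                n_nuc += 1
        box = _even_bbox(band, (slide_side, slide_side))
        sv_boxes.append(box)
        sv_records.append(
            {
                "center": (int(box.center[0]), int(box.center[1])),
                "band_width": w,
                "lumen_areas": lumen_areas,
                "n_nuclei": n_nuc,
            }
        )

    pixels = np.empty((slide_side, slide_side, 3), dtype=np.int16)
    pixels[:] = pal.background
    pixels[annulus] = pal.cochlea
    pixels[sv_full] = pal.tissue
    pixels[cap_full] = pal.lumen
    pixels[nuc_full] = pal.nucleus
    if spec.noise_sd > 0:
        noise = np.rint(
            rng.normal(0.0, spec.noise_sd, size=pixels.shape).astype(np.float32)
        ).astype(np.int16)
        pixels += noise
    pixels = np.clip(pixels, 0, 255).astype(np.uint8)

    structure = annulus | sv_full
    cochlea_box = _even_bbox(structure, (slide_side, slide_side))
    slide = SlideImage(pixels=pixels, frame_id=FULL_FRAME, slide_id=f"mini_wsi_seed{spec.seed}")
    truth = {
        "cochlea_box": cochlea_box,
        "sv_boxes": sv_boxes,
        "sv_records": sv_records,
        "sv_mask_full": sv_full,
        "cap_mask_full": cap_full,
        "nuclei_mask_full": nuc_full,
    }
    return slide, truth
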
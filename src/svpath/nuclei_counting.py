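"""Nuclei counting inside the SV by K-means color clustering.

Hematoxylin renders nuclei dark blue-purple against the pink eosin-stained
epithelium, so within the SV mask the nuclei form the darkest color cluster.
The count is estimated by the area-division rule: total nuclei area divided
by the median area of a singleton nucleus in the same patch, which resolves
clumps of fused nuclei without instance segmentation.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from skimage import measure
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "NucleiParams",
    "NucleiResult",
    "segment_nuclei_kmeans",
    "estimate_single_nucleus_area",
    "count_nuclei",
]

#: mean luminance (0-255) above which the darkest cluster is not accepted as
#: nuclei — guards against fabricating nuclei on nucleus-free tissue
DEFAULT_LUMINANCE_GUARD = 140.0

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclasses.dataclass(frozen=True)
class NucleiParams:
    """Tunables of the nuclei counter.

    ``k`` color clusters (background/tissue, cytoplasm, dark nuclei);
    singleton nuclei are components with area inside ``area_bounds`` (px^2,
    set for ~4 px-radius nuclei at 512-px patch scale)."""

    k: int = 3
    seed: int = 0
    area_bounds: tuple[float, float] = (10.0, 200.0)
    luminance_guard: float = DEFAULT_LUMINANCE_GUARD


@dataclasses.dataclass
class NucleiResult:
    nuclei_mask: np.ndarray
    total_nuclei_area: float
    single_nucleus_area: float
    nuclei_count: float
    k_used: int
    seed: int


def segment_nuclei_kmeans(
    patch: np.ndarray,
    sv_mask: np.ndarray,
    k: int = 3,
    seed: int = 0,
    luminance_guard: float = DEFAULT_LUMINANCE_GUARD,
) -> tuple[np.ndarray, int]:
    """Segment nuclei inside the SV by K-means on raw RGB values.

    Clusters the colors of the pixels under ``sv_mask`` (no spatial
    features); the cluster with the darkest mean luminance is taken as the
    hematoxylin / nuclei cluster, unless its mean luminance exceeds the
    guard, in which case the mask is empty (no nuclei present). Returns
    ``(nuclei_mask, k_used)``; ``k`` is reduced with a warning when the
    masked pixels hold fewer distinct colors.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    sv_mask = np.asarray(sv_mask).astype(bool)
    if not sv_mask.any():
        raise ValueError("sv_mask is empty; nothing to cluster")
    pixels = np.asarray(patch)
    if pixels.shape[:2] != sv_mask.shape:
        raise ValueError(f"patch {pixels.shape[:2]} and sv_mask {sv_mask.shape} disagree")

    colors = pixels[sv_mask].reshape(-1, 3).astype(float)
    n_distinct = len(np.unique(colors, axis=0))
    k_used = k
    if n_distinct < k:
        k_used = max(n_distinct, 1)
        logger.warning("only %d distinct colors under the SV mask; reducing k to %d", n_distinct, k_used)
    empty = np.zeros_like(sv_mask)
    if k_used < 2:
        return empty, k_used

    km = KMeans(n_clusters=k_used, random_state=seed, n_init=10)
    labels = km.fit_predict(colors)
    luminance = km.cluster_centers_ @ _LUMA
    dark = int(np.argmin(luminance))
    if luminance[dark] > luminance_guard:
        return empty, k_used

    nuclei_mask = np.zeros_like(sv_mask)
    nuclei_mask[sv_mask] = labels == dark
    return nuclei_mask, k_used


def estimate_single_nucleus_area(
    nuclei_mask: np.ndarray, area_bounds: tuple[float, float] = (10.0, 200.0)
) -> float:
    """Median area of singleton nuclei: 8-connected components with area
    inside ``area_bounds`` (larger blobs are clumps of fused nuclei, smaller
    ones noise). Returns 0 when no component qualifies."""
    lo, hi = area_bounds
    labels = measure.label(np.asarray(nuclei_mask).astype(bool), connectivity=2)
    areas = [p.area for p in measure.regionprops(labels) if lo <= p.area <= hi]
    return float(np.median(areas)) if areas else 0.0


def count_nuclei(
    patch: np.ndarray, sv_mask: np.ndarray, params: NucleiParams = NucleiParams()
) -> NucleiResult:
    """Estimate nuclei per SV: total nuclei area / median singleton area.

    The count is reported as a real number (not rounded); it is 0 when no
    singleton nucleus can be identified.
    """
    nuclei_mask, k_used = segment_nuclei_kmeans(
        patch,
        sv_mask,
        k=params.k,
        seed=params.seed,
        luminance_guard=params.luminance_guard,
    )
    total = float(nuclei_mask.sum())
    single = estimate_single_nucleus_area(nuclei_mask, params.area_bounds)
    count = total / single if single > 0 else 0.0
    return NucleiResult(
        nuclei_mask=nuclei_mask,
        total_nuclei_area=total,
        single_nucleus_area=single,
        nuclei_count=count,
        k_used=k_used,
        seed=params.seed,
    )
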
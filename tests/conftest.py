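import numpy as np
import pytest

from svpath import FixtureSpec, make_mini_wsi, make_sv_patch


@pytest.fixture(scope="session")
def default_patch():
    """One synthetic SV patch at default fixture settings, with truth."""
    return make_sv_patch(FixtureSpec())


@pytest.fixture(scope="session")
def mini_wsi():
    """One 4096-px miniature slide with two planted SV bands, with truth."""
    return make_mini_wsi(n_sv=2, spec=FixtureSpec(seed=7))


def random_blob_mask(rng: np.random.Generator, side: int = 64, convex: bool = False) -> np.ndarray:
    """Random nonempty mask: one ellipse (convex) or a union of disks
    (generally concave). Test-local helper, independent of the package's
    rasterizers."""
    rr, cc = np.mgrid[:side, :side]
    mask = np.zeros((side, side), dtype=bool)
    if convex:
        cy, cx = rng.uniform(side * 0.3, side * 0.7, size=2)
        a = rng.uniform(4, side * 0.35)
        b = rng.uniform(4, side * 0.35)
        th = rng.uniform(0, np.pi)
        u = (rr - cy) * np.cos(th) + (cc - cx) * np.sin(th)
        v = -(rr - cy) * np.sin(th) + (cc - cx) * np.cos(th)
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1
    else:
        for _ in range(rng.integers(2, 5)):
            cy, cx = rng.uniform(8, side - 8, size=2)
            r = rng.uniform(3, side * 0.25)
            mask |= (rr - cy) ** 2 + (cc - cx) ** 2 <= r**2
    if not mask.any():
        mask[side // 2, side // 2] = True
    return mask


def brute_force_min_feret(mask: np.ndarray, n_angles: int = 3600) -> float:
    """Independent oracle: minimum projection width of the set pixels' outer
    corners over ``n_angles`` uniformly spaced directions."""
    rows, cols = np.nonzero(mask)
    pts = np.concatenate(
        [
            np.stack([rows, cols], axis=1),
            np.stack([rows + 1, cols], axis=1),
            np.stack([rows, cols + 1], axis=1),
            np.stack([rows + 1, cols + 1], axis=1),
        ]
    ).astype(float)
    ang = np.linspace(0.0, np.pi, n_angles, endpoint=False)
    dirs = np.stack([np.cos(ang), np.sin(ang)])
    proj = pts @ dirs
    return float((proj.max(axis=0) - proj.min(axis=0)).min())
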
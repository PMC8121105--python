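"""Shared fixtures: one mid-sized synthetic monolayer reused across tests."""

import numpy as np
import pytest

import trijunction as tj

PIXEL_SIZE = 0.5  # µm/px for all raster fixtures


@pytest.fixture(scope="session")
def tess50():
    """50-cell relaxed tessellation on a 200x200 µm domain."""
    return tj.generate_tessellation(50, (200.0, 200.0), seed=1)


@pytest.fixture(scope="session")
def labels50(tess50):
    return tj.rasterize_labels(tess50, PIXEL_SIZE)


@pytest.fixture(scope="session")
def junctions_skel50(labels50):
    skel = tj.skeletonize(tj.boundary_mask_from_labels(labels50))
    g = tj.build_skeleton_graph(skel, PIXEL_SIZE, spur_length=2.0)
    return tj.junctions_from_skeleton(g, labels50 > 0)


@pytest.fixture(scope="session")
def junctions_lab50(labels50):
    return tj.junctions_from_labels(labels50, PIXEL_SIZE)


@pytest.fixture(scope="session")
def hex_lattice():
    """Regular hexagonal tiling, side 20 µm, 200x200 µm domain."""
    return tj.hexagonal_tessellation(20.0, (200.0, 200.0))


@pytest.fixture
def y_mask():
    """32x32 Y-shaped 3-px band: three arms meeting at one point."""
    mask = np.zeros((32, 32), dtype=bool)
    rr = np.arange(16)
    for r, c in [(16 + i, 16) for i in range(16)]:          # stem down
        mask[r, max(c - 1, 0):c + 2] = True
    for i in rr:                                            # arm up-left
        r, c = 16 - i, 16 - i
        if 0 <= r < 32 and 0 <= c < 32:
            mask[max(r - 1, 0):r + 2, c] = True
    for i in rr:                                            # arm up-right
        r, c = 16 - i, 16 + i
        if 0 <= r < 32 and 0 <= c < 32:
            mask[max(r - 1, 0):r + 2, c] = True
    return mask


def brute_force_distance(shape, feature_pixels, pixel_size):
    """Naive per-pixel nearest-feature Euclidean distance (µm).

    Independent oracle for the EDT-based category map: explicit
    differences of pixel-centre coordinates, minimised over all feature
    pixels, chunked only to bound memory.
    """
    H, W = shape
    if len(feature_pixels) == 0:
        return np.full(shape, np.inf)
    yy, xx = np.mgrid[0:H, 0:W]
    py = (yy.ravel() + 0.5) * pixel_size
    px = (xx.ravel() + 0.5) * pixel_size
    fy = (feature_pixels[:, 0] + 0.5) * pixel_size
    fx = (feature_pixels[:, 1] + 0.5) * pixel_size
    out = np.empty(H * W)
    step = 4096
    for i in range(0, H * W, step):
        dy = py[i:i + step, None] - fy[None, :]
        dx = px[i:i + step, None] - fx[None, :]
        out[i:i + step] = np.sqrt((dy * dy + dx * dx).min(axis=1))
    return out.reshape(shape)
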
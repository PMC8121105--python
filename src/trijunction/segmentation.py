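"""Projection, background correction and boundary-based cell segmentation.

The junction label lives on cell borders, so segmentation is
boundary-driven: mean-project the z-stack, flatten the background with a
rolling ball, then run a marker-based watershed with the boundary signal
as the elevation map.  Cells are the catchment basins; the watershed lines
recover the boundary network.  A precomputed label TIFF from any external
segmenter can be substituted for this stage — downstream only needs a
faithful label map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.restoration import rolling_ball
from skimage.segmentation import watershed

__all__ = [
    "SegmentationParams",
    "project_stack",
    "subtract_background",
    "segment_boundaries",
    "boundary_mask_from_labels",
]


@dataclass
class SegmentationParams:
    """Knobs of the classical boundary segmentation.

    background_radius is in pixels (default 20, the standard rolling-ball
    radius for thin junctional signal); smoothing_sigma smooths the
    elevation map before seeding; seed_min_distance (px) sets the minimum
    separation between cell seeds, i.e. the smallest resolvable cell;
    boundary_threshold is either "otsu" or a float absolute threshold on
    the smoothed boundary signal.
    """

    background_radius: int = 20
    smoothing_sigma: float = 2.0
    seed_min_distance: int = 10
    boundary_threshold: str | float = "otsu"

    def __post_init__(self):
        if self.background_radius < 1:
            raise ValueError("background_radius must be >= 1 px")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")


def project_stack(stack: np.ndarray) -> np.ndarray:
    """Mean-intensity projection over z; a single plane passes through."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        return stack
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be a (z, H, W) array with >= 1 plane")
    if stack.shape[0] == 1:
        return stack[0]
    return stack.mean(axis=0)


def subtract_background(img: np.ndarray, radius: int = 20) -> np.ndarray:
    """Rolling-ball background subtraction, clipped at zero.

    The background is the envelope of a ball of the given radius rolled
    under the intensity surface; subtracting it removes slowly varying
    offsets and shading while preserving ridges much thinner than the
    radius.
    """
    img = np.asarray(img, dtype=float)
    if radius < 1:
        raise ValueError("radius must be >= 1 px")
    if radius >= min(img.shape):
        raise ValueError(
            f"radius {radius} px must be smaller than the image "
            f"({img.shape[0]}x{img.shape[1]})")
    bg = rolling_ball(img, radius=radius)
    return np.clip(img - bg, 0.0, None)


def _seed_markers(elev: np.ndarray, below: np.ndarray,
                  min_distance: int) -> np.ndarray:
    """Cell seeds: one marker per minimum plateau of the elevation map.

    Local minima of the boundary elevation form broad plateaus — the cell
    interiors — separated by the boundary band, so each 4-connected
    component of the sub-threshold region is one seed.  Components smaller
    than min_distance^2 pixels (noise specks, thinner than the smallest
    resolvable cell) are discarded.
    """
    comp, n = ndimage.label(below)
    if n == 0:
        return np.zeros(elev.shape, dtype=np.int32)
    areas = ndimage.sum_labels(np.ones_like(comp), comp, range(1, n + 1))
    keep = np.flatnonzero(areas >= min_distance ** 2) + 1
    markers = np.zeros(elev.shape, dtype=np.int32)
    for i, lab in enumerate(keep, start=1):
        markers[comp == lab] = i
    return markers


def segment_boundaries(img: np.ndarray,
                       params: SegmentationParams | None = None
                       ) -> np.ndarray:
    """Watershed the boundary signal into a cell label map.

    The (projected, background-corrected) image is smoothed, thresholded to
    find boundary-free interior, seeded at interior points maximally far
    from boundaries, and flooded with the smoothed intensity as elevation.
    Labels are positive integers over 4-connected regions.  Deterministic.
    """
    if params is None:
        params = SegmentationParams()
    img = np.asarray(img, dtype=float)
    elev = (gaussian(img, sigma=params.smoothing_sigma, preserve_range=True)
            if params.smoothing_sigma > 0 else img)

    if params.boundary_threshold == "otsu":
        span = elev.max() - elev.min()
        if span <= 0 or span < 1e-6 * max(abs(elev.max()), 1.0):
            raise ValueError("no cells detected: image has no boundary signal")
        thr = threshold_otsu(elev)
    else:
        thr = float(params.boundary_threshold)
    below = elev < thr

    markers = _seed_markers(elev, below, params.seed_min_distance)
    if markers.max() == 0:
        raise ValueError("no cells detected: no watershed seeds found")
    labels = watershed(elev, markers=markers)
    # watershed returns labels 1..k over the full image; re-label as
    # 4-connected regions so the public contract holds exactly
    out = np.zeros_like(labels, dtype=np.int32)
    nxt = 1
    for lab in range(1, labels.max() + 1):
        comp, ncomp = ndimage.label(labels == lab)
        for c in range(1, ncomp + 1):
            out[comp == c] = nxt
            nxt += 1
    return out


def boundary_mask_from_labels(lmap: np.ndarray) -> np.ndarray:
    """Binary inter-cell boundary mask of a label map.

    A pixel is boundary iff a 4-neighbour carries a different nonzero
    label (label/0 interfaces at the monolayer rim are not junctions).
    The mask is at most 2 px wide — one pixel on each side of the
    interface — and thins to a clean skeleton.
    """
    lmap = np.asarray(lmap)
    if np.unique(lmap[lmap > 0]).size < 2:
        raise ValueError("boundary mask needs a label map with >= 2 cells")
    mask = np.zeros(lmap.shape, dtype=bool)
    a, b = lmap[:-1, :], lmap[1:, :]
    diff = (a != b) & (a > 0) & (b > 0)
    mask[:-1, :] |= diff
    mask[1:, :] |= diff
    a, b = lmap[:, :-1], lmap[:, 1:]
    diff = (a != b) & (a > 0) & (b > 0)
    mask[:, :-1] |= diff
    mask[:, 1:] |= diff
    return mask
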
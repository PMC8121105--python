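"""Synthetic monolayers, fluorescence renders and diapedesis events.

Everything downstream is validated against ground truth produced here:

* :func:`generate_tessellation` — a confluent sheet of convex-ish,
  size-regular cells (seeded random points, centroidal relaxation,
  optional anisotropic elongation mimicking flow-aligned endothelium),
  with exact polygon cells, shared-edge polylines and interior vertices
  where ≥3 cells meet;
* :func:`rasterize_labels` — the exact pixel label map of a tessellation;
* :func:`render_fluorescence` — a junction-label-like image stack: bright
  boundary ridges plus blur, uneven illumination and per-plane noise;
* :func:`generate_events` — diapedesis endpoints placed uniformly at
  random over the monolayer or with category-biased probabilities.

All generators are deterministic for a fixed seed.  Coordinates are
physical (µm, pixel-centre convention); events stay continuous and are
snapped to pixels only when classified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import Polygon
from skimage.draw import line as draw_line
from skimage.filters import gaussian
from skimage.morphology import dilation, disk

from .frequency import BI, BODY, CATEGORY_NAMES, OUTSIDE, TRI, CategoryMap

__all__ = [
    "Tessellation", "ImagingConfig", "EventModel", "EVENT_PRESETS",
    "generate_tessellation", "hexagonal_tessellation", "rasterize_labels",
    "render_fluorescence", "generate_events",
    "write_label_map", "write_stack", "write_events", "read_events",
]

_NAME_TO_CODE = {v: k for k, v in CATEGORY_NAMES.items()}


@dataclass
class Tessellation:
    """Ground-truth monolayer geometry in µm.

    ``cells`` are closed polygons (vertex arrays) that tile the rectangular
    domain; ``vertices`` are the interior points where ≥3 cells meet (the
    true tricellular junctions); ``edges`` are the shared-boundary
    polylines between cell pairs, keyed by the two cell indices.
    ``generators`` are the Voronoi seed points in the isotropic
    (pre-elongation) frame; the label of any point is its nearest
    generator in that frame, which makes rasterization exact.
    """

    cells: list[np.ndarray]
    vertices: np.ndarray                   # (M, 2) x, y µm
    edges: list[tuple[int, int, np.ndarray]]  # (cell_i, cell_j, polyline)
    domain_size: tuple[float, float]       # (width, height) µm
    seed: int | None
    generators: np.ndarray = field(default=None, repr=False)
    elongation: float = 1.0

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "domain_size": list(self.domain_size),
            "seed": self.seed,
            "elongation": self.elongation,
            "cells": [c.tolist() for c in self.cells],
            "vertices": self.vertices.tolist(),
            "edges": [[int(i), int(j), pl.tolist()]
                      for i, j, pl in self.edges],
            "generators": (self.generators.tolist()
                           if self.generators is not None else None),
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "Tessellation":
        obj = json.loads(Path(path).read_text())
        return cls(
            cells=[np.asarray(c, dtype=float) for c in obj["cells"]],
            vertices=np.asarray(obj["vertices"], dtype=float).reshape(-1, 2),
            edges=[(i, j, np.asarray(pl, dtype=float))
                   for i, j, pl in obj["edges"]],
            domain_size=tuple(obj["domain_size"]),
            seed=obj["seed"],
            generators=(np.asarray(obj["generators"], dtype=float)
                        if obj["generators"] is not None else None),
            elongation=float(obj.get("elongation", 1.0)),
        )


@dataclass
class ImagingConfig:
    """Rendering parameters emulating junction-marker fluorescence."""

    pixel_size: float = 0.5        # µm/px
    ridge_sigma: float = 0.5       # µm boundary blur
    noise_sd: float = 0.0          # additive Gaussian noise (ridge peak = 1)
    illumination_gradient: float = 0.0  # fractional range across the field
    z_planes: int = 1

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.z_planes < 1:
            raise ValueError("z_planes must be >= 1")


@dataclass
class EventModel:
    """How diapedesis endpoints are placed on a category map.

    ``uniform`` draws every event uniformly over in-monolayer pixels —
    the random-location null itself.  ``category_probs`` first draws a
    category from ``probs = (p_tri, p_bi, p_body)`` and then a pixel
    uniformly within it, emulating junction-tropic migration.  The
    footprint diameter (default 5 µm, a typical diapedesis pore) is
    metadata for reporting; events are point coordinates.
    """

    kind: str = "uniform"
    probs: tuple[float, float, float] | None = None
    n_events: int = 100
    footprint_diameter: float = 5.0
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in ("uniform", "category_probs"):
            raise ValueError(f"unknown event model kind {self.kind!r}")
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if self.kind == "category_probs":
            if self.probs is None:
                raise ValueError("category_probs model requires probs")
            if abs(sum(self.probs) - 1.0) > 1e-9:
                raise ValueError("probs must sum to 1")


#: Simulation presets for the observed diapedesis compositions
#: (p_tri, p_bi, p_body).  "il1b_lo_paracellular_split" reads the 60%
#: tricellular figure as a fraction of paracellular events (tri:bi = 3:2
#: among junctional crossings, with a 10% transcellular share);
#: "il1b_lo_all_events" reads it as a fraction of all diapedesis events;
#: "live_imaging_tri40" mirrors the ~40% tricellular share seen in
#: live imaging irrespective of inflammatory conditions.
EVENT_PRESETS: dict[str, tuple[float, float, float]] = {
    "il1b_lo_paracellular_split": (0.54, 0.36, 0.10),
    "il1b_lo_all_events": (0.60, 0.30, 0.10),
    "live_imaging_tri40": (0.40, 0.35, 0.25),
}


# ---------------------------------------------------------------------------
# tessellation construction

def _mirrored_voronoi_cells(points: np.ndarray, width: float, height: float
                            ) -> tuple[list[np.ndarray], Voronoi]:
    """Voronoi cells of ``points`` clipped exactly to the domain rectangle.

    Reflecting every point across the four domain edges makes each interior
    cell finite and bounded by the rectangle, so the cells of the original
    points tile [0, w] x [0, h] exactly.
    """
    refl = [points,
            points * [-1, 1],                       # across x = 0
            points * [1, -1],                       # across y = 0
            np.column_stack([2 * width - points[:, 0], points[:, 1]]),
            np.column_stack([points[:, 0], 2 * height - points[:, 1]])]
    vor = Voronoi(np.concatenate(refl))
    cells = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        poly = vor.vertices[region]
        cells.append(poly)
    return cells, vor


def _tessellation_from_points(points: np.ndarray, width: float,
                              height: float, seed: int | None,
                              elongation: float = 1.0,
                              lloyd_rounds: int = 3) -> Tessellation:
    points = points.copy()
    for _ in range(lloyd_rounds):
        cells, _ = _mirrored_voronoi_cells(points, width, height)
        points = np.array([Polygon(c).centroid.coords[0] for c in cells])
        points[:, 0] = np.clip(points[:, 0], 1e-9, width - 1e-9)
        points[:, 1] = np.clip(points[:, 1], 1e-9, height - 1e-9)
    cells, vor = _mirrored_voronoi_cells(points, width, height)
    n = len(points)

    # interior vertices: Voronoi vertices used by >= 3 original-point regions
    vert_use: dict[int, int] = {}
    for i in range(n):
        for vi in vor.regions[vor.point_region[i]]:
            vert_use[vi] = vert_use.get(vi, 0) + 1
    interior = sorted(vi for vi, cnt in vert_use.items() if cnt >= 3)
    vertices = (vor.vertices[interior] if interior
                else np.empty((0, 2)))
    if len(vertices):
        # domain-edge vertices are acquisition cuts, not junctions
        eps = 1e-3
        keep = ((vertices[:, 0] > eps) & (vertices[:, 0] < width - eps)
                & (vertices[:, 1] > eps) & (vertices[:, 1] < height - eps))
        vertices = vertices[keep]

    # shared edges between pairs of original cells
    edges = []
    for (p, q), (v0, v1) in zip(vor.ridge_points, vor.ridge_vertices):
        if p < n and q < n and v0 >= 0 and v1 >= 0:
            edges.append((int(p), int(q),
                          np.array([vor.vertices[v0], vor.vertices[v1]])))

    scale = np.array([elongation, 1.0])
    return Tessellation(
        cells=[c * scale for c in cells],
        vertices=vertices * scale,
        edges=[(i, j, pl * scale) for i, j, pl in edges],
        domain_size=(width * elongation, height),
        seed=seed,
        generators=points,
        elongation=elongation,
    )


def generate_tessellation(n_cells: int, domain_size: tuple[float, float],
                          elongation: float = 1.0,
                          seed: int | None = None) -> Tessellation:
    """Confluent random tessellation of a rectangular domain.

    Seed points are dropped uniformly at random, relaxed by three rounds of
    Lloyd iteration (each point moved to its clipped-Voronoi-cell centroid)
    to give size-regular, convex-ish cells, then anisotropically scaled by
    ``elongation`` (≥1) along x to emulate flow-aligned endothelial cells.
    ``domain_size`` is the final (width, height) in µm.  Deterministic for
    a fixed seed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    width, height = float(domain_size[0]), float(domain_size[1])
    if width <= 0 or height <= 0:
        raise ValueError("domain_size must be positive")
    if elongation < 1:
        raise ValueError("elongation must be >= 1")

    if n_cells == 1:
        cell = np.array([[0, 0], [width, 0], [width, height], [0, height]],
                        dtype=float)
        return Tessellation(cells=[cell], vertices=np.empty((0, 2)),
                            edges=[], domain_size=(width, height), seed=seed,
                            generators=np.array([[width / 2 / elongation,
                                                  height / 2]]),
                            elongation=elongation)

    w_iso = width / elongation
    rng = np.random.default_rng(seed)
    pts = rng.uniform([0, 0], [w_iso, height], size=(n_cells, 2))
    return _tessellation_from_points(pts, w_iso, height, seed,
                                     elongation=elongation)


def hexagonal_tessellation(edge: float, domain_size: tuple[float, float]
                           ) -> Tessellation:
    """Regular hexagonal tiling (hexagon side ``edge`` µm) clipped to a
    rectangle — the textbook monolayer where every interior vertex is
    exactly tricellular."""
    width, height = float(domain_size[0]), float(domain_size[1])
    # Voronoi of a triangular lattice (spacing sqrt(3)*edge) is the hex tiling
    d = np.sqrt(3.0) * edge
    centers = []
    row_h = 1.5 * edge
    j = 0
    y = row_h / 2.0
    while y < height:
        off = 0.0 if j % 2 == 0 else d / 2.0
        x = off + d / 2.0 - d
        while x < width + d:
            if -d < x < width + d:
                centers.append((x, y))
            x += d
        y += row_h
        j += 1
    centers = np.asarray(centers)
    # keep generators inside for the mirror construction; jitter breaks
    # reflection-induced degeneracies without moving vertices measurably
    inside = ((centers[:, 0] > 0) & (centers[:, 0] < width)
              & (centers[:, 1] > 0) & (centers[:, 1] < height))
    pts = centers[inside]
    pts = pts + np.random.default_rng(0).normal(0, 1e-7 * edge, pts.shape)
    return _tessellation_from_points(pts, width, height, seed=None,
                                     lloyd_rounds=0)


# ---------------------------------------------------------------------------
# rasterization and rendering

def rasterize_labels(t: Tessellation, pixel_size: float) -> np.ndarray:
    """Exact label map: each pixel takes the cell containing its centre.

    For a (possibly elongated) Voronoi tessellation, containment equals
    nearest-generator in the isotropic frame, evaluated here with a KD-tree
    — no polygon scan-conversion error.  Labels run 1..n_cells; pixels with
    centres outside the domain are 0.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    width, height = t.domain_size
    nx, ny = int(round(width / pixel_size)), int(round(height / pixel_size))
    if nx < 8 or ny < 8:
        raise ValueError(
            f"pixel_size {pixel_size} yields a {ny}x{nx} image; need >= 8 px "
            "per side")
    xs = (np.arange(nx) + 0.5) * pixel_size
    ys = (np.arange(ny) + 0.5) * pixel_size
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel() / t.elongation, yy.ravel()])
    tree = cKDTree(t.generators)
    _, idx = tree.query(pts)
    lmap = (idx.astype(np.int32) + 1).reshape(ny, nx)
    outside = ((xx < 0) | (xx > width) | (yy < 0) | (yy > height))
    lmap[outside] = 0
    return lmap


def render_fluorescence(t: Tessellation, cfg: ImagingConfig,
                        seed: int | None = None) -> np.ndarray:
    """Render the boundary network as a fluorescence-like image stack.

    Shared-edge polylines are drawn as 3-px-wide ridges, Gaussian-blurred
    at ``ridge_sigma``, scaled to unit peak, then modulated by a linear
    illumination gradient along x and corrupted by independent additive
    Gaussian noise per z-plane.  Returns a float array of shape
    (z_planes, H, W); deterministic for a fixed seed.
    """
    ps = cfg.pixel_size
    width, height = t.domain_size
    nx, ny = int(round(width / ps)), int(round(height / ps))
    canvas = np.zeros((ny, nx), dtype=float)
    for _, _, pl in t.edges:
        for k in range(len(pl) - 1):
            r0 = int(np.clip(round(pl[k][1] / ps - 0.5), 0, ny - 1))
            c0 = int(np.clip(round(pl[k][0] / ps - 0.5), 0, nx - 1))
            r1 = int(np.clip(round(pl[k + 1][1] / ps - 0.5), 0, ny - 1))
            c1 = int(np.clip(round(pl[k + 1][0] / ps - 0.5), 0, nx - 1))
            rr, cc = draw_line(r0, c0, r1, c1)
            canvas[rr, cc] = 1.0
    canvas = dilation(canvas, disk(1))            # 3-px ridge before blur
    if cfg.ridge_sigma > 0:
        canvas = gaussian(canvas, sigma=cfg.ridge_sigma / ps,
                          preserve_range=True)
    if canvas.max() > 0:
        canvas = canvas / canvas.max()

    if cfg.illumination_gradient:
        ramp = 1.0 + cfg.illumination_gradient * (
            np.arange(nx) / max(nx - 1, 1) - 0.5)
        canvas = canvas * ramp[None, :]

    rng = np.random.default_rng(seed)
    stack = np.empty((cfg.z_planes, ny, nx), dtype=float)
    for z in range(cfg.z_planes):
        noise = (rng.normal(0.0, cfg.noise_sd, size=(ny, nx))
                 if cfg.noise_sd > 0 else 0.0)
        stack[z] = canvas + noise
    return stack


# ---------------------------------------------------------------------------
# event placement

def generate_events(cmap: CategoryMap, model: EventModel) -> pd.DataFrame:
    """Place diapedesis endpoints on a category map.

    Returns a table ``event_id, x_um, y_um, true_category`` with continuous
    µm coordinates jittered uniformly within the chosen pixel, so snapping
    back to pixels recovers the generating pixel exactly.
    """
    rng = np.random.default_rng(model.seed)
    cats = cmap.categories
    ps = cmap.pixel_size
    in_mono = np.argwhere(cats != OUTSIDE)
    if len(in_mono) == 0:
        raise ValueError("category map has no in-monolayer pixels")

    if model.kind == "uniform":
        picks = in_mono[rng.integers(0, len(in_mono), size=model.n_events)]
    else:
        pools = {}
        for code, p in zip((TRI, BI, BODY), model.probs):
            if p > 0:
                pool = np.argwhere(cats == code)
                if len(pool) == 0:
                    raise ValueError(
                        f"requested category {CATEGORY_NAMES[code]} has no "
                        "pixels in the category map")
                pools[code] = pool
        codes = rng.choice([TRI, BI, BODY], size=model.n_events,
                           p=list(model.probs))
        picks = np.empty((model.n_events, 2), dtype=int)
        for code in (TRI, BI, BODY):
            sel = codes == code
            if sel.any():
                pool = pools[code]
                picks[sel] = pool[rng.integers(0, len(pool), size=sel.sum())]

    jitter = rng.uniform(-0.49, 0.49, size=(model.n_events, 2))
    x = (picks[:, 1] + 0.5 + jitter[:, 0]) * ps
    y = (picks[:, 0] + 0.5 + jitter[:, 1]) * ps
    true_cat = [CATEGORY_NAMES[int(cats[r, c])] for r, c in picks]
    return pd.DataFrame({
        "event_id": np.arange(model.n_events),
        "x_um": x,
        "y_um": y,
        "true_category": true_cat,
    })


# ---------------------------------------------------------------------------
# I/O

def write_label_map(lmap: np.ndarray, path: str | Path) -> None:
    import tifffile
    if lmap.max() > np.iinfo(np.uint16).max:
        raise ValueError("label map exceeds 16-bit range")
    tifffile.imwrite(Path(path), lmap.astype(np.uint16))


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    import tifffile
    tifffile.imwrite(Path(path), stack.astype(np.float32))


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    cols = ["event_id", "x_um", "y_um"]
    for opt in ("true_category", "observed_category"):
        if opt in events.columns:
            cols.append(opt)
    events[cols].to_csv(Path(path), index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = {"event_id", "x_um", "y_um"} - set(df.columns)
    if missing:
        raise ValueError(
            f"events CSV is missing required column(s): {sorted(missing)}")
    return df
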
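"""Seeded segmentation of muscle fibers and nuclear regions.

Muscle fibers are delineated in the cytoplasm (green) channel by a seeded
level-set evolution: the user (or a script) supplies a polygon enclosing one
fiber, and the contour shrinks inward from the polygon boundary until it
locks onto image edges.  The speed of the front is the geodesic
edge-stopping function

    g = 1 / (1 + grey_weight * |grad(G_sigma * I)|),

so the front moves freely across flat grey values (g near 1) and stalls on
strong gradients (g near 0); a morphological curvature operator regularises
the contour, and a gradient-advection step pins it to the gradient ridge.
Evolution is strictly confined to the seed polygon — early-pupal histolysis
debris outside the seed can never leak in, which is why segmentation here is
seeded rather than fully automatic.  If the contour vanishes (no edge to
stop on) a :class:`SegmentationFailure` is raised so the caller can fall
back to a manually drawn ROI.

Nuclear clusters are detected inside each muscle ROI by Otsu thresholding of
the red channel restricted to the ROI; individual nuclei are not separated
(at 10x the resolution does not support it), so connected components above a
small area floor are reported as nuclear regions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np
import shapely
from scipy import ndimage as ndi
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage.measure import find_contours

from .errors import DegenerateHistogramError, GeometryError, SegmentationFailure

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .tracking import CellAnnotation

_roi_counter = itertools.count(1)


@dataclass
class SeedPolygon:
    """A simple polygon drawn around one muscle fiber in one frame."""

    vertices: np.ndarray  # (N, 2) of (x, y)
    frame_idx: int = 0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if len(self.vertices) < 3:
            raise GeometryError("a polygon needs at least 3 vertices")
        poly = _ShapelyPolygon(self.vertices)
        if not poly.is_valid or poly.area <= 0:
            raise GeometryError("polygon must be simple with positive area")

    @property
    def shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)


@dataclass
class LevelSetParams:
    """Tunable parameters of the seeded level-set evolution.

    grey_weight scales the gradient magnitude inside the edge-stopping
    function (dimensionless); curvature_weight sets how many morphological
    curvature-smoothing passes run per iteration; edge_sigma (pixels) is the
    Gaussian scale at which gradients are measured; convergence_tol is the
    fraction of the seed area that may change per iteration at convergence.
    """

    grey_weight: float = 1.0
    curvature_weight: float = 1.0
    edge_sigma: float = 2.0
    max_iterations: int = 500
    convergence_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.grey_weight < 0 or self.curvature_weight < 0:
            raise ValueError("weights must be non-negative")
        if self.edge_sigma <= 0 or self.max_iterations <= 0 or self.convergence_tol <= 0:
            raise ValueError("edge_sigma, max_iterations, convergence_tol must be positive")


@dataclass
class MuscleROI:
    """One segmented muscle fiber at one time point."""

    roi_id: int
    stack_name: str
    frame_idx: int
    polygon: np.ndarray  # (N, 2) boundary vertices, (x, y)
    mask: np.ndarray  # bool, full-frame grid
    centroid: tuple[float, float]  # (x, y), mask centre of mass
    source: str  # "levelset" | "manual"
    annotation: Optional["CellAnnotation"] = None

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float).reshape(-1, 2)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.source not in ("levelset", "manual"):
            raise ValueError(f"unknown ROI source {self.source!r}")

    @property
    def area_px(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass
class NuclearRegion:
    """A cluster of nuclei inside one muscle ROI."""

    parent_roi: int
    mask: np.ndarray
    area_px: int = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.area_px = int(np.count_nonzero(self.mask))


def mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Centre of mass of a binary mask, as (x, y)."""
    cy, cx = ndi.center_of_mass(mask)
    return (float(cx), float(cy))


def rasterize_polygon(polygon: SeedPolygon | np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise a simple polygon: a pixel is set iff its centre lies inside
    (even-odd rule); centres exactly on the boundary are included."""
    if not isinstance(polygon, SeedPolygon):
        polygon = SeedPolygon(np.asarray(polygon))
    poly = polygon.shapely
    h, w = shape
    minx, miny, maxx, maxy = poly.bounds
    x0 = max(0, int(np.floor(minx)))
    y0 = max(0, int(np.floor(miny)))
    x1 = min(w - 1, int(np.ceil(maxx)))
    y1 = min(h - 1, int(np.ceil(maxy)))
    mask = np.zeros(shape, dtype=bool)
    if x1 < x0 or y1 < y0:
        return mask
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    inside = shapely.intersects_xy(poly, xs.ravel(), ys.ravel()).reshape(xs.shape)
    mask[y0 : y1 + 1, x0 : x1 + 1] = inside
    return mask


def mask_to_polygon(mask: np.ndarray) -> np.ndarray:
    """Extract the outer boundary of a mask as an (N, 2) (x, y) polygon
    (marching squares at the 0.5 level; the longest contour is taken)."""
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        raise GeometryError("mask has no boundary contour")
    longest = max(contours, key=len)
    return longest[:, ::-1].copy()  # (row, col) -> (x, y)


# 3x3 line structuring elements for the morphological curvature operator
_LINES = [
    np.array([[0, 0, 0], [1, 1, 1], [0, 0, 0]], bool),
    np.array([[0, 1, 0], [0, 1, 0], [0, 1, 0]], bool),
    np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]], bool),
    np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], bool),
]


def _sup_inf(u: np.ndarray) -> np.ndarray:
    return np.logical_or.reduce([ndi.binary_erosion(u, line) for line in _LINES])


def _inf_sup(u: np.ndarray) -> np.ndarray:
    return np.logical_and.reduce([ndi.binary_dilation(u, line) for line in _LINES])


def edge_stopping(image: np.ndarray, grey_weight: float, edge_sigma: float) -> np.ndarray:
    """g = 1/(1 + grey_weight * |grad(G_sigma * I)|) on [~0, 1]."""
    smoothed = ndi.gaussian_filter(np.asarray(image, dtype=float), edge_sigma)
    gy, gx = np.gradient(smoothed)
    return 1.0 / (1.0 + grey_weight * np.hypot(gx, gy))


def evolve_levelset(
    image: np.ndarray,
    seed: SeedPolygon,
    params: LevelSetParams | None = None,
    stack_name: str = "",
    *,
    edge_stop_threshold: float = 0.15,
) -> MuscleROI:
    """Shrink a contour inward from the seed polygon until it locks onto edges.

    The front erodes one pixel per iteration wherever the edge-stopping
    function exceeds ``edge_stop_threshold`` (no edge), is advected toward
    gradient ridges, and is smoothed by ``curvature_weight`` passes of a
    morphological curvature operator.  The result is always contained in the
    seed polygon.  Raises :class:`SegmentationFailure` if the contour
    vanishes.
    """
    params = params or LevelSetParams()
    image = np.asarray(image, dtype=float)
    seed_mask = rasterize_polygon(seed, image.shape)
    seed_area = int(seed_mask.sum())
    if seed_area == 0:
        raise GeometryError("seed polygon does not cover any pixel of the image")

    # evolve on a bounding-box crop for speed; containment makes this exact
    ys, xs = np.nonzero(seed_mask)
    m = int(np.ceil(3 * params.edge_sigma)) + 2
    y0, y1 = max(0, ys.min() - m), min(image.shape[0], ys.max() + 1 + m)
    x0, x1 = max(0, xs.min() - m), min(image.shape[1], xs.max() + 1 + m)
    crop = image[y0:y1, x0:x1]
    seed_crop = seed_mask[y0:y1, x0:x1]

    g = edge_stopping(crop, params.grey_weight, params.edge_sigma)
    dgy, dgx = np.gradient(g)
    free = g > edge_stop_threshold
    n_smooth = int(round(params.curvature_weight))

    u = seed_crop.copy()
    flip = False
    calm = 0  # consecutive iterations under the convergence tolerance
    for _ in range(params.max_iterations):
        prev = u
        eroded = ndi.binary_erosion(u)
        u = np.where(free, eroded, u)
        # advect the front toward the gradient ridge (minimum of g); the
        # evolution is inward-only, so advection may remove but never add
        uf = u.astype(float)
        uy, ux = np.gradient(uf)
        adv = dgx * ux + dgy * uy
        u = u.copy()
        u[adv < 0] = False
        for _k in range(n_smooth):
            u = _inf_sup(_sup_inf(u)) if flip else _sup_inf(_inf_sup(u))
            flip = not flip
        u &= prev  # monotone shrinkage: curvature smoothing only trims
        u &= seed_crop
        if not u.any():
            raise SegmentationFailure("level-set contour vanished inside the seed")
        calm = calm + 1 if np.count_nonzero(u ^ prev) / seed_area <= params.convergence_tol else 0
        if calm >= 2:
            break

    # keep the largest connected component (stray islets can survive smoothing)
    labels, n = ndi.label(u, structure=np.ones((3, 3), bool))
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        u = labels == (1 + int(np.argmax(sizes)))

    mask = np.zeros(image.shape, dtype=bool)
    mask[y0:y1, x0:x1] = u
    poly = mask_to_polygon(mask)
    return MuscleROI(
        roi_id=next(_roi_counter),
        stack_name=stack_name,
        frame_idx=seed.frame_idx,
        polygon=poly,
        mask=mask,
        centroid=mask_centroid(mask),
        source="levelset",
    )


def manual_roi(
    polygon: SeedPolygon, shape: tuple[int, int], stack_name: str = ""
) -> MuscleROI:
    """ROI taken directly from a hand-drawn polygon (level-set fallback)."""
    verts = polygon.vertices
    h, w = shape
    if (
        verts[:, 0].min() < -0.5
        or verts[:, 1].min() < -0.5
        or verts[:, 0].max() > w - 0.5
        or verts[:, 1].max() > h - 0.5
    ):
        raise GeometryError("polygon extends outside the image bounds")
    mask = rasterize_polygon(polygon, shape)
    if not mask.any():
        raise GeometryError("polygon does not cover any pixel centre")
    return MuscleROI(
        roi_id=next(_roi_counter),
        stack_name=stack_name,
        frame_idx=polygon.frame_idx,
        polygon=verts.copy(),
        mask=mask,
        centroid=mask_centroid(mask),
        source="manual",
    )


def otsu_threshold(histogram: np.ndarray) -> int:
    """Threshold of a 256-bin histogram maximising between-class variance.

    Foreground is the class of values >= threshold.  If several thresholds
    tie, the lowest is returned.  A histogram concentrated in a single bin
    raises :class:`DegenerateHistogramError`.
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    if hist.sum() <= 0:
        raise ValueError("histogram must contain at least one count")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("all pixels share one grey value")

    levels = np.arange(256, dtype=float)
    total = hist.sum()
    mean_total = (levels * hist).sum() / total
    # class 0 = values < t, for cut t in 1..255
    w0 = np.cumsum(hist)[:-1] / total  # w0[t-1] = P(value < t)
    mu_cum = np.cumsum(levels * hist)[:-1] / total
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.full(255, -np.inf)
    mu0 = np.where(valid, mu_cum / np.where(w0 > 0, w0, 1), 0.0)
    mu1 = np.where(valid, (mean_total - mu_cum) / np.where(w1 > 0, w1, 1), 0.0)
    sigma_b[valid] = (w0 * w1 * (mu0 - mu1) ** 2)[valid]
    return int(np.argmax(sigma_b)) + 1  # lowest maximiser, thanks to argmax tie rule


def segment_nuclei(
    red_channel: np.ndarray, roi: MuscleROI, min_area_px: int = 4
) -> list[NuclearRegion]:
    """Detect nuclear clusters inside a muscle ROI.

    Otsu's threshold is computed on the red-channel histogram restricted to
    the ROI; pixels at or above it form candidate regions (8-connected),
    and components below ``min_area_px`` are discarded as shot noise.
    """
    red = np.asarray(red_channel)
    if not roi.mask.any():
        raise ValueError("ROI mask is empty")
    values = red[roi.mask].astype(np.int64)
    hist = np.bincount(np.clip(values, 0, 255), minlength=256)[:256]
    try:
        thr = otsu_threshold(hist)
    except DegenerateHistogramError:
        return []
    fg = (red >= thr) & roi.mask
    labels, n = ndi.label(fg, structure=np.ones((3, 3), bool))
    regions = []
    for i in range(1, n + 1):
        m = labels == i
        if int(m.sum()) >= min_area_px:
            regions.append(NuclearRegion(parent_roi=roi.roi_id, mask=m))
    return regions
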
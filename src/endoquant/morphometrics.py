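"""Cell-scale morphometry from high-magnification fields.

Endothelial health is read off three classic indices: cell density
(cells/mm**2), hexagonality (percentage of cells with exactly six neighbors;
pleomorphism index) and the coefficient of variation of cell area
(polymegethism index), plus the percentage of dead cells in live/dead
co-stains.  Density comes from counting nuclear intensity maxima, the
approach of ImageJ-style nucleus counters: calcein-loaded cells usually show
a nucleus brighter than the cytoplasm, so local maxima of a band-passed
image mark cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.spatial import Voronoi, cKDTree

__all__ = [
    "DetectionParams",
    "DensityEstimate",
    "HexagonalityResult",
    "MorphometryReport",
    "detect_nuclei",
    "estimate_density",
    "neighbor_analysis",
    "area_cov",
    "dead_fraction",
    "match_points",
]

MIN_CELLS_REPORT_GRADE = 1000


@dataclass(frozen=True)
class DetectionParams:
    """Nuclear-maxima detector settings, all in pixels/grey levels.

    Defaults are expressed relative to the expected cell width: smoothing
    sigma 0.15x, minimum peak separation 0.7x, and a 5-grey-level prominence
    over the local background (estimated by a 2x-cell-width Gaussian).
    """

    cell_width_px: float
    smooth_sigma_px: float | None = None
    min_separation_px: float | None = None
    prominence: float = 5.0

    def __post_init__(self) -> None:
        if self.cell_width_px <= 0 or self.prominence <= 0:
            raise ValueError("cell width and prominence must be positive")
        if self.smooth_sigma_px is not None and self.smooth_sigma_px <= 0:
            raise ValueError("smooth_sigma_px must be positive")
        if self.min_separation_px is not None and self.min_separation_px <= 0:
            raise ValueError("min_separation_px must be positive")

    @property
    def sigma(self) -> float:
        return self.smooth_sigma_px if self.smooth_sigma_px is not None else 0.15 * self.cell_width_px

    @property
    def separation(self) -> float:
        return (
            self.min_separation_px
            if self.min_separation_px is not None
            else 0.7 * self.cell_width_px
        )


@dataclass(frozen=True)
class DensityEstimate:
    n_cells: int
    area_mm2: float
    method: Literal["calcein_maxima", "nuclei_channel"]

    @property
    def density(self) -> float:
        return self.n_cells / self.area_mm2


@dataclass(frozen=True)
class HexagonalityResult:
    n_interior: int
    neighbor_counts: np.ndarray  # per interior cell
    hexagonality_pct: float
    n_edges: int  # total adjacency edges over ALL cells (handshake check)
    all_neighbor_counts: np.ndarray  # per cell, interior and border alike


@dataclass(frozen=True)
class MorphometryReport:
    hexagonality_pct: float
    area_cov: float
    dead_pct: float
    n_analyzed: int

    @property
    def report_grade(self) -> bool:
        """True when at least 1000 cells back the morphometry."""
        return self.n_analyzed >= MIN_CELLS_REPORT_GRADE


def detect_nuclei(image: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Detect nuclear intensity maxima; returns (n, 2) array of (row, col).

    The image is band-passed (Gaussian at ``params.sigma`` minus a local
    background Gaussian at 2x cell width).  Pixels that are 3x3 local maxima
    with band-pass amplitude above ``params.prominence`` are candidates; a
    plateau of tied maxima collapses to its centroid.  Candidates are then
    accepted strongest-first subject to a Euclidean minimum separation of
    ``params.separation``.  Output is sorted in raster (row, col) order.
    """
    if image.ndim != 2:
        raise ValueError("expected a single-channel image")
    if params.separation >= min(image.shape):
        raise ValueError("minimum separation exceeds the image size")
    img = image.astype(np.float64)
    fine = ndimage.gaussian_filter(img, params.sigma)
    background = ndimage.gaussian_filter(img, 2.0 * params.cell_width_px)
    band = fine - background

    is_max = (band == ndimage.maximum_filter(band, size=3)) & (band >= params.prominence)
    labels, n_plateaus = ndimage.label(is_max)
    if n_plateaus == 0:
        return np.empty((0, 2))
    centers = np.asarray(ndimage.center_of_mass(is_max, labels, range(1, n_plateaus + 1)))
    heights = np.asarray(
        ndimage.maximum(band, labels, range(1, n_plateaus + 1)), dtype=float
    )
    # strongest first; ties broken in raster order for determinism
    order = np.lexsort((centers[:, 1], centers[:, 0], -heights))
    centers = centers[order]
    accepted: list[np.ndarray] = []
    tree: cKDTree | None = None
    pending: list[np.ndarray] = []
    for c in centers:
        ok = True
        if tree is not None and tree.query_ball_point(c, params.separation):
            ok = False
        if ok:
            for a in pending:
                if np.hypot(*(c - a)) < params.separation:
                    ok = False
                    break
        if ok:
            pending.append(c)
            if len(pending) >= 256:  # amortize KDTree rebuilds
                accepted.extend(pending)
                tree = cKDTree(np.asarray(accepted))
                pending = []
    accepted.extend(pending)
    pts = np.asarray(accepted)
    return pts[np.lexsort((pts[:, 1], pts[:, 0]))]


def estimate_density(
    points: np.ndarray,
    area_mm2: float,
    method: Literal["calcein_maxima", "nuclei_channel"] = "calcein_maxima",
) -> DensityEstimate:
    """Cell density in cells/mm**2 from detected points in a counted region."""
    if area_mm2 <= 0:
        raise ValueError("counted area must be positive")
    return DensityEstimate(n_cells=len(points), area_mm2=float(area_mm2), method=method)


def points_in_rect(
    points: np.ndarray, row_range: tuple[int, int], col_range: tuple[int, int]
) -> np.ndarray:
    """Subset of (row, col) points inside a half-open rectangle."""
    if len(points) == 0:
        return points
    keep = (
        (points[:, 0] >= row_range[0])
        & (points[:, 0] < row_range[1])
        & (points[:, 1] >= col_range[0])
        & (points[:, 1] < col_range[1])
    )
    return points[keep]


def neighbor_analysis(
    centroids: np.ndarray,
    bounds: tuple[float, float, float, float] | None = None,
    min_ridge_fraction: float = 1e-3,
) -> HexagonalityResult:
    """Voronoi neighbor counts and hexagonality of a centroid set.

    Two cells are neighbors when their Voronoi regions share an edge of
    meaningful length: shared edges shorter than ``min_ridge_fraction`` of
    the median nearest-neighbor spacing are point contacts (e.g. the broken
    four-corner degeneracy of a near-square arrangement), not adjacencies.
    Cells whose region is unbounded or has a vertex outside ``bounds``
    (xmin, xmax, ymin, ymax; default the centroid bounding box) touch the
    field border and are excluded from the hexagonality percentage, though
    they still count as neighbors of interior cells.
    """
    pts = np.asarray(centroids, dtype=float)
    if len(pts) < 4:
        raise ValueError("need at least 4 centroids for a neighbor analysis")
    try:
        vor = Voronoi(pts)
    except Exception as exc:  # qhull degenerate input
        raise ValueError(f"degenerate centroid configuration: {exc}") from None
    if bounds is None:
        bounds = (pts[:, 0].min(), pts[:, 0].max(), pts[:, 1].min(), pts[:, 1].max())
    xmin, xmax, ymin, ymax = bounds

    nn, _ = cKDTree(pts).query(pts, k=2)
    min_len = min_ridge_fraction * float(np.median(nn[:, 1]))
    counts = np.zeros(len(pts), dtype=int)
    n_edges = 0
    for (a, b), rv in zip(vor.ridge_points, vor.ridge_vertices):
        if -1 not in rv:
            v0, v1 = vor.vertices[rv]
            if np.hypot(*(v0 - v1)) <= min_len:
                continue
        counts[a] += 1
        counts[b] += 1
        n_edges += 1

    interior = np.ones(len(pts), dtype=bool)
    for i, region_idx in enumerate(vor.point_region):
        region = vor.regions[region_idx]
        if -1 in region or len(region) == 0:
            interior[i] = False
            continue
        verts = vor.vertices[region]
        if (
            verts[:, 0].min() < xmin or verts[:, 0].max() > xmax
            or verts[:, 1].min() < ymin or verts[:, 1].max() > ymax
        ):
            interior[i] = False
    if interior.sum() == 0:
        raise ValueError("no interior cells: field too small for neighbor analysis")
    hexagonality = 100.0 * float((counts[interior] == 6).mean())
    return HexagonalityResult(
        n_interior=int(interior.sum()),
        neighbor_counts=counts[interior],
        hexagonality_pct=hexagonality,
        n_edges=n_edges,
        all_neighbor_counts=counts,
    )


def area_cov(areas: np.ndarray) -> float:
    """Coefficient of variation of cell areas (population SD / mean)."""
    a = np.asarray(areas, dtype=float)
    if len(a) < 2:
        raise ValueError("need at least 2 cell areas")
    if np.any(a <= 0):
        raise ValueError("cell areas must be positive")
    return float(a.std() / a.mean())


def dead_fraction(
    live_points: np.ndarray, dead_points: np.ndarray, matching_radius: float
) -> float:
    """Percent dead cells among live+dead detections from co-registered channels.

    A live detection closer than ``matching_radius`` to any dead detection is
    the same cell seen in both channels; the conflict resolves to dead (a
    calcein-positive but ethidium-positive cell is dying).
    """
    live = np.asarray(live_points, dtype=float).reshape(-1, 2)
    dead = np.asarray(dead_points, dtype=float).reshape(-1, 2)
    if len(live) == 0 and len(dead) == 0:
        raise ValueError("no detections in either channel")
    if len(dead) == 0:
        return 0.0
    if len(live):
        d, _ = cKDTree(dead).query(live)
        live = live[d > matching_radius]
    return 100.0 * len(dead) / (len(live) + len(dead))


def match_points(
    detected: np.ndarray, truth: np.ndarray, radius: float
) -> tuple[list[tuple[int, int]], float, float]:
    """Greedy nearest-pair matching within a radius; returns (pairs, recall, precision)."""
    det = np.asarray(detected, dtype=float).reshape(-1, 2)
    tru = np.asarray(truth, dtype=float).reshape(-1, 2)
    if len(det) == 0 or len(tru) == 0:
        return [], 0.0, 0.0
    tree = cKDTree(tru)
    cand: list[tuple[float, int, int]] = []
    for i, p in enumerate(det):
        for j in tree.query_ball_point(p, radius):
            cand.append((float(np.hypot(*(p - tru[j]))), i, j))
    cand.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in cand:
        if i in used_d or j in used_t:
            continue
        pairs.append((i, j))
        used_d.add(i)
        used_t.add(j)
    return pairs, len(pairs) / len(tru), len(pairs) / len(det)
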
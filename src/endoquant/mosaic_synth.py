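"""Ground-truthed synthetic corneal endothelial mosaics and their fluorescence renders.

The corneal endothelium is a quasi-hexagonal monolayer of cells on Descemet
membrane (DM).  A DMEK graft is an 8-mm trephined disc of that monolayer.
This module simulates such a graft as a centroidal Voronoi tessellation of a
disc, lets the caller inflict surgically realistic damage (incarceration
wedges, ejection streaks, tears, a triangular orientation mark, a non-viable
peripheral rim), and renders the result as an 8-bit calcein-AM fluorescence
image: bright viable cytoplasm with brighter nuclei, dim attached dead cells
only marginally above bare DM, and near-black bare membrane.

Every stochastic operation takes an explicit seed; identical (spec, seed)
pairs produce byte-identical ground truth and images.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import shapely
from scipy.ndimage import gaussian_filter
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import Point, Polygon

__all__ = [
    "MosaicSpec",
    "RenderSpec",
    "GroundTruthMosaic",
    "DamageSpec",
    "PeripheralRim",
    "Wedge",
    "Streaks",
    "PolygonPatch",
    "Tear",
    "OrientationMark",
    "generate_mosaic",
    "apply_damage",
    "benchmark_rim_damage",
    "calibrate_streak_width",
    "staining_intensity",
    "calibrate_render",
    "render",
    "rasterize_states",
    "DECAY_RATE_PER_H",
    "PEAK_TIME_H",
    "DOSE_SLOPE",
]

# Cell states
VIABLE = 0
DEAD_ATTACHED = 1
ABSENT = 2
STATE_NAMES = {VIABLE: "viable", DEAD_ATTACHED: "dead_attached", ABSENT: "absent"}

# Nucleus radius as a fraction of the equivalent cell radius.
NUCLEUS_RADIUS_RATIO = 0.27
# Nucleus-center jitter as a fraction of the equivalent cell radius.
NUCLEUS_JITTER_RATIO = 0.15
# Mean intensity of the medium outside the graft disc (anterior chamber).
BACKGROUND_MEAN = 0.0
# Brightness of nuclei in the companion (Hoechst-like / ethidium-like) channels.
COUNTERSTAIN_NUCLEUS_MEAN = 200.0

# Staining kinetics: fluorescence peaks 2 h after incubation and then decays
# exponentially at a storage-dependent rate.  The rates are fixed so that the
# peak intensity of 109 falls to 36 by 24 h in organ culture at 37 degC, and
# 99 falls to 89 by 7 days in Optisol at 4 degC.
PEAK_TIME_H = 2.0
DECAY_RATE_PER_H = {
    "organ_culture_37C": math.log(109.0 / 36.0) / 22.0,
    "optisol_4C": math.log(99.0 / 89.0) / 166.0,
}
# Relative fluorescence per uM of calcein AM: unit intensity 100 at the
# 2.67 uM working dose.
DOSE_SLOPE = 100.0 / 2.67

StorageCondition = Literal["organ_culture_37C", "optisol_4C"]
DamageMode = Literal["bare_dm", "dead_attached"]


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MosaicSpec:
    """Geometry of a synthetic endothelial graft.

    Parameters
    ----------
    graft_diameter_mm:
        Trephine diameter; clinical DMEK grafts are punched at 8 mm.
    target_density:
        Endothelial cell density in cells/mm**2.  Healthy donor tissue spans
        roughly 1700-3600 cells/mm**2.
    regularity:
        Number of Lloyd relaxation iterations toward a centroidal Voronoi
        tessellation.  0 gives a Poisson-Voronoi mosaic; ~10 gives the
        quasi-hexagonal regularity of a healthy endothelium.
    pixel_size_um:
        Physical pixel pitch of the rendered image (um per pixel).  5 um/px
        puts an 8-mm graft at ~1600 px across (global view); 0.8 um/px is a
        high-magnification field.
    image_size:
        Image side in pixels; defaults to the graft diameter plus a margin.
    rng_seed:
        Seed for cell-seed placement and nucleus jitter.
    """

    graft_diameter_mm: float = 8.0
    target_density: float = 2500.0
    regularity: int = 10
    pixel_size_um: float = 5.0
    image_size: int | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.graft_diameter_mm <= 0:
            raise ValueError("graft_diameter_mm must be positive")
        if self.target_density <= 0:
            raise ValueError("target_density must be positive")
        if self.regularity < 0 or int(self.regularity) != self.regularity:
            raise ValueError("regularity must be a non-negative integer")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.image_size is not None:
            needed = self.graft_diameter_mm * 1000.0 / self.pixel_size_um
            if needed > self.image_size:
                raise ValueError(
                    f"graft ({needed:.0f} px) does not fit in image_size={self.image_size}"
                )

    @property
    def radius_um(self) -> float:
        return self.graft_diameter_mm * 500.0

    @property
    def resolved_image_size(self) -> int:
        if self.image_size is not None:
            return int(self.image_size)
        return int(math.ceil(self.graft_diameter_mm * 1000.0 / self.pixel_size_um)) + 16


@dataclass(frozen=True)
class RenderSpec:
    """Photometric model of an 8-bit calcein-AM fluorescence image.

    Region means are grey levels on the 0-255 scale.  A Gaussian PSF of
    ``psf_sigma`` pixels blurs the piecewise-constant mosaic; zero-mean
    Gaussian read noise of SD ``noise_sigma`` is added after the blur, so a
    uniform patch has SD exactly ``noise_sigma``.  A fraction
    ``undetectable_nucleus_fraction`` of viable cells is rendered without
    nuclear contrast (their nucleus takes the cytoplasm mean), emulating
    cells whose nuclear calcein signal does not exceed the cytoplasm.
    """

    cytoplasm_mean: float = 100.0
    nucleus_mean: float = 130.0
    dead_attached_mean: float = 9.0
    bare_dm_mean: float = 6.0
    psf_sigma: float = 1.2
    noise_sigma: float = 6.0
    undetectable_nucleus_fraction: float = 0.075
    dose_um: float = 2.67
    time_since_stain_h: float = 2.0
    storage: StorageCondition = "optisol_4C"

    def __post_init__(self) -> None:
        for name in ("cytoplasm_mean", "nucleus_mean", "dead_attached_mean", "bare_dm_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 255.0:
                raise ValueError(f"{name}={v} outside the 8-bit range [0, 255]")
        if self.dead_attached_mean <= self.bare_dm_mean:
            raise ValueError("dead_attached_mean must exceed bare_dm_mean")
        if self.nucleus_mean < self.cytoplasm_mean:
            raise ValueError("nucleus_mean must be >= cytoplasm_mean")
        if self.psf_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("psf_sigma and noise_sigma must be non-negative")
        if not 0.0 <= self.undetectable_nucleus_fraction <= 1.0:
            raise ValueError("undetectable_nucleus_fraction must be in [0, 1]")
        if self.dose_um < 0 or self.time_since_stain_h < 0:
            raise ValueError("dose and time since staining must be non-negative")
        if self.storage not in DECAY_RATE_PER_H:
            raise ValueError(f"unknown storage condition {self.storage!r}")


# --------------------------------------------------------------------------
# damage primitives
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class _Primitive:
    mode: DamageMode = "bare_dm"

    def footprint(self, radius_um: float) -> Polygon:  # pragma: no cover - abstract
        raise NotImplementedError

    @property
    def name(self) -> str:
        return type(self).__name__.lower()


@dataclass(frozen=True)
class PeripheralRim(_Primitive):
    """Annular band of damage at the graft edge (trephination / handling)."""

    width_um: float = 400.0

    def footprint(self, radius_um: float) -> Polygon:
        outer = Point(0, 0).buffer(radius_um, quad_segs=180)
        inner = Point(0, 0).buffer(max(radius_um - self.width_um, 0.0), quad_segs=180)
        return outer.difference(inner)


@dataclass(frozen=True)
class Wedge(_Primitive):
    """Sector of damage reaching in from the edge, as from wound incarceration."""

    center_angle_deg: float = 0.0
    angular_width_deg: float = 60.0
    radial_depth_um: float = 1500.0

    def footprint(self, radius_um: float) -> Polygon:
        a0 = math.radians(self.center_angle_deg - self.angular_width_deg / 2.0)
        a1 = math.radians(self.center_angle_deg + self.angular_width_deg / 2.0)
        angles = np.linspace(a0, a1, max(int(self.angular_width_deg) + 2, 8))
        arc = np.c_[np.cos(angles), np.sin(angles)] * (radius_um * 1.001)
        sector = Polygon(np.vstack([[0.0, 0.0], arc]))
        inner = Point(0, 0).buffer(
            max(radius_um - self.radial_depth_um, 0.0), quad_segs=180
        )
        return sector.difference(inner)


@dataclass(frozen=True)
class Streaks(_Primitive):
    """Parallel linear bands of cell loss (touch/ejection trauma)."""

    count: int = 5
    width_um: float = 150.0
    orientation_deg: float = 30.0
    spacing_um: float = 900.0

    def footprint(self, radius_um: float) -> Polygon:
        half_len = radius_um * 1.5
        bands = []
        theta = math.radians(self.orientation_deg)
        u = np.array([math.cos(theta), math.sin(theta)])  # along the streak
        v = np.array([-math.sin(theta), math.cos(theta)])  # across
        for i in range(self.count):
            offset = (i - (self.count - 1) / 2.0) * self.spacing_um
            c = v * offset
            h = self.width_um / 2.0
            corners = [
                c + u * half_len + v * h,
                c + u * half_len - v * h,
                c - u * half_len - v * h,
                c - u * half_len + v * h,
            ]
            bands.append(Polygon(corners))
        return shapely.unary_union(bands)


@dataclass(frozen=True)
class PolygonPatch(_Primitive):
    """Arbitrary polygonal damage footprint (vertices in um from graft center)."""

    vertices: tuple[tuple[float, float], ...] = ()

    def footprint(self, radius_um: float) -> Polygon:
        if len(self.vertices) < 3:
            raise ValueError("polygon_patch needs at least 3 vertices")
        return Polygon(self.vertices)


@dataclass(frozen=True)
class Tear(_Primitive):
    """Tear along a polyline, gaping open by ``gape_um``."""

    polyline: tuple[tuple[float, float], ...] = ()
    gape_um: float = 120.0

    def footprint(self, radius_um: float) -> Polygon:
        if len(self.polyline) < 2:
            raise ValueError("tear needs a polyline of at least 2 points")
        return shapely.LineString(self.polyline).buffer(self.gape_um / 2.0)


@dataclass(frozen=True)
class OrientationMark(_Primitive):
    """Triangular peripheral mark cut to disambiguate graft orientation."""

    vertices: tuple[tuple[float, float], tuple[float, float], tuple[float, float]] = (
        (3600.0, -350.0),
        (3600.0, 350.0),
        (4050.0, 0.0),
    )

    def footprint(self, radius_um: float) -> Polygon:
        return Polygon(self.vertices)


@dataclass(frozen=True)
class DamageSpec:
    """Ordered list of damage primitives; later primitives override earlier ones."""

    primitives: tuple[_Primitive, ...] = ()

    def __iter__(self):
        return iter(self.primitives)

    def __len__(self) -> int:
        return len(self.primitives)


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------


@dataclass
class GroundTruthMosaic:
    """The simulation's truth record: one row of arrays per cell.

    Coordinates are physical micrometres from the graft center; the pixel
    grid maps ``x_um = (col + 0.5) * pixel_size - image_size * pixel_size / 2``
    (row-major, origin top-left).
    """

    spec: MosaicSpec
    points: np.ndarray  # (N, 2) Voronoi sites, um
    polygons: list[np.ndarray]  # per-cell polygon vertices, um
    centroids: np.ndarray  # (N, 2) um
    areas_um2: np.ndarray  # (N,)
    nucleus_centers: np.ndarray  # (N, 2) um
    nucleus_radii_um: np.ndarray  # (N,)
    states: np.ndarray  # (N,) int codes
    damage_footprints: list[tuple[str, Polygon, str]] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.states)

    @property
    def radius_um(self) -> float:
        return self.spec.radius_um

    @property
    def graft_area_mm2(self) -> float:
        return float(self.areas_um2.sum()) / 1e6

    @property
    def true_viable_fraction(self) -> float:
        """Viable cell area divided by total graft (tessellated) area."""
        total = self.areas_um2.sum()
        return float(self.areas_um2[self.states == VIABLE].sum() / total)

    @property
    def live_density(self) -> float:
        """Density of viable cells over the whole graft, cells/mm**2."""
        return float((self.states == VIABLE).sum() / self.graft_area_mm2)

    @property
    def center_px(self) -> tuple[float, float]:
        half = self.spec.resolved_image_size / 2.0
        return (half, half)

    @property
    def radius_px(self) -> float:
        return self.radius_um / self.spec.pixel_size_um

    def state_counts(self) -> dict[str, int]:
        return {
            name: int((self.states == code).sum()) for code, name in STATE_NAMES.items()
        }

    def pixel_centers_um(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical coordinates (x, y) of every pixel center, um from graft center."""
        n = self.spec.resolved_image_size
        px = self.spec.pixel_size_um
        coords = (np.arange(n) + 0.5) * px - n * px / 2.0
        x, y = np.meshgrid(coords, coords)  # x varies along columns
        return x, y


# --------------------------------------------------------------------------
# polygon helpers (vectorized over scipy's ragged Voronoi regions)
# --------------------------------------------------------------------------


def _region_arrays(vor: Voronoi, n_real: int) -> tuple[np.ndarray, np.ndarray]:
    """Flattened vertex indices and per-region lengths for the first n_real sites."""
    regions = [vor.regions[vor.point_region[i]] for i in range(n_real)]
    lengths = np.array([len(r) for r in regions])
    if lengths.min() < 3 or any(-1 in r for r in regions):
        raise RuntimeError("unbounded Voronoi region among graft cells")
    flat = np.concatenate(regions)
    return flat, lengths


def _polygon_centroids_areas(
    vertices: np.ndarray, flat: np.ndarray, lengths: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Shoelace centroids and areas of ragged polygons, fully vectorized."""
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    pts = vertices[flat]
    nxt = np.arange(len(flat)) + 1
    ends = np.cumsum(lengths) - 1
    nxt[ends] = starts  # wrap each polygon
    p0, p1 = pts, pts[nxt]
    cross = p0[:, 0] * p1[:, 1] - p1[:, 0] * p0[:, 1]
    a2 = np.add.reduceat(cross, starts)
    cx = np.add.reduceat((p0[:, 0] + p1[:, 0]) * cross, starts)
    cy = np.add.reduceat((p0[:, 1] + p1[:, 1]) * cross, starts)
    areas = np.abs(a2) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        centroids = np.c_[cx, cy] / (3.0 * a2)[:, None]
    return centroids, areas


def _mirror_points(points: np.ndarray, radius: float, band: float) -> np.ndarray:
    """Reflect near-boundary points across the circle so edge cells close at the rim."""
    r = np.hypot(points[:, 0], points[:, 1])
    near = r > radius - band
    p = points[near]
    rn = r[near]
    mirrored = p * ((2.0 * radius - rn) / np.maximum(rn, 1e-9))[:, None]
    return mirrored


def _voronoi_with_mirrors(points: np.ndarray, radius: float, band: float) -> Voronoi:
    mirrors = _mirror_points(points, radius, band)
    # Four distant sentinels guarantee every real region is bounded.
    far = radius * 20.0
    sentinels = np.array([[far, 0.0], [-far, 0.0], [0.0, far], [0.0, -far]])
    return Voronoi(np.vstack([points, mirrors, sentinels]))


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------


def generate_mosaic(spec: MosaicSpec) -> GroundTruthMosaic:
    """Generate a ground-truthed endothelial mosaic on a disc.

    Seeds ``N = round(density * pi * r**2)`` points uniformly in the graft
    disc and applies ``spec.regularity`` Lloyd iterations toward a centroidal
    Voronoi tessellation (near-boundary sites are mirrored across the circle
    so edge cells close at the rim).  All cells start viable; each nucleus
    sits at its cell centroid with a jitter of at most 15% of the equivalent
    cell radius.
    """
    radius = spec.radius_um
    area_mm2 = math.pi * (spec.graft_diameter_mm / 2.0) ** 2
    n_cells = int(round(spec.target_density * area_mm2))
    if n_cells < 50:
        raise ValueError(
            f"degenerate mosaic: only {n_cells} cells at {spec.target_density}/mm^2 "
            f"on a {spec.graft_diameter_mm} mm disc (need >= 50)"
        )
    rng = np.random.default_rng(spec.rng_seed)
    u = rng.random(n_cells)
    theta = rng.random(n_cells) * 2.0 * math.pi
    r = radius * np.sqrt(u)
    points = np.c_[r * np.cos(theta), r * np.sin(theta)]

    spacing = 1000.0 / math.sqrt(spec.target_density)  # mean inter-cell distance, um
    band = 3.0 * spacing
    for _ in range(int(spec.regularity)):
        vor = _voronoi_with_mirrors(points, radius, band)
        flat, lengths = _region_arrays(vor, n_cells)
        centroids, _ = _polygon_centroids_areas(vor.vertices, flat, lengths)
        # Keep relaxed sites strictly inside the disc.
        rr = np.hypot(centroids[:, 0], centroids[:, 1])
        out = rr >= radius
        if out.any():
            centroids[out] *= (radius * 0.999 / rr[out])[:, None]
        points = centroids

    vor = _voronoi_with_mirrors(points, radius, band)
    flat, lengths = _region_arrays(vor, n_cells)
    centroids, areas = _polygon_centroids_areas(vor.vertices, flat, lengths)

    # Exact polygons: clip boundary-crossing cells to the disc.
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    polygons: list[np.ndarray] = []
    vert_r = np.hypot(vor.vertices[flat][:, 0], vor.vertices[flat][:, 1])
    disc = Point(0, 0).buffer(radius, quad_segs=360)
    for i in range(n_cells):
        sl = slice(starts[i], starts[i] + lengths[i])
        poly = vor.vertices[flat[sl]]
        if vert_r[sl].max() > radius:
            clipped = Polygon(poly).intersection(disc)
            if clipped.geom_type == "MultiPolygon":
                clipped = max(clipped.geoms, key=lambda g: g.area)
            poly = np.asarray(clipped.exterior.coords[:-1])
            areas[i] = clipped.area
            c = clipped.centroid
            centroids[i] = (c.x, c.y)
        polygons.append(poly)

    achieved = n_cells / area_mm2
    if abs(achieved - spec.target_density) / spec.target_density > 0.05:
        raise RuntimeError("achieved density deviates >5% from target")

    cell_radii = np.sqrt(areas / math.pi)
    jitter_r = rng.random(n_cells) * NUCLEUS_JITTER_RATIO * cell_radii
    jitter_a = rng.random(n_cells) * 2.0 * math.pi
    nucleus_centers = centroids + np.c_[
        jitter_r * np.cos(jitter_a), jitter_r * np.sin(jitter_a)
    ]

    return GroundTruthMosaic(
        spec=spec,
        points=points,
        polygons=polygons,
        centroids=centroids,
        areas_um2=areas,
        nucleus_centers=nucleus_centers,
        nucleus_radii_um=NUCLEUS_RADIUS_RATIO * cell_radii,
        states=np.full(n_cells, VIABLE, dtype=np.int8),
    )


def apply_damage(gt: GroundTruthMosaic, damage: DamageSpec) -> GroundTruthMosaic:
    """Apply damage primitives; cells whose centroid falls in a footprint change state.

    ``bare_dm`` primitives strip cells off the membrane (state ``absent``);
    ``dead_attached`` primitives kill cells in place.  Primitives compose in
    order, later ones overriding earlier ones; footprints are clipped to the
    graft disc and retained for per-region damage attribution.  An empty
    DamageSpec is the identity.
    """
    radius = gt.radius_um
    disc = Point(0, 0).buffer(radius, quad_segs=360)
    states = gt.states.copy()
    footprints = list(gt.damage_footprints)
    for prim in damage:
        fp = prim.footprint(radius).intersection(disc)
        if fp.is_empty or fp.area == 0.0:
            warnings.warn(
                f"damage primitive {prim.name} lies entirely outside the graft; ignored",
                stacklevel=2,
            )
            continue
        inside = shapely.contains_xy(fp, gt.centroids[:, 0], gt.centroids[:, 1])
        states[inside] = ABSENT if prim.mode == "bare_dm" else DEAD_ATTACHED
        footprints.append((prim.name, fp, prim.mode))
    return GroundTruthMosaic(
        spec=gt.spec,
        points=gt.points,
        polygons=gt.polygons,
        centroids=gt.centroids,
        areas_um2=gt.areas_um2,
        nucleus_centers=gt.nucleus_centers,
        nucleus_radii_um=gt.nucleus_radii_um,
        states=states,
        damage_footprints=footprints,
    )


def calibrate_streak_width(
    gt: GroundTruthMosaic,
    target_viable_fraction: float,
    count: int = 5,
    orientation_deg: float = 30.0,
    spacing_um: float | None = None,
    mode: DamageMode = "bare_dm",
    tol: float = 0.005,
) -> Streaks:
    """Find a streak width leaving the requested true viable-area fraction.

    Bisects the band width: wider streaks capture a superset of cell
    centroids, so the viable fraction is monotone non-increasing in width.
    """
    if not 0.0 < target_viable_fraction < 1.0:
        raise ValueError("target_viable_fraction must be in (0, 1)")
    if spacing_um is None:
        spacing_um = 2.0 * gt.radius_um / (count + 1)

    def frac(width: float) -> float:
        s = Streaks(count=count, width_um=width, orientation_deg=orientation_deg,
                    spacing_um=spacing_um, mode=mode)
        return apply_damage(gt, DamageSpec((s,))).true_viable_fraction

    lo, hi = 0.0, spacing_um * 0.98
    if frac(hi) > target_viable_fraction:
        raise ValueError("streak pattern cannot remove enough area; increase count")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        f = frac(mid)
        if abs(f - target_viable_fraction) <= tol:
            lo = hi = mid
            break
        if f > target_viable_fraction:
            lo = mid
        else:
            hi = mid
    width = 0.5 * (lo + hi)
    return Streaks(count=count, width_um=width, orientation_deg=orientation_deg,
                   spacing_um=spacing_um, mode=mode)


def benchmark_rim_damage(
    rim_width_um: float = 400.0, dead_band_fraction: float = 0.5
) -> DamageSpec:
    """Standard non-viable graft periphery: bare DM edged by attached dead cells.

    The outer ``(1 - dead_band_fraction)`` of the rim is bare membrane
    (cells scraped off at trephination/handling); the inner band keeps its
    cells attached but dead, the way bare cores are surrounded by
    ethidium-positive cells in real grafts.
    """
    return DamageSpec(
        (
            PeripheralRim(width_um=rim_width_um, mode="dead_attached"),
            PeripheralRim(
                width_um=rim_width_um * (1.0 - dead_band_fraction), mode="bare_dm"
            ),
        )
    )


# --------------------------------------------------------------------------
# staining kinetics
# --------------------------------------------------------------------------


def staining_intensity(
    dose_um: float, time_h: float, storage: StorageCondition = "optisol_4C"
) -> float:
    """Relative calcein fluorescence for a given dose, time and storage.

    Linear in dose; rises linearly to a peak at 2 h, then decays
    exponentially at a storage-dependent rate (fast in organ culture at
    37 degC, slow in Optisol at 4 degC).
    """
    if dose_um < 0 or time_h < 0:
        raise ValueError("dose and time must be non-negative")
    if storage not in DECAY_RATE_PER_H:
        raise ValueError(f"unknown storage condition {storage!r}")
    rise = min(time_h, PEAK_TIME_H) / PEAK_TIME_H
    decay = math.exp(-DECAY_RATE_PER_H[storage] * max(0.0, time_h - PEAK_TIME_H))
    return DOSE_SLOPE * dose_um * rise * decay


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------


def rasterize_states(gt: GroundTruthMosaic) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel owning-cell label, in-disc mask, and owner state raster.

    Ownership inside the disc is nearest-site (exactly the Voronoi cell).
    Pixels outside the graft disc get label -1.
    """
    x, y = gt.pixel_centers_um()
    inside = x * x + y * y <= gt.radius_um**2
    labels = np.full(inside.shape, -1, dtype=np.int64)
    pts = np.c_[x[inside], y[inside]]
    _, idx = cKDTree(gt.points).query(pts)
    labels[inside] = idx
    state_map = np.full(inside.shape, -1, dtype=np.int8)
    state_map[inside] = gt.states[idx]
    return labels, inside, state_map


def render(
    gt: GroundTruthMosaic,
    spec: RenderSpec,
    seed: int = 0,
    channels: Sequence[str] = ("calcein",),
) -> dict[str, np.ndarray]:
    """Render a mosaic to 8-bit fluorescence channel(s).

    ``calcein``: viable cytoplasm at ``cytoplasm_mean`` with nuclei at
    ``nucleus_mean`` (a seeded fraction of viable cells lacks nuclear
    contrast), dead attached cells flat at ``dead_attached_mean``, bare DM at
    ``bare_dm_mean``, background outside the disc near black.  The whole
    scene scales with ``staining_intensity(dose, time, storage)`` relative to
    the 2.67-uM, 2-h reference.  ``nuclei``: all attached cells' nuclei
    (Hoechst-like).  ``dead``: dead-attached nuclei (ethidium-like).
    Gaussian PSF blur, then seeded additive Gaussian noise, clip to [0, 255],
    quantize to uint8.
    """
    rng = np.random.default_rng(seed)
    labels, inside, state_map = rasterize_states(gt)
    n = gt.spec.resolved_image_size
    x, y = gt.pixel_centers_um()

    undetectable = rng.random(gt.n_cells) < spec.undetectable_nucleus_fraction

    scale = staining_intensity(spec.dose_um, spec.time_since_stain_h, spec.storage) / (
        staining_intensity(2.67, PEAK_TIME_H, spec.storage)
    )

    # squared distance from each in-disc pixel to its own cell's nucleus
    idx = labels[inside]
    dxn = x[inside] - gt.nucleus_centers[idx, 0]
    dyn = y[inside] - gt.nucleus_centers[idx, 1]
    in_nucleus = dxn * dxn + dyn * dyn <= gt.nucleus_radii_um[idx] ** 2

    out: dict[str, np.ndarray] = {}
    for ch in channels:
        img = np.full((n, n), BACKGROUND_MEAN, dtype=np.float64)
        if ch == "calcein":
            base = np.choose(
                gt.states,
                [spec.cytoplasm_mean, spec.dead_attached_mean, spec.bare_dm_mean],
            )
            vals = base[idx]
            nuc = in_nucleus & (gt.states[idx] == VIABLE) & ~undetectable[idx]
            vals = np.where(nuc, spec.nucleus_mean, vals)
            img[inside] = vals * scale
        elif ch == "nuclei":
            mark = in_nucleus & (gt.states[idx] != ABSENT)
            img[inside] = np.where(mark, COUNTERSTAIN_NUCLEUS_MEAN, 0.0)
        elif ch == "dead":
            mark = in_nucleus & (gt.states[idx] == DEAD_ATTACHED)
            img[inside] = np.where(mark, COUNTERSTAIN_NUCLEUS_MEAN, 0.0)
        else:
            raise ValueError(f"unknown channel {ch!r}")
        if spec.psf_sigma > 0:
            img = gaussian_filter(img, spec.psf_sigma)
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
        out[ch] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return out


# --------------------------------------------------------------------------
# photometric calibration
# --------------------------------------------------------------------------


class CalibrationError(RuntimeError):
    """Raised when render targets cannot be met by any noise/background level."""


def calibrate_render(
    target_contrast: float = 15.41,
    target_snr: float = 14.27,
    base: RenderSpec | None = None,
    mosaic_spec: MosaicSpec | None = None,
    rim_width_um: float = 400.0,
    dead_band_fraction: float = 0.5,
    patch_side: int = 25,
    self_check_tol: float = 0.05,
) -> RenderSpec:
    """Solve for noise_sigma and bare_dm_mean hitting photometric targets.

    ``target_contrast`` is the expected viable-patch mean divided by the
    expected peripheral (non-viable) patch mean; ``target_snr`` the expected
    viable-patch mean over its pixel SD.  Because read noise is added after
    the PSF, viable-patch variance decomposes exactly as structural variance
    (nucleus/cytoplasm texture, measured on a noise-free reference render)
    plus ``noise_sigma**2``; the SNR target then gives ``noise_sigma`` in
    closed form.  The peripheral mean is affected by zero-clipping and
    quantization, so ``bare_dm_mean`` is refined by a damped fixed-point
    iteration against rendered rim patches (the periphery is modelled as in
    real grafts: an outer bare-DM band with an inner band of attached dead
    cells occupying ``dead_band_fraction`` of the rim width).  Calibration
    patches follow the same seeded sampling rule as downstream photometry.
    The returned spec is verified by a rendered self-check within
    ``self_check_tol``.
    """
    if target_contrast <= 1.0 or target_snr <= 1.0:
        raise ValueError("contrast and SNR targets must exceed 1")
    base = base or RenderSpec()
    mosaic_spec = mosaic_spec or MosaicSpec(
        graft_diameter_mm=2.4, target_density=2500.0, pixel_size_um=5.0, rng_seed=1720
    )
    dead_offset = base.dead_attached_mean - base.bare_dm_mean

    from .photometry import sample_patches_in_mask

    gt = generate_mosaic(mosaic_spec)
    damaged = apply_damage(gt, benchmark_rim_damage(rim_width_um, dead_band_fraction))
    _, inside, state_map = rasterize_states(damaged)
    viable_mask = state_map == VIABLE
    nonviable_mask = inside & (state_map != VIABLE)

    def patch_stats(img: np.ndarray, mask: np.ndarray, seed: int) -> tuple[float, float]:
        # same seeded sampling rule as downstream contrast/SNR photometry:
        # non-overlapping patches fully inside the region
        patches = sample_patches_in_mask(img, mask, 50, side=patch_side, seed=seed,
                                         min_inside=1.0)
        means = [p.mean for p in patches]
        variances = [p.sd**2 for p in patches]
        return float(np.mean(means)), float(np.mean(variances))

    # 1) structural variance of viable tissue at zero noise
    quiet = replace(base, noise_sigma=0.0)
    img0 = render(damaged, quiet, seed=314159)["calcein"]
    m_v, var_struct = patch_stats(img0, viable_mask, 101)
    var_total = (m_v / target_snr) ** 2
    if var_total <= var_struct:
        raise CalibrationError(
            f"structural SD {math.sqrt(var_struct):.2f} already exceeds the SD "
            f"{math.sqrt(var_total):.2f} implied by SNR {target_snr}"
        )
    noise_sigma = math.sqrt(var_total - var_struct)

    # 2) fixed-point refinement of bare_dm_mean against rendered rim patches
    m_nv_target = m_v / target_contrast
    bare = max(m_nv_target - dead_offset * dead_band_fraction, 0.01)
    spec = base
    for _ in range(6):
        spec = replace(
            base,
            bare_dm_mean=bare,
            dead_attached_mean=bare + dead_offset,
            noise_sigma=noise_sigma,
        )
        img = render(damaged, spec, seed=271828)["calcein"]
        m_nv, _ = patch_stats(img, nonviable_mask, 102)
        step = m_nv_target - m_nv
        if abs(step) < 0.01:
            break
        bare = float(np.clip(bare + step, 0.0, 255.0))

    # 3) rendered self-check
    img = render(damaged, spec, seed=999331)["calcein"]
    m_v2, var_v2 = patch_stats(img, viable_mask, 103)
    m_nv2, _ = patch_stats(img, nonviable_mask, 104)
    got_contrast = m_v2 / m_nv2
    got_snr = m_v2 / math.sqrt(var_v2)
    if (
        abs(got_contrast - target_contrast) / target_contrast > self_check_tol
        or abs(got_snr - target_snr) / target_snr > self_check_tol
    ):
        raise CalibrationError(
            f"self-check failed: contrast {got_contrast:.2f} vs {target_contrast}, "
            f"SNR {got_snr:.2f} vs {target_snr}"
        )
    return spec
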
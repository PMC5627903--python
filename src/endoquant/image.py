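"""Image and ground-truth I/O: 8-bit single-channel TIFF/PNG, truth JSON.

Fluorescence rasters live on the 0-255 grey-level scale.  16-bit inputs are
rescaled to that range (the factor is logged); RGB inputs are rejected with
an instruction to extract a channel first.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .mosaic_synth import (
    STATE_NAMES,
    GroundTruthMosaic,
    MosaicSpec,
)

__all__ = ["FluorescenceImage", "read_image", "write_image",
           "ground_truth_to_json", "ground_truth_from_json"]

log = logging.getLogger("endoquant")

GROUND_TRUTH_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class FluorescenceImage:
    """A single-channel 8-bit fluorescence raster with its physical pixel pitch."""

    pixels: np.ndarray  # uint8
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("FluorescenceImage is single-channel 2-D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def read_image(path: str | Path, pixel_size_um: float | None = None) -> FluorescenceImage:
    """Read an 8- or 16-bit single-channel TIFF/PNG as a FluorescenceImage.

    16-bit data are rescaled onto 0-255 (by 1/257, logged).  The pixel size
    comes from the config/caller; a TIFF resolution tag is honored when
    present but an explicit ``pixel_size_um`` wins (logged on conflict).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise ValueError(
            f"{path.name} is multi-channel; extract the fluorescence channel first"
        )
    if arr.dtype == np.uint16:
        log.info("rescaling 16-bit %s to 8-bit (factor 1/257)", path.name)
        arr = (arr.astype(np.float64) / 257.0).round().astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise ValueError(f"unsupported dtype {arr.dtype}; expected uint8 or uint16")

    tag_px = None
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if res is not None and unit is not None and res.value[0]:
                num, den = res.value
                per_unit = num / den
                unit_um = {2: 25400.0, 3: 10000.0}.get(int(getattr(unit.value, "value", unit.value)))
                if unit_um and per_unit > 0:
                    tag_px = unit_um / per_unit
    if pixel_size_um is None:
        if tag_px is None:
            raise ValueError(
                f"{path.name} carries no resolution tag; supply pixel_size_um"
            )
        pixel_size_um = tag_px
    elif tag_px is not None and abs(tag_px - pixel_size_um) / pixel_size_um > 1e-3:
        log.info(
            "%s: TIFF tag pixel size %.3f um differs from configured %.3f um; using config",
            path.name, tag_px, pixel_size_um,
        )
    return FluorescenceImage(pixels=arr, pixel_size_um=float(pixel_size_um))


def write_image(path: str | Path, image: FluorescenceImage | np.ndarray,
                pixel_size_um: float | None = None) -> None:
    """Write an 8-bit single-channel TIFF (with resolution tags) or PNG."""
    path = Path(path)
    if isinstance(image, FluorescenceImage):
        arr, px = image.pixels, image.pixel_size_um
    else:
        arr, px = np.asarray(image, dtype=np.uint8), pixel_size_um
    if path.suffix.lower() in (".tif", ".tiff"):
        kwargs = {}
        if px:
            per_cm = 10000.0 / px
            kwargs = dict(resolution=(per_cm, per_cm), resolutionunit="CENTIMETER")
        tifffile.imwrite(path, arr, **kwargs)
    else:
        iio.imwrite(path, arr)


def ground_truth_to_json(gt: GroundTruthMosaic, path: str | Path) -> None:
    """Serialize a ground-truth mosaic (polygons in px, versioned schema)."""
    n = gt.spec.resolved_image_size
    px = gt.spec.pixel_size_um

    def to_px(xy: np.ndarray) -> list[list[float]]:
        out = np.asarray(xy, dtype=float) / px + n / 2.0
        return np.round(out, 3).tolist()

    cells = []
    for i in range(gt.n_cells):
        cells.append(
            {
                "polygon_px": to_px(gt.polygons[i]),
                "centroid_px": to_px(gt.centroids[i : i + 1])[0],
                "nucleus_px": to_px(gt.nucleus_centers[i : i + 1])[0],
                "nucleus_radius_px": round(float(gt.nucleus_radii_um[i] / px), 3),
                "area_um2": round(float(gt.areas_um2[i]), 3),
                "state": STATE_NAMES[int(gt.states[i])],
            }
        )
    doc = {
        "schema_version": GROUND_TRUTH_SCHEMA_VERSION,
        "spec": {
            "graft_diameter_mm": gt.spec.graft_diameter_mm,
            "target_density": gt.spec.target_density,
            "regularity": gt.spec.regularity,
            "pixel_size_um": gt.spec.pixel_size_um,
            "image_size": n,
            "rng_seed": gt.spec.rng_seed,
        },
        "graft": {"center_px": [n / 2.0, n / 2.0], "radius_px": gt.radius_px},
        "summary": {
            "n_cells": gt.n_cells,
            "state_counts": gt.state_counts(),
            "true_viable_fraction": gt.true_viable_fraction,
            "live_density_per_mm2": gt.live_density,
        },
        "damage_footprints": [
            {"name": name, "mode": mode, "wkt": poly.wkt}
            for name, poly, mode in gt.damage_footprints
        ],
        "cells": cells,
    }
    Path(path).write_text(json.dumps(doc))


def ground_truth_from_json(path: str | Path) -> GroundTruthMosaic:
    """Round-trip loader for the truth JSON written by :func:`ground_truth_to_json`."""
    import shapely.wkt

    doc = json.loads(Path(path).read_text())
    if doc["schema_version"] != GROUND_TRUTH_SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {doc['schema_version']}")
    s = doc["spec"]
    spec = MosaicSpec(
        graft_diameter_mm=s["graft_diameter_mm"], target_density=s["target_density"],
        regularity=s["regularity"], pixel_size_um=s["pixel_size_um"],
        image_size=s["image_size"], rng_seed=s["rng_seed"],
    )
    n, px = s["image_size"], s["pixel_size_um"]
    code = {v: k for k, v in STATE_NAMES.items()}

    def to_um(a) -> np.ndarray:
        return (np.asarray(a, dtype=float) - n / 2.0) * px

    cells = doc["cells"]
    polygons = [to_um(c["polygon_px"]) for c in cells]
    centroids = np.array([to_um(c["centroid_px"]) for c in cells])
    nuclei = np.array([to_um(c["nucleus_px"]) for c in cells])
    gt = GroundTruthMosaic(
        spec=spec,
        points=centroids.copy(),  # sites are not serialized; centroids approximate them
        polygons=polygons,
        centroids=centroids,
        areas_um2=np.array([c["area_um2"] for c in cells], dtype=float),
        nucleus_centers=nuclei,
        nucleus_radii_um=np.array([c["nucleus_radius_px"] for c in cells]) * px,
        states=np.array([code[c["state"]] for c in cells], dtype=np.int8),
        damage_footprints=[
            (d["name"], shapely.wkt.loads(d["wkt"]), d["mode"])
            for d in doc["damage_footprints"]
        ],
    )
    return gt
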
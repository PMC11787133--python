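"""Label maps: the geometric substrate of the pipeline.

A :class:`LabelMap` is a per-case class raster with classes
``{0: background, 1: tumor, 2: stroma, 3: TLS}`` and a physical resolution
(microns per pixel, mpp).  Coordinate convention: row-major grid, origin at
the top-left, 0-based indices; the physical coordinate of pixel ``(row, col)``
is its center, ``x = (col + 0.5) * mpp``, ``y = (row + 0.5) * mpp``.  All
areas in µm² and distances in µm follow from this convention.

Rasters are read/written as single-channel PNG or TIFF.  Polygon annotations
(GeoJSON feature collections with a ``class`` property) can be rasterized with
the pixel-center rule: a pixel is assigned to a polygon iff its center lies
inside it; later features overwrite earlier ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import shapely
import shapely.affinity
import tifffile
from PIL import Image
from shapely.geometry import shape as shapely_shape

from .errors import ConfigError, FormatError

VALID_CODES = (0, 1, 2, 3)
BACKGROUND, TUMOR, STROMA, TLS = VALID_CODES
CLASS_NAMES = {0: "background", 1: "tumor", 2: "stroma", 3: "tls"}
NAME_TO_CODE = {
    "background": 0,
    "tumor": 1,
    "stroma": 2,
    "tls": 3,
}


@dataclass
class LabelMap:
    """Class raster plus physical resolution for one case."""

    pixels: np.ndarray  # 2D uint8, values in {0,1,2,3}
    mpp: float  # microns per pixel, > 0
    case_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise FormatError("label map must be a non-empty 2D grid")
        bad = np.setdiff1d(np.unique(self.pixels), VALID_CODES)
        if bad.size:
            raise FormatError(f"unknown pixel class value(s) {bad.tolist()}")
        self.pixels = self.pixels.astype(np.uint8)
        if not (self.mpp is not None and self.mpp > 0):
            raise ConfigError(f"mpp must be positive, got {self.mpp!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def mask(self, code: int) -> np.ndarray:
        return self.pixels == code

    def pixel_centers_um(self, mask: np.ndarray) -> np.ndarray:
        """Physical (x, y) centers (µm) of the pixels selected by ``mask``."""
        rows, cols = np.nonzero(mask)
        return np.column_stack([(cols + 0.5) * self.mpp, (rows + 0.5) * self.mpp])

    def class_areas_um2(self) -> dict[str, float]:
        px_area = self.mpp**2
        return {
            CLASS_NAMES[c]: float(np.count_nonzero(self.pixels == c) * px_area)
            for c in VALID_CODES
        }


def read_labelmap(
    path: str | Path,
    mpp: float,
    case_id: Optional[str] = None,
    class_map: Optional[dict[int, int]] = None,
) -> LabelMap:
    """Read a single-channel raster (PNG/TIFF) into a LabelMap.

    ``class_map`` optionally remaps raw pixel values to the canonical codes
    (e.g. palette images with {0, 85, 170, 255}).  Unknown values raise
    :class:`FormatError`; a missing/invalid mpp raises :class:`ConfigError`.
    """
    if mpp is None or mpp <= 0:
        raise ConfigError(f"microns-per-pixel is required and must be > 0, got {mpp!r}")
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:  # single-channel stored with trailing axis
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise FormatError(f"{path.name}: expected single-channel raster, got shape {arr.shape}")
    if class_map is not None:
        out = np.full(arr.shape, 255, dtype=np.uint8)
        for raw, code in class_map.items():
            out[arr == raw] = code
        unmapped = np.setdiff1d(np.unique(arr), list(class_map))
        if unmapped.size:
            raise FormatError(f"{path.name}: pixel value(s) {unmapped.tolist()} not in class_map")
        arr = out
    return LabelMap(arr, mpp=mpp, case_id=case_id or path.stem)


def write_labelmap(lmap: LabelMap, path: str | Path) -> None:
    """Write the raster as single-channel PNG or TIFF (lossless)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, lmap.pixels)
    else:
        Image.fromarray(lmap.pixels, mode="L").save(path)


def rasterize_annotations(
    features,
    mpp: float,
    extent_um: Sequence[float],
    case_id: str = "",
    coords_in_pixels: bool = False,
) -> LabelMap:
    """Rasterize a GeoJSON feature collection into a LabelMap.

    Each feature must carry a ``class`` property in {tumor, stroma, TLS}
    (case-insensitive; "background" also accepted to punch holes).  Features
    are painted in listed order, later ones overwriting earlier ones.  A pixel
    is assigned iff its center lies inside the polygon.  Coordinates are in
    microns unless ``coords_in_pixels`` is set, in which case they are scaled
    by mpp first.

    ``features`` may be a path to a .geojson file, a parsed FeatureCollection
    dict, or a list of feature dicts.
    """
    if mpp is None or mpp <= 0:
        raise ConfigError(f"microns-per-pixel is required and must be > 0, got {mpp!r}")
    if isinstance(features, (str, Path)):
        with open(features) as fh:
            features = json.load(fh)
    if isinstance(features, dict):
        features = features.get("features", [])

    width_um, height_um = float(extent_um[0]), float(extent_um[1])
    ncols = int(round(width_um / mpp))
    nrows = int(round(height_um / mpp))
    if ncols <= 0 or nrows <= 0:
        raise ConfigError(f"extent {extent_um} too small for mpp={mpp}")
    pixels = np.zeros((nrows, ncols), dtype=np.uint8)

    # pixel-center coordinate grids in µm
    xs = (np.arange(ncols) + 0.5) * mpp
    ys = (np.arange(nrows) + 0.5) * mpp

    for feat in features:
        props = feat.get("properties") or {}
        cls = props.get("class") or props.get("label")
        if cls is None or str(cls).lower() not in NAME_TO_CODE:
            raise FormatError(f"feature has unknown class property {cls!r}")
        code = NAME_TO_CODE[str(cls).lower()]
        geom = shapely_shape(feat["geometry"])
        if coords_in_pixels:
            geom = shapely.affinity.scale(geom, xfact=mpp, yfact=mpp, origin=(0, 0))
        minx, miny, maxx, maxy = geom.bounds
        c0 = max(0, int(np.floor(minx / mpp - 0.5)))
        c1 = min(ncols, int(np.ceil(maxx / mpp + 0.5)))
        r0 = max(0, int(np.floor(miny / mpp - 0.5)))
        r1 = min(nrows, int(np.ceil(maxy / mpp + 0.5)))
        if c1 <= c0 or r1 <= r0:
            continue
        gx, gy = np.meshgrid(xs[c0:c1], ys[r0:r1])
        inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel()).reshape(gx.shape)
        block = pixels[r0:r1, c0:c1]
        block[inside] = code

    return LabelMap(pixels, mpp=mpp, case_id=case_id)
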
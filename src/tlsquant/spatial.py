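"""Spatial quantification: TLS extraction, margin distances, tiling, iTIL.

The pipeline measures, for each connected TLS component in a label map, its
area (µm²), its area centroid (µm), and the Euclidean distance from the
tumor invasive margin to that centroid — operationally, the distance to the
nearest tumor-class pixel center.  TLSs closer than the proximal cutoff
(default 500 µm) are *proximal* (pTLS); those between the proximal and
distal cutoffs (default 500–5000 µm, both ends included in the distal
window) are *distal* (dTLS); farther ones are excluded from analysis, as
are components smaller than the minimum area (default 1000 µm²).

TIL scoring tiles the map into fixed squares (default 500 µm), assigns each
tile its plurality class, and defines the iTIL score as the fraction of
tumor tiles called TIL-positive — with equal-area tiles the area ratio
equals the count ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import AnalysisError, TlsQuantError
from .labelmap import BACKGROUND, STROMA, TLS, TUMOR, LabelMap

CATEGORIES = ("proximal", "distal", "excluded_far", "excluded_small")
RETAINED = ("proximal", "distal")


@dataclass
class TLSRecord:
    """One connected TLS component."""

    case_id: str
    component_id: int
    area_um2: float
    centroid_x_um: float
    centroid_y_um: float
    margin_distance_um: Optional[float] = None  # unset until distances computed
    category: Optional[str] = None

    @property
    def retained(self) -> bool:
        return self.category in RETAINED


@dataclass
class TileGrid:
    """Fixed square tiling of a label map with per-tile plurality classes."""

    tile_size_um: float
    tile_size_px: int
    dominant_class: np.ndarray  # 2D int array (n_tile_rows, n_tile_cols), -1 = dropped edge tile
    case_id: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.dominant_class.shape

    def tumor_tiles(self) -> np.ndarray:
        return self.dominant_class == TUMOR


@dataclass
class CaseSpatialSummary:
    case_id: str
    n_ptls: int
    n_dtls: int
    tls_positive: bool
    ptls_positive: bool
    dtls_positive: bool
    itil_score: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "n_ptls": self.n_ptls,
            "n_dtls": self.n_dtls,
            "tls_positive": self.tls_positive,
            "ptls_positive": self.ptls_positive,
            "dtls_positive": self.dtls_positive,
            "itil_score": self.itil_score,
        }


def extract_tls_components(
    lmap: LabelMap, config: PipelineConfig = DEFAULT_CONFIG
) -> list[TLSRecord]:
    """Connected TLS components (8-connected by default), distances unset.

    Components with area below ``config.min_tls_area_um2`` are categorized
    ``excluded_small`` immediately; others stay uncategorized until
    distances are assigned.
    """
    labeled = measure.label(lmap.mask(TLS), connectivity=config.connectivity)
    records: list[TLSRecord] = []
    px_area = lmap.mpp**2
    for prop in measure.regionprops(labeled):
        area_um2 = prop.area * px_area
        crow, ccol = prop.centroid  # mean of member pixel indices
        rec = TLSRecord(
            case_id=lmap.case_id,
            component_id=int(prop.label),
            area_um2=float(area_um2),
            centroid_x_um=float((ccol + 0.5) * lmap.mpp),
            centroid_y_um=float((crow + 0.5) * lmap.mpp),
        )
        if area_um2 < config.min_tls_area_um2:
            rec.category = "excluded_small"
        records.append(rec)
    return records


def _tumor_mask(lmap: LabelMap, config: PipelineConfig) -> np.ndarray:
    mask = lmap.mask(TUMOR)
    min_area_px = config.min_tumor_component_area_um2 / lmap.mpp**2
    if min_area_px > 1:
        labeled = measure.label(mask, connectivity=config.connectivity)
        keep = np.zeros_like(mask)
        for prop in measure.regionprops(labeled):
            if prop.area >= min_area_px:
                keep[labeled == prop.label] = True
        mask = keep
    return mask


def margin_distance(
    lmap: LabelMap,
    points_um: Sequence[float] | np.ndarray,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> np.ndarray | float:
    """Euclidean distance (µm) from physical point(s) to the nearest tumor pixel center.

    ``points_um`` is a single (x, y) pair or an (n, 2) array.  A point lying
    on a tumor pixel center has distance 0; a point inside a tumor pixel has
    the (sub-pixel) distance to that pixel's center, which is clamped to 0
    for classification purposes by the caller when the point falls within
    the tumor mask.  Exact nearest-neighbor search over tumor pixel centers;
    agrees with the brute-force minimum over all tumor pixels to machine
    precision.
    """
    tumor = _tumor_mask(lmap, config)
    if not tumor.any():
        raise AnalysisError("no tumor region in label map")
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    tree = cKDTree(lmap.pixel_centers_um(tumor))
    dist, _ = tree.query(pts, k=1)
    return float(dist[0]) if np.asarray(points_um).ndim == 1 else dist


def margin_distance_field(
    lmap: LabelMap, config: PipelineConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Distance (µm) from every pixel center to the nearest tumor pixel center.

    Computed with the exact Euclidean distance transform of the tumor-mask
    complement, scaled by mpp; tumor pixels have distance 0.
    """
    tumor = _tumor_mask(lmap, config)
    if not tumor.any():
        raise AnalysisError("no tumor region in label map")
    return ndimage.distance_transform_edt(~tumor, sampling=lmap.mpp)


def classify_tls(
    distance_um: float, config: PipelineConfig = DEFAULT_CONFIG
) -> str:
    """Proximal / distal / excluded_far by margin distance.

    Boundary convention: proximal is [0, proximal_cutoff), distal is
    [proximal_cutoff, distal_cutoff] (both ends included), excluded beyond.
    """
    if distance_um < 0:
        raise TlsQuantError(f"negative margin distance {distance_um}")
    if distance_um < config.proximal_cutoff_um:
        return "proximal"
    if distance_um <= config.distal_cutoff_um:
        return "distal"
    return "excluded_far"


def assign_distances(
    lmap: LabelMap,
    records: Iterable[TLSRecord],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[TLSRecord]:
    """Fill margin distance and category for extracted components.

    Components that touch the tumor mask (any member pixel 8-adjacent to a
    tumor pixel, i.e. intratumoral or overlapping structures) or whose
    centroid falls on a tumor pixel get distance 0 — closest-possible, hence
    proximal.  Components already marked ``excluded_small`` keep that
    category but still receive a distance for reporting.
    """
    records = list(records)
    if not records:
        return records
    pts = np.array([[r.centroid_x_um, r.centroid_y_um] for r in records])
    dists = margin_distance(lmap, pts, config)
    tumor = _tumor_mask(lmap, config)
    near_tumor = ndimage.binary_dilation(tumor, structure=np.ones((3, 3), dtype=bool))
    labeled = measure.label(lmap.mask(TLS), connectivity=config.connectivity)
    touching = set(np.unique(labeled[near_tumor & (labeled > 0)]).tolist())
    nrows, ncols = lmap.shape
    for rec, d in zip(records, dists):
        row = min(nrows - 1, max(0, int(rec.centroid_y_um / lmap.mpp)))
        col = min(ncols - 1, max(0, int(rec.centroid_x_um / lmap.mpp)))
        if tumor[row, col] or rec.component_id in touching:
            d = 0.0
        rec.margin_distance_um = float(d)
        if rec.category != "excluded_small":
            rec.category = classify_tls(float(d), config)
    return records


def summarize_case(
    lmap: LabelMap,
    config: PipelineConfig = DEFAULT_CONFIG,
    til_calls: Optional[pd.DataFrame] = None,
) -> tuple[CaseSpatialSummary, list[TLSRecord]]:
    """Extract → distance → classify → count, for one case.

    Only retained categories (proximal/distal) are counted.  If ``til_calls``
    is given, the iTIL score is computed on the default tile grid.
    """
    records = assign_distances(lmap, extract_tls_components(lmap, config), config)
    n_ptls = sum(r.category == "proximal" for r in records)
    n_dtls = sum(r.category == "distal" for r in records)
    summary = CaseSpatialSummary(
        case_id=lmap.case_id,
        n_ptls=n_ptls,
        n_dtls=n_dtls,
        tls_positive=(n_ptls + n_dtls) >= 1,
        ptls_positive=n_ptls >= 1,
        dtls_positive=n_dtls >= 1,
    )
    if til_calls is not None:
        grid = build_tile_grid(lmap, config)
        summary.itil_score = itil_score(grid, til_calls)
    return summary, records


def records_to_frame(records: Iterable[TLSRecord]) -> pd.DataFrame:
    rows = [
        {
            "case_id": r.case_id,
            "component_id": r.component_id,
            "area_um2": r.area_um2,
            "centroid_x_um": r.centroid_x_um,
            "centroid_y_um": r.centroid_y_um,
            "margin_distance_um": r.margin_distance_um,
            "category": r.category,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "case_id", "component_id", "area_um2", "centroid_x_um",
            "centroid_y_um", "margin_distance_um", "category",
        ],
    )


def distance_histogram(
    records: Iterable[TLSRecord],
    bin_width_um: float = 500.0,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Counts of retained TLSs per distance bin over [0, distal_cutoff].

    Bins are half-open ``[lo, hi)``; the final bin is truncated at the
    distal cutoff and closed on the right so the cutoff itself is counted.
    """
    if bin_width_um <= 0:
        raise TlsQuantError("bin_width_um must be > 0")
    hi = config.distal_cutoff_um
    edges = np.arange(0.0, hi, bin_width_um)
    edges = np.append(edges, hi)
    dists = [
        r.margin_distance_um
        for r in records
        if r.retained and r.margin_distance_um is not None
    ]
    counts, _ = np.histogram(dists, bins=edges)  # last bin closed on the right
    return pd.DataFrame(
        {"bin_lo_um": edges[:-1], "bin_hi_um": edges[1:], "count": counts}
    )


def build_tile_grid(
    lmap: LabelMap, config: PipelineConfig = DEFAULT_CONFIG
) -> TileGrid:
    """Tile the map from the origin into tile_size_um squares.

    Each tile's dominant class is the plurality of its pixel classes; ties
    broken by priority tumor > TLS > stroma > background (conservative
    toward the tumor area used as the iTIL denominator).  Partial edge tiles
    are retained iff at least 50% of a full tile's area lies on the map;
    dropped tiles are coded -1.
    """
    t_px = max(1, int(round(config.tile_size_um / lmap.mpp)))
    nrows, ncols = lmap.shape
    n_tr = math.ceil(nrows / t_px)
    n_tc = math.ceil(ncols / t_px)
    dominant = np.full((n_tr, n_tc), -1, dtype=np.int8)
    # tie priority: tumor > TLS > stroma > background
    priority = {TUMOR: 3, TLS: 2, STROMA: 1, BACKGROUND: 0}
    half_tile = t_px * t_px / 2.0
    for tr in range(n_tr):
        r0, r1 = tr * t_px, min((tr + 1) * t_px, nrows)
        for tc in range(n_tc):
            c0, c1 = tc * t_px, min((tc + 1) * t_px, ncols)
            n_px = (r1 - r0) * (c1 - c0)
            if n_px < half_tile:
                continue
            counts = np.bincount(lmap.pixels[r0:r1, c0:c1].ravel(), minlength=4)
            best = max(range(4), key=lambda c: (counts[c], priority[c]))
            dominant[tr, tc] = best
    return TileGrid(
        tile_size_um=config.tile_size_um,
        tile_size_px=t_px,
        dominant_class=dominant,
        case_id=lmap.case_id,
    )


def itil_score(grid: TileGrid, til_calls: pd.DataFrame) -> float:
    """Fraction of tumor tiles flagged TIL-positive.

    ``til_calls`` must have columns tile_row, tile_col, til_positive and
    cover every tumor tile; flags on non-tumor tiles are ignored.
    """
    tumor = grid.tumor_tiles()
    n_tumor = int(tumor.sum())
    if n_tumor == 0:
        raise AnalysisError("no tumor area: zero tumor tiles")
    flags = {
        (int(r), int(c)): bool(p)
        for r, c, p in zip(
            til_calls["tile_row"], til_calls["tile_col"], til_calls["til_positive"]
        )
    }
    rows, cols = np.nonzero(tumor)
    missing = [(int(r), int(c)) for r, c in zip(rows, cols) if (int(r), int(c)) not in flags]
    if missing:
        raise AnalysisError(f"TIL calls missing for tumor tile(s) {missing[:5]}")
    n_pos = sum(flags[(int(r), int(c))] for r, c in zip(rows, cols))
    return n_pos / n_tumor
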
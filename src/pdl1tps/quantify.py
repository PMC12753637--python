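"""Cell quantification and tumour proportion score (TPS).

A segmentation mask (0 background, 1 PD-L1-positive tumour cell, 2
PD-L1-negative tumour cell) is turned into cell counts by connected-component
labelling with a radius-4 merge: the binary mask of one class is dilated by a
Chebyshev-radius-4 structuring element, the dilation is labelled with
4-connectivity, and original pixels inherit the label of their dilated
component — so fragments of one cell within four pixels of each other count
as a single cell.

The TPS is

    TPS% = 100 * (positive intact tumour cells) / (all intact tumour cells),

computed over an annotated region of interest (ROI) by tiling the ROI into
fixed-size patches, counting cells per patch, and summing the tallies before
applying the ratio. A region with no detected tumour cells raises
:class:`NoTumourCellsError` rather than reporting a score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import shape as _geojson_shape
from shapely.geometry.base import BaseGeometry
import shapely

__all__ = [
    "CellTally",
    "TPSResult",
    "Tile",
    "NoTumourCellsError",
    "EmptyROIError",
    "label_cells",
    "count_cells",
    "compute_tps",
    "tile_roi",
    "score_roi",
    "score_mask",
    "roi_from_geojson",
]

DEFAULT_MERGE_RADIUS_PX = 4
DEFAULT_TILE_PX = 256
# 4-connectivity structuring element used after the dilation merge
_CONN4 = ndimage.generate_binary_structure(2, 1)


class NoTumourCellsError(RuntimeError):
    """No intact tumour cells present; a TPS cannot be reported."""


class EmptyROIError(ValueError):
    """The ROI does not intersect the image."""


@dataclass(frozen=True)
class CellTally:
    """Counts of PD-L1-positive and -negative intact tumour cells."""

    n_positive: int
    n_negative: int

    def __post_init__(self):
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_positive + self.n_negative

    def __add__(self, other: "CellTally") -> "CellTally":
        return CellTally(self.n_positive + other.n_positive,
                         self.n_negative + other.n_negative)


@dataclass
class TPSResult:
    """A TPS with its per-patch provenance."""

    tps_percent: float
    tally: CellTally
    per_patch_tallies: list[CellTally]
    tile_offsets: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_patches(self) -> int:
        return len(self.per_patch_tallies)

    def to_dict(self) -> dict:
        return {
            "tps_percent": self.tps_percent,
            "n_positive": self.tally.n_positive,
            "n_negative": self.tally.n_negative,
            "n_patches": self.n_patches,
            "per_patch": [
                {"offset": list(o), "n_positive": t.n_positive,
                 "n_negative": t.n_negative}
                for o, t in zip(self.tile_offsets or
                                [(0, 0)] * self.n_patches,
                                self.per_patch_tallies)],
        }


def _validate_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("label mask must be 2-D")
    if not np.isin(mask, (0, 1, 2)).all():
        raise ValueError("label mask values must be in {0,1,2}")
    return mask


def label_cells(mask: np.ndarray, class_label: int,
                merge_radius_px: int = DEFAULT_MERGE_RADIUS_PX,
                connectivity: int = 1,
                min_size_px: int = 0) -> list[np.ndarray]:
    """Group pixels of one class into cells.

    Returns one boolean pixel array per cell (same shape as ``mask``).
    Fragments whose Chebyshev separation is within the merge radius belong
    to the same cell. ``connectivity`` is the scipy convention: 1 for
    4-connectivity (default), 2 for 8-connectivity. ``min_size_px``
    optionally drops components smaller than an intact cell (0 keeps all);
    size is measured on the original, undilated pixels.
    """
    mask = _validate_mask(mask)
    if class_label not in (1, 2):
        raise ValueError("class_label must be 1 (positive) or 2 (negative)")
    binary = mask == class_label
    if not binary.any():
        return []
    if merge_radius_px > 0:
        size = 2 * merge_radius_px + 1
        dilated = ndimage.binary_dilation(binary, structure=np.ones((size, size),
                                                                    dtype=bool))
    else:
        dilated = binary
    structure = ndimage.generate_binary_structure(2, connectivity)
    labels, n = ndimage.label(dilated, structure=structure)
    cells = []
    for i in range(1, n + 1):
        cell = binary & (labels == i)
        if int(np.count_nonzero(cell)) >= max(min_size_px, 1):
            cells.append(cell)
    return cells


def count_cells(mask: np.ndarray,
                merge_radius_px: int = DEFAULT_MERGE_RADIUS_PX,
                connectivity: int = 1,
                min_size_px: int = 0) -> CellTally:
    """Count positive and negative tumour cells in a label mask."""
    return CellTally(
        len(label_cells(mask, 1, merge_radius_px, connectivity, min_size_px)),
        len(label_cells(mask, 2, merge_radius_px, connectivity, min_size_px)))


def compute_tps(tally: CellTally) -> float:
    """TPS% = 100 * positive / (positive + negative); requires total > 0."""
    if tally.total == 0:
        raise NoTumourCellsError(
            "no intact tumour cells detected; report 'no viable tumour' "
            "instead of a TPS")
    return 100.0 * tally.n_positive / tally.total


@dataclass
class Tile:
    """One ROI tile: image patch, validity mask and its image offset."""

    image: np.ndarray            # (tile_px, tile_px, 3) uint8
    valid: np.ndarray            # (tile_px, tile_px) bool; False outside ROI/pad
    offset: tuple[int, int]      # (row, col) of the tile origin in the image


def _as_geometry(roi) -> BaseGeometry:
    if isinstance(roi, BaseGeometry):
        geom = roi
    elif isinstance(roi, dict):
        geom = roi_from_geojson(roi)
    else:
        raise TypeError("roi must be a shapely geometry or GeoJSON mapping")
    if geom.is_empty or geom.area <= 0:
        raise EmptyROIError("ROI polygon has no area")
    return geom


def roi_from_geojson(obj: dict) -> BaseGeometry:
    """Read ROI polygon(s) from a GeoJSON mapping.

    Accepts a FeatureCollection, Feature or bare geometry with Polygon /
    MultiPolygon members in 0-based pixel coordinates (x right, y down, the
    QuPath export convention). Multiple features are unioned.
    """
    if obj.get("type") == "FeatureCollection":
        geoms = [_geojson_shape(f["geometry"]) for f in obj["features"]]
    elif obj.get("type") == "Feature":
        geoms = [_geojson_shape(obj["geometry"])]
    else:
        geoms = [_geojson_shape(obj)]
    bad = [g.geom_type for g in geoms
           if g.geom_type not in ("Polygon", "MultiPolygon")]
    if bad:
        raise ValueError(f"ROI features must be polygons, got {bad}")
    invalid = [g for g in geoms if not g.is_valid]
    if invalid:
        raise ValueError("ROI polygon is invalid (self-intersecting?)")
    return shapely.union_all(geoms)


def _rasterize(geom: BaseGeometry, y0: int, x0: int, h: int, w: int
               ) -> np.ndarray:
    """Pixel-centre membership grid for a window of the image plane."""
    yy, xx = np.mgrid[y0:y0 + h, x0:x0 + w]
    return shapely.contains_xy(geom, xx + 0.5, yy + 0.5)


def tile_roi(image: np.ndarray, roi, tile_px: int = DEFAULT_TILE_PX,
             pad_value: int = 255) -> list[Tile]:
    """Cut the ROI bounding box into a row-major grid of fixed-size tiles.

    Pixels outside the ROI polygon (or outside the image, for partial edge
    tiles padded to ``tile_px``) are marked invalid and filled with
    ``pad_value``; they carry no cells.
    """
    geom = _as_geometry(roi)
    h, w = image.shape[:2]
    minx, miny, maxx, maxy = geom.bounds
    y_start = max(int(np.floor(miny)), 0)
    x_start = max(int(np.floor(minx)), 0)
    y_stop = min(int(np.ceil(maxy)), h)
    x_stop = min(int(np.ceil(maxx)), w)
    if y_stop <= y_start or x_stop <= x_start:
        raise EmptyROIError("ROI lies outside the image")
    tiles = []
    for ty in range(y_start, y_stop, tile_px):
        for tx in range(x_start, x_stop, tile_px):
            th = min(tile_px, h - ty)
            tw = min(tile_px, w - tx)
            patch = np.full((tile_px, tile_px, 3), pad_value, dtype=np.uint8)
            patch[:th, :tw] = image[ty:ty + th, tx:tx + tw]
            valid = np.zeros((tile_px, tile_px), dtype=bool)
            valid[:th, :tw] = _rasterize(geom, ty, tx, th, tw)
            if valid.any():
                tiles.append(Tile(image=patch, valid=valid, offset=(ty, tx)))
    if not tiles:
        raise EmptyROIError("ROI covers no pixel centres inside the image")
    return tiles


def _score_tallies(tallies: list[CellTally],
                   offsets: list[tuple[int, int]]) -> TPSResult:
    total = CellTally(0, 0)
    for t in tallies:
        total = total + t
    return TPSResult(tps_percent=compute_tps(total), tally=total,
                     per_patch_tallies=tallies, tile_offsets=offsets)


def score_roi(model, image: np.ndarray, roi, *,
              tile_px: int = DEFAULT_TILE_PX,
              merge_radius_px: int = DEFAULT_MERGE_RADIUS_PX,
              min_size_px: int = 0,
              mask_threshold: float | None = None) -> TPSResult:
    """Segment, count and score an annotated ROI.

    Each tile is segmented with ``model``, predictions outside the ROI are
    discarded via the tile validity mask, cells are counted per tile with
    :func:`count_cells`, tallies are summed over tiles and the TPS ratio is
    applied to the sum. Raises :class:`NoTumourCellsError` when no tumour
    cell is detected anywhere in the ROI.
    """
    from .segmenter import predict_mask  # local import to avoid a cycle
    tiles = tile_roi(image, roi, tile_px=tile_px)
    tallies, offsets = [], []
    for tile in tiles:
        pred = predict_mask(model, tile.image, mask_threshold)
        pred = np.where(tile.valid, pred, 0).astype(np.uint8)
        tallies.append(count_cells(pred, merge_radius_px,
                                   min_size_px=min_size_px))
        offsets.append(tile.offset)
    return _score_tallies(tallies, offsets)


def score_mask(mask: np.ndarray, roi=None, *,
               tile_px: int = DEFAULT_TILE_PX,
               merge_radius_px: int = DEFAULT_MERGE_RADIUS_PX,
               min_size_px: int = 0) -> TPSResult:
    """Score a label mask directly (e.g. ground truth), with optional tiling.

    With ``roi`` given, the mask is tiled exactly like :func:`score_roi`
    tiles an image; otherwise the whole mask is one patch.
    """
    mask = _validate_mask(mask)
    if roi is None:
        tallies = [count_cells(mask, merge_radius_px, min_size_px=min_size_px)]
        offsets = [(0, 0)]
    else:
        geom = _as_geometry(roi)
        tiles = tile_roi(np.repeat(mask[..., None], 3, axis=-1), geom,
                         tile_px=tile_px, pad_value=0)
        tallies, offsets = [], []
        for tile in tiles:
            sub = np.where(tile.valid, tile.image[..., 0], 0).astype(np.uint8)
            tallies.append(count_cells(sub, merge_radius_px,
                                       min_size_px=min_size_px))
            offsets.append(tile.offset)
    return _score_tallies(tallies, offsets)
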
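"""From annotated image to selected 512x512 tiles.

Mirrors the slide-preparation steps used for annotated biopsy images:
crop the minimum bounding rectangle of the pathologist's tumor-region
polygons, downsample by block mean (x400 -> x200 magnification), cut a
non-overlapping grid of fixed-size tiles anchored at the crop origin,
and keep either an explicitly listed subset of tiles (replaying a
manual selection) or the tiles that are sufficiently covered by tissue.

Coordinates are 0-based (row, col) with half-open pixel bounds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .texture import to_grayscale

__all__ = [
    "RoiAnnotation",
    "Tile",
    "TileGrid",
    "crop_bounding_rect",
    "downsample",
    "tile_image",
    "select_tiles",
    "extract_tile",
    "BACKGROUND_LUMINANCE",
]

#: 8-bit luminance above which a pixel counts as background (glass/whitespace).
BACKGROUND_LUMINANCE = 220.0


@dataclass
class RoiAnnotation:
    """Polygonal regions of interest on a source image.

    ``polygons`` are (n, 2) float arrays of (row, col) vertices at the
    source magnification; polygons are implicitly closed.  ``magnification``
    is a free-text tag ("x400" or "x200").
    """

    polygons: list[np.ndarray]
    magnification: str = "x400"

    def __post_init__(self) -> None:
        polys = []
        for poly in self.polygons:
            poly = np.asarray(poly, dtype=np.float64)
            if poly.ndim != 2 or poly.shape[1] != 2:
                raise ValueError("each polygon must be an (n, 2) array")
            # drop an explicit closing vertex, then require 3 distinct ones
            if len(poly) > 1 and np.allclose(poly[0], poly[-1]):
                poly = poly[:-1]
            if len(np.unique(poly, axis=0)) < 3:
                raise ValueError("polygon needs at least 3 distinct vertices")
            if _shoelace_area(poly) == 0:
                raise ValueError("polygon has empty interior (zero area)")
            polys.append(poly)
        if not polys:
            raise ValueError("annotation must contain at least one polygon")
        self.polygons = polys

    def bounding_rect(self) -> tuple[int, int, int, int]:
        """Half-open (r0, r1, c0, c1) of the union of polygons."""
        vertices = np.vstack(self.polygons)
        r0 = int(np.floor(vertices[:, 0].min()))
        c0 = int(np.floor(vertices[:, 1].min()))
        r1 = int(np.ceil(vertices[:, 0].max()))
        c1 = int(np.ceil(vertices[:, 1].max()))
        return r0, r1, c0, c1

    def to_geojson(self, path) -> None:
        """Serialize as a GeoJSON FeatureCollection (x=col, y=row)."""
        features = [
            {
                "type": "Feature",
                "properties": {"magnification": self.magnification},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [
                        [[float(c), float(r)] for r, c in poly] + [[float(poly[0][1]), float(poly[0][0])]]
                    ],
                },
            }
            for poly in self.polygons
        ]
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": features}, indent=2)
        )

    @classmethod
    def from_geojson(cls, path) -> "RoiAnnotation":
        data = json.loads(Path(path).read_text())
        polygons = []
        magnification = "x400"
        for feat in data["features"]:
            ring = feat["geometry"]["coordinates"][0]
            polygons.append(np.asarray([[y, x] for x, y in ring]))
            magnification = feat.get("properties", {}).get("magnification", magnification)
        return cls(polygons=polygons, magnification=magnification)


def _shoelace_area(poly: np.ndarray) -> float:
    r, c = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))


def crop_bounding_rect(
    image: np.ndarray, annotation: RoiAnnotation
) -> tuple[np.ndarray, tuple[int, int]]:
    """Axis-aligned minimum bounding rectangle of the ROI union.

    Returns ``(subimage, (row_offset, col_offset))``; adding the offset
    to subimage coordinates recovers source coordinates.
    """
    r0, r1, c0, c1 = annotation.bounding_rect()
    h, w = image.shape[:2]
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise ValueError(
            f"ROI bounding rect ({r0},{c0})-({r1},{c1}) outside image {h}x{w}"
        )
    return image[r0:r1, c0:c1], (r0, c0)


def downsample(image: np.ndarray, factor: int = 2) -> np.ndarray:
    """Block-mean downsampling by an integer factor.

    Every output pixel is the mean of the corresponding factor x factor
    input block; trailing rows/cols that do not fill a block are
    dropped, so output dims are floor(input/factor).  8-bit input stays
    8-bit, rounded half-to-even.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    image = np.asarray(image)
    if factor == 1:
        return image.copy()
    h, w = image.shape[:2]
    nh, nw = h // factor, w // factor
    trimmed = image[: nh * factor, : nw * factor].astype(np.float64)
    if image.ndim == 2:
        out = trimmed.reshape(nh, factor, nw, factor).mean(axis=(1, 3))
    else:
        out = trimmed.reshape(nh, factor, nw, factor, -1).mean(axis=(1, 3))
    if image.dtype == np.uint8:
        return np.rint(out).astype(np.uint8)
    return out


@dataclass(frozen=True)
class Tile:
    """One grid cell: half-open pixel bounds within the (cropped) image."""

    tile_id: str
    patient_id: str
    row: int
    col: int
    bounds: tuple[int, int, int, int]  # (r0, r1, c0, c1), half-open
    tissue_fraction: float


@dataclass
class TileGrid:
    tile_size: int
    n_rows: int
    n_cols: int
    tiles: list[Tile]
    origin: tuple[int, int] = (0, 0)

    def __getitem__(self, tile_id: str) -> Tile:
        for t in self.tiles:
            if t.tile_id == tile_id:
                return t
        raise KeyError(tile_id)

    def manifest(self, selected: "set[str] | None" = None) -> pd.DataFrame:
        sel = selected if selected is not None else set()
        return pd.DataFrame(
            [
                {
                    "tile_id": t.tile_id,
                    "patient_id": t.patient_id,
                    "row": t.row,
                    "col": t.col,
                    "tissue_fraction": t.tissue_fraction,
                    "selected": t.tile_id in sel,
                }
                for t in self.tiles
            ]
        )


def tile_image(
    image: np.ndarray, tile_size: int = 512, patient_id: str = "img"
) -> TileGrid:
    """Non-overlapping grid of tiles anchored at (0, 0).

    Right/bottom remainders smaller than a full tile are dropped.  Each
    tile records its tissue fraction: the share of pixels whose
    luminance is at or below :data:`BACKGROUND_LUMINANCE`.
    """
    h, w = image.shape[:2]
    n_rows, n_cols = h // tile_size, w // tile_size
    if n_rows == 0 or n_cols == 0:
        warnings.warn(
            f"image {h}x{w} smaller than one {tile_size}x{tile_size} tile; empty grid",
            stacklevel=2,
        )
        return TileGrid(tile_size=tile_size, n_rows=0, n_cols=0, tiles=[])
    if image.ndim == 3:
        lum = to_grayscale(image)
    else:
        lum = np.asarray(image, dtype=np.float64)
    tissue = lum <= BACKGROUND_LUMINANCE
    tiles = []
    for r in range(n_rows):
        for c in range(n_cols):
            r0, c0 = r * tile_size, c * tile_size
            frac = float(tissue[r0 : r0 + tile_size, c0 : c0 + tile_size].mean())
            tiles.append(
                Tile(
                    tile_id=f"{patient_id}_{r}_{c}",
                    patient_id=patient_id,
                    row=r,
                    col=c,
                    bounds=(r0, r0 + tile_size, c0, c0 + tile_size),
                    tissue_fraction=frac,
                )
            )
    return TileGrid(tile_size=tile_size, n_rows=n_rows, n_cols=n_cols, tiles=tiles)


def select_tiles(
    grid: TileGrid,
    mode: str = "tissue-fraction",
    threshold: float = 0.8,
    tile_ids: "list[str] | None" = None,
) -> list[Tile]:
    """Choose the tiles to analyze.

    ``explicit-list`` replays a manual (pathologist-style) selection and
    returns the listed tiles in list order; ``tissue-fraction`` is the
    automated surrogate keeping tiles with tissue_fraction >= threshold.
    """
    if mode == "explicit-list":
        if tile_ids is None:
            raise ValueError("explicit-list mode requires tile_ids")
        out = []
        for tid in tile_ids:
            try:
                out.append(grid[tid])
            except KeyError:
                raise ValueError(f"tile id {tid!r} not present in grid") from None
        return out
    if mode == "tissue-fraction":
        return [t for t in grid.tiles if t.tissue_fraction >= threshold]
    raise ValueError(f"unknown selection mode {mode!r}")


def extract_tile(image: np.ndarray, tile: Tile) -> np.ndarray:
    """Pixel data of one tile (a view into ``image``)."""
    r0, r1, c0, c1 = tile.bounds
    return image[r0:r1, c0:c1]
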
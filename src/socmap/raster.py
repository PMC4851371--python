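"""Georeferenced single-band rasters and aligned predictor stacks.

A :class:`RasterGrid` is the carrier for the DEM, the spectral bands and
every derived predictor surface: a 2-D array of cell values in projected
map coordinates (meters), an upper-left origin, a square cell size and a
boolean nodata mask.  A :class:`PredictorStack` is an ordered, geometry-
aligned collection of such grids keyed by predictor id (``"slope@135"``,
``"ndvi"``...).

GeoTIFF I/O is implemented on tifffile using the standard GeoTIFF tags
(ModelPixelScale, ModelTiepoint) plus GDAL's nodata tag, which is all the
georeferencing this pipeline needs: single band, projected meters, no
reprojection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import tifffile

__all__ = [
    "RasterGrid",
    "PredictorStack",
    "AlignmentError",
    "read_raster",
    "write_raster",
    "assemble_stack",
]

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999.0


class AlignmentError(ValueError):
    """Raised when grids that must share geometry do not."""


@dataclass
class RasterGrid:
    """Single-band georeferenced grid.

    Parameters
    ----------
    values
        2-D array of cell values (row 0 = northernmost row).
    cell_size
        Edge length of the square cells in meters; must be positive.
    origin
        ``(x, y)`` map coordinates of the upper-left corner of the
        upper-left cell.
    nodata_mask
        Boolean array of the same shape; ``True`` marks invalid cells.
        Defaults to all-valid.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError(
                "nodata_mask shape %s does not match values shape %s"
                % (self.nodata_mask.shape, self.values.shape)
            )
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def same_geometry(self, other: "RasterGrid", *, tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )

    def copy(self) -> "RasterGrid":
        return RasterGrid(
            self.values.copy(), self.cell_size, self.origin, self.nodata_mask.copy()
        )

    def masked(self) -> np.ma.MaskedArray:
        """Values as a numpy masked array (statistics exclude nodata)."""
        return np.ma.masked_array(self.values, mask=self.nodata_mask)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing map point ``(x, y)``.

        Cells are half-open intervals ``[x0, x0 + cs)`` east and
        ``(y0 - cs, y0]`` going south from the origin, so a point on a
        shared edge belongs to exactly one cell.
        """
        col = int(np.floor((x - self.origin[0]) / self.cell_size))
        row = int(np.floor((self.origin[1] - y) / self.cell_size))
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.origin[0] + (col + 0.5) * self.cell_size
        y = self.origin[1] - (row + 0.5) * self.cell_size
        return x, y

    def contains(self, x: float, y: float) -> bool:
        row, col = self.cell_of(x, y)
        nrow, ncol = self.shape
        return 0 <= row < nrow and 0 <= col < ncol


def read_raster(path) -> RasterGrid:
    """Read a single-band GeoTIFF into a :class:`RasterGrid`.

    Raises
    ------
    ValueError
        If the file has more than one band/page (the band count is named
        in the message) or lacks a pixel-scale tag.
    """
    with tifffile.TiffFile(path) as tf:
        if len(tf.pages) != 1:
            raise ValueError(
                f"{path}: expected a single-band GeoTIFF, found {len(tf.pages)} pages"
            )
        page = tf.pages[0]
        spp = page.tags.get("SamplesPerPixel")
        nbands = int(spp.value) if spp is not None else 1
        if nbands != 1:
            raise ValueError(
                f"{path}: expected a single-band GeoTIFF, found {nbands} bands"
            )
        values = page.asarray().astype(float)
        scale_tag = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
        if scale_tag is None:
            raise ValueError(f"{path}: no ModelPixelScale tag; not a GeoTIFF?")
        sx, sy = float(scale_tag.value[0]), float(scale_tag.value[1])
        if abs(sx - sy) > 1e-6 * max(sx, sy):
            raise ValueError(f"{path}: non-square cells ({sx} x {sy}) unsupported")
        tie_tag = page.tags.get(_TAG_MODEL_TIEPOINT)
        if tie_tag is None:
            origin = (0.0, 0.0)
        else:
            i, j, _k, x, y, _z = (float(v) for v in tie_tag.value[:6])
            # tie point (i, j) is in raster space at the UL corner of cell (j, i)
            origin = (x - i * sx, y + j * sy)
        nodata_tag = page.tags.get(_TAG_GDAL_NODATA)
        mask = np.isnan(values)
        if nodata_tag is not None:
            nodata = float(str(nodata_tag.value))
            if np.isnan(nodata):
                mask = np.isnan(values)
            else:
                mask |= values == nodata
    return RasterGrid(values, sx, origin, mask)


def write_raster(grid: RasterGrid, path, *, nodata: float = DEFAULT_NODATA) -> None:
    """Write a :class:`RasterGrid` to a single-band float32 GeoTIFF.

    Masked cells are stored as ``nodata`` and the GDAL nodata tag is set so
    :func:`read_raster` (and GDAL-based readers) restore the mask.
    """
    out = grid.values.astype(np.float32).copy()
    out[grid.nodata_mask] = np.float32(nodata)
    cs = float(grid.cell_size)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin[0], grid.origin[1], 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(nodata))),
    ]
    tifffile.imwrite(path, out, extratags=extratags)


class PredictorStack:
    """Ordered mapping ``predictor_id -> RasterGrid``, all geometry-aligned.

    Predictor ids follow the ``name`` or ``name@radius_m`` convention
    (e.g. ``"altitude"``, ``"profile@405"``).  Insertion order is
    preserved; all layers must share shape, cell size and origin.
    """

    def __init__(self, layers: Mapping[str, RasterGrid] | None = None):
        self._layers: dict[str, RasterGrid] = {}
        if layers:
            for pid, grid in layers.items():
                self.add(pid, grid)

    def add(self, predictor_id: str, grid: RasterGrid) -> None:
        if predictor_id in self._layers:
            raise ValueError(f"duplicate predictor id {predictor_id!r}")
        if self._layers:
            ref = next(iter(self._layers.values()))
            if not ref.same_geometry(grid):
                raise AlignmentError(
                    f"layer {predictor_id!r} geometry (shape {grid.shape}, "
                    f"cell {grid.cell_size}, origin {grid.origin}) does not match "
                    f"stack (shape {ref.shape}, cell {ref.cell_size}, origin {ref.origin})"
                )
        self._layers[predictor_id] = grid

    def __getitem__(self, predictor_id: str) -> RasterGrid:
        return self._layers[predictor_id]

    def __contains__(self, predictor_id: str) -> bool:
        return predictor_id in self._layers

    def __iter__(self) -> Iterator[str]:
        return iter(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    @property
    def predictor_ids(self) -> list[str]:
        return list(self._layers)

    @property
    def cell_size(self) -> float:
        return next(iter(self._layers.values())).cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self._layers.values())).shape

    @property
    def origin(self) -> tuple[float, float]:
        return next(iter(self._layers.values())).origin

    def items(self):
        return self._layers.items()

    def subset(self, predictor_ids) -> "PredictorStack":
        return PredictorStack({pid: self._layers[pid] for pid in predictor_ids})

    def update(self, other: "PredictorStack") -> None:
        for pid, grid in other.items():
            self.add(pid, grid)


def assemble_stack(grids: Mapping[str, RasterGrid]) -> PredictorStack:
    """Assemble aligned grids into a :class:`PredictorStack`.

    Raises :class:`AlignmentError` naming the offending layer on any
    shape/cell-size/origin mismatch, and ``ValueError`` on duplicate ids
    or an empty mapping.
    """
    if not grids:
        raise ValueError("cannot assemble an empty stack")
    return PredictorStack(grids)
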
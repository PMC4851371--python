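"""Spectral predictors: band calibration, vegetation and moisture indices.

Landsat 8 OLI/TIRS digital numbers are converted to top-of-atmosphere
reflectance (and at-satellite brightness-temperature proxies for the TIRS
bands) by per-band affine transforms; the default gains/offsets are the
calibration coefficients of the 2014 scene this pipeline was designed
around.  Two of the four indices, PVI and TSAVI, rest on the *soil line*
concept: the empirical linear NIR-vs-Red relationship of bare soil,

    NIR = beta1 * Red + beta0,

whose slope/intercept are estimated automatically from the imagery as the
lower envelope of the NIR-vs-Red point cloud.  Pixels on the soil line
have PVI = TSAVI = 0 by construction; vegetated pixels plot above it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import AlignmentError, RasterGrid

__all__ = [
    "BandTransform",
    "SoilLine",
    "LANDSAT8_TRANSFORMS",
    "apply_band_transform",
    "ndvi",
    "ndmi",
    "fit_soil_line",
    "pvi",
    "tsavi",
]


@dataclass(frozen=True)
class BandTransform:
    """Affine DN calibration: ``reflectance = gain * DN + offset``."""

    gain: float
    offset: float


#: Scene calibration coefficients, one affine transform per input band.
LANDSAT8_TRANSFORMS: dict[str, BandTransform] = {
    "aerosol": BandTransform(1.2901e-02, -64.50640),   # band 1
    "blue": BandTransform(1.3211e-02, -66.05534),      # band 2
    "green": BandTransform(1.2174e-02, -60.86943),     # band 3
    "red": BandTransform(1.0266e-02, -51.32853),       # band 4
    "nir": BandTransform(6.2821e-03, -31.41050),       # band 5
    "swir1": BandTransform(1.5623e-03, -7.81151),      # band 6
    "swir2": BandTransform(5.2658e-04, -2.63290),      # band 7
    "pan": BandTransform(1.1618e-02, -58.08977),       # band 8
    "tirs1": BandTransform(3.3420e-04, 0.10000),       # band 10
    "tirs2": BandTransform(3.3420e-04, 0.10000),       # band 11
}


@dataclass(frozen=True)
class SoilLine:
    """Bare-soil NIR-vs-Red line (slope ``beta1``, intercept ``beta0``).

    ``X`` is the soil-adjustment constant used by TSAVI, conventionally
    0.08.
    """

    beta1: float
    beta0: float
    X: float = 0.08

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta1):
            raise ValueError("soil line slope must be finite")


def _check_aligned(*grids: RasterGrid) -> None:
    ref = grids[0]
    for g in grids[1:]:
        if not ref.same_geometry(g):
            raise AlignmentError("band grids are not aligned")


def apply_band_transform(band: RasterGrid, t: BandTransform) -> RasterGrid:
    """Cellwise affine calibration; the nodata mask is carried through."""
    return RasterGrid(
        t.gain * band.values + t.offset,
        band.cell_size,
        band.origin,
        band.nodata_mask.copy(),
    )


def _normalized_difference(a: RasterGrid, b: RasterGrid) -> RasterGrid:
    _check_aligned(a, b)
    denom = a.values + b.values
    mask = a.nodata_mask | b.nodata_mask | (denom == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(denom == 0, np.nan, (a.values - b.values) / denom)
    return RasterGrid(vals, a.cell_size, a.origin, mask)


def ndvi(red: RasterGrid, nir: RasterGrid) -> RasterGrid:
    """Normalized difference vegetation index, (NIR - R)/(NIR + R)."""
    return _normalized_difference(nir, red)


def ndmi(nir: RasterGrid, swir1: RasterGrid) -> RasterGrid:
    """Normalized difference moisture index, (NIR - SWIR1)/(NIR + SWIR1)."""
    return _normalized_difference(nir, swir1)


def fit_soil_line(
    red_values: np.ndarray,
    nir_values: np.ndarray,
    *,
    n_bins: int = 20,
    X: float = 0.08,
) -> SoilLine:
    """Estimate the soil line as a binned-minimum lower envelope.

    The red-reflectance range is partitioned into ``n_bins`` equal-width
    bins; within each bin the minimum NIR value is taken as a bare-soil
    candidate, and an ordinary least-squares line through the bin minima
    gives (beta1, beta0).  Vegetated pixels, which plot above the soil
    line, are thereby excluded automatically.

    Masked/NaN pairs are ignored.  Raises on degenerate input (fewer than
    two distinct red values).
    """
    red = np.asarray(red_values, dtype=float).ravel()
    nir = np.asarray(nir_values, dtype=float).ravel()
    ok = np.isfinite(red) & np.isfinite(nir)
    red, nir = red[ok], nir[ok]
    if red.size < 2 or np.ptp(red) == 0:
        raise ValueError("cannot fit soil line: fewer than two distinct red values")
    edges = np.linspace(red.min(), red.max(), n_bins + 1)
    # right-inclusive last bin so the maximum red value is not dropped
    idx = np.clip(np.digitize(red, edges[1:-1]), 0, n_bins - 1)
    bin_red, bin_nir = [], []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        j = np.argmin(nir[sel])
        bin_red.append(red[sel][j])
        bin_nir.append(nir[sel][j])
    if len(bin_red) < 2:
        raise ValueError("cannot fit soil line: fewer than two occupied red bins")
    beta1, beta0 = np.polyfit(bin_red, bin_nir, 1)
    return SoilLine(float(beta1), float(beta0), X=X)


def pvi(red: RasterGrid, nir: RasterGrid, soil_line: SoilLine) -> RasterGrid:
    """Perpendicular vegetation index.

    PVI = (NIR - beta1*R - beta0) / sqrt(beta1^2 + 1): the signed
    perpendicular distance of a pixel from the soil line, positive above
    (vegetated), zero on the line.
    """
    _check_aligned(red, nir)
    b1, b0 = soil_line.beta1, soil_line.beta0
    vals = (nir.values - b1 * red.values - b0) / np.sqrt(b1 * b1 + 1.0)
    return RasterGrid(vals, red.cell_size, red.origin, red.nodata_mask | nir.nodata_mask)


def tsavi(red: RasterGrid, nir: RasterGrid, soil_line: SoilLine) -> RasterGrid:
    """Transformed soil-adjusted vegetation index.

    TSAVI = beta1*(NIR - beta1*R - beta0) /
            (beta1*NIR + R - beta1*beta0 + X*(1 + beta1^2)),

    zero on the soil line; the soil-adjustment constant ``X`` (default
    0.08) damps the denominator at low reflectance.  Cells with a zero
    denominator are masked.
    """
    _check_aligned(red, nir)
    b1, b0, X = soil_line.beta1, soil_line.beta0, soil_line.X
    num = b1 * (nir.values - b1 * red.values - b0)
    denom = b1 * nir.values + red.values - b1 * b0 + X * (1.0 + b1 * b1)
    mask = red.nodata_mask | nir.nodata_mask | (denom == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(denom == 0, np.nan, num / denom)
    return RasterGrid(vals, red.cell_size, red.origin, mask)
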
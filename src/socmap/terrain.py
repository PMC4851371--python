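"""Multi-scale geomorphometric predictors from a DEM.

Terrain attributes are derived by fitting, at every cell, the bivariate
quadratic

    z(u, v) = a*u^2 + b*v^2 + c*u*v + d*u + e*v + f

by least squares over a circular neighborhood of a given *search radius*
(u east, v north, meters, centered on the target cell).  Slope, aspect
and the six curvatures follow the Evans/Wood quadratic-fit family:

    slope        = atan(sqrt(d^2 + e^2))                       [rad]
    aspect       = azimuth of steepest descent, clockwise from north [deg]
    longitudinal = -2 (a d^2 + b e^2 + c d e) / g2
    cross        = -2 (a e^2 + b d^2 - c d e) / g2
    minimum      = a + b - sqrt((a - b)^2 + c^2)
    maximum      = a + b + sqrt((a - b)^2 + c^2)
    profile      = -2 (a d^2 + b e^2 + c d e) / (g2 * (1 + g2)^(3/2))
    plan         =  2 (a e^2 + b d^2 - c d e) / g2^(3/2)

with g2 = d^2 + e^2 (curvature units 1/m).  Profile and plan are the
slope-normalized normal-section forms in the Zevenbergen-Thorne /
Wood tradition; longitudinal and cross-sectional are their unnormalized
counterparts.  Sign convention: a bowl (z = r^2) has positive minimum
curvature; a dome has negative a + b.  Gradient-dependent curvatures and
aspect are undefined (masked) on flat cells.

The search radius controls the scale of the predictor: radius r on cell
size cs uses a (2*floor(r/cs)+1)-square window restricted to cells whose
center lies within r of the target (45 m -> 3x3, 615 m -> 41x41 at 30 m
cells).  The convergence index and the terrain ruggedness index are
computed over the same circular neighborhoods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import PredictorStack, RasterGrid

__all__ = [
    "QuadraticSurface",
    "ScaleSpec",
    "fit_quadratic_surface",
    "slope",
    "aspect",
    "curvatures",
    "quadratic_coefficient_grids",
    "convergence_index",
    "terrain_ruggedness",
    "multiscale_stack",
    "DEFAULT_RADII",
    "MULTISCALE_PARAMS",
]

#: Search radii in meters: 45 to 615 in steps of 30 (20 scales at 30 m cells).
DEFAULT_RADII: tuple[float, ...] = tuple(float(r) for r in range(45, 616, 30))

#: Multi-scale parameters derivable by :func:`multiscale_stack`.
MULTISCALE_PARAMS: tuple[str, ...] = (
    "slope", "aspect", "plan", "profile", "long", "cross", "min", "max", "ci", "tri",
)

CURVATURE_NAMES = ("plan", "profile", "longitudinal", "cross_sectional", "minimum", "maximum")

_SHORT = {"long": "longitudinal", "cross": "cross_sectional", "min": "minimum", "max": "maximum"}


@dataclass(frozen=True)
class QuadraticSurface:
    """Coefficients of the locally fitted quadratic (see module docstring)."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float


@dataclass(frozen=True)
class ScaleSpec:
    """A search radius and the square window it induces on a given grid."""

    radius_m: float
    cell_size: float

    def __post_init__(self) -> None:
        if self.radius_m < self.cell_size:
            raise ValueError(
                f"search radius {self.radius_m} m is below the cell size {self.cell_size} m"
            )

    @property
    def half_width(self) -> int:
        return int(np.floor(self.radius_m / self.cell_size))

    @property
    def window_cells(self) -> int:
        return 2 * self.half_width + 1


def _window_offsets(scale: ScaleSpec, *, include_center: bool = True) -> np.ndarray:
    """(k, 2) array of (row, col) offsets within the circular neighborhood."""
    h = scale.half_width
    di, dj = np.mgrid[-h : h + 1, -h : h + 1]
    dist = np.hypot(di, dj) * scale.cell_size
    keep = dist <= scale.radius_m
    if not include_center:
        keep[h, h] = False
    return np.stack([di[keep], dj[keep]], axis=1)


def _design_matrix(offsets: np.ndarray, cell_size: float) -> np.ndarray:
    u = offsets[:, 1] * cell_size          # east
    v = -offsets[:, 0] * cell_size         # north (row increases southward)
    return np.column_stack([u * u, v * v, u * v, u, v, np.ones_like(u)])


def fit_quadratic_surface(dem_window: np.ndarray, cell_size: float) -> QuadraticSurface:
    """Least-squares quadratic fit over one odd-sized square window.

    NaN cells are excluded; fewer than 6 usable cells raises.  The window
    is restricted to the inscribed circle of radius (half_width + 0.5)
    cells only when larger than 3x3, matching the grid pipeline (a 3x3
    always uses all 9 cells).
    """
    w = np.asarray(dem_window, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] % 2 == 0 or w.shape[0] < 3:
        raise ValueError("window must be odd-sized square, at least 3x3")
    h = w.shape[0] // 2
    scale = ScaleSpec(radius_m=(h + 0.5) * cell_size, cell_size=cell_size)
    offsets = _window_offsets(scale)
    z = w[offsets[:, 0] + h, offsets[:, 1] + h]
    ok = np.isfinite(z)
    if ok.sum() < 6:
        raise ValueError(f"need >= 6 unmasked cells to fit quadratic, got {int(ok.sum())}")
    A = _design_matrix(offsets[ok], cell_size)
    coef, *_ = np.linalg.lstsq(A, z[ok], rcond=None)
    return QuadraticSurface(*(float(v) for v in coef))


def slope(surface: QuadraticSurface) -> float:
    """Slope angle in radians, atan of the gradient magnitude."""
    return float(np.arctan(np.hypot(surface.d, surface.e)))


#: Gradient magnitude below which a cell counts as flat (pure numerical
#: noise from the least-squares fit; a real 1e-10 gradient is ~1e-8 % slope).
FLAT_GRADIENT = 1e-10


def aspect(surface: QuadraticSurface) -> float:
    """Downslope azimuth in degrees clockwise from north; NaN if flat."""
    if np.hypot(surface.d, surface.e) < FLAT_GRADIENT:
        return float("nan")
    deg = float(np.degrees(np.arctan2(-surface.d, -surface.e)) % 360.0)
    return 0.0 if deg >= 360.0 else deg


def curvatures(surface: QuadraticSurface) -> dict[str, float]:
    """The six curvatures (1/m); gradient-dependent ones NaN on flat cells."""
    a, b, c, d, e = surface.a, surface.b, surface.c, surface.d, surface.e
    g2 = d * d + e * e
    disc = np.sqrt((a - b) ** 2 + c * c)
    out = {"minimum": a + b - disc, "maximum": a + b + disc}
    if g2 < FLAT_GRADIENT**2:
        out.update({k: float("nan") for k in ("plan", "profile", "longitudinal", "cross_sectional")})
    else:
        num_long = a * d * d + b * e * e + c * d * e
        num_cross = a * e * e + b * d * d - c * d * e
        out["longitudinal"] = -2.0 * num_long / g2
        out["cross_sectional"] = -2.0 * num_cross / g2
        out["profile"] = -2.0 * num_long / (g2 * (1.0 + g2) ** 1.5)
        out["plan"] = 2.0 * num_cross / g2**1.5
    return {k: float(v) for k, v in out.items()}


def _coef_grids_fast(dem: RasterGrid, scale: ScaleSpec) -> np.ndarray:
    """(6, nrow, ncol) coefficient grids by linear filtering (no nodata)."""
    offsets = _window_offsets(scale)
    A = _design_matrix(offsets, dem.cell_size)
    P = np.linalg.pinv(A)  # (6, k): coef = P @ z_window
    h = scale.half_width
    coefs = np.empty((6,) + dem.shape)
    for k in range(6):
        kernel = np.zeros((2 * h + 1, 2 * h + 1))
        kernel[offsets[:, 0] + h, offsets[:, 1] + h] = P[k]
        coefs[k] = ndimage.correlate(dem.values, kernel, mode="nearest")
    return coefs


def quadratic_coefficient_grids(dem: RasterGrid, scale: ScaleSpec) -> tuple[np.ndarray, np.ndarray]:
    """Fit the quadratic at every cell of the grid.

    Returns ``(coefs, invalid)`` where ``coefs`` is (6, nrow, ncol) in the
    order (a, b, c, d, e, f) and ``invalid`` marks cells that could not be
    fitted: border cells whose window leaves the grid, and cells with
    fewer than 6 unmasked window cells.  Cells whose window merely touches
    nodata are refitted on their unmasked subset.
    """
    h = scale.half_width
    nrow, ncol = dem.shape
    if nrow < scale.window_cells or ncol < scale.window_cells:
        raise ValueError(
            f"grid {dem.shape} too small for radius {scale.radius_m} m "
            f"({scale.window_cells}x{scale.window_cells} window)"
        )
    coefs = _coef_grids_fast(dem, scale)
    invalid = np.zeros(dem.shape, dtype=bool)
    invalid[:h, :] = invalid[-h:, :] = True
    invalid[:, :h] = invalid[:, -h:] = True
    if dem.nodata_mask.any():
        offsets = _window_offsets(scale)
        touch = ndimage.binary_dilation(
            dem.nodata_mask, structure=np.ones((2 * h + 1, 2 * h + 1), dtype=bool)
        )
        rows, cols = np.nonzero(touch & ~invalid)
        A_full = _design_matrix(offsets, dem.cell_size)
        for r, c in zip(rows, cols):
            z = dem.values[r + offsets[:, 0], c + offsets[:, 1]]
            bad = dem.nodata_mask[r + offsets[:, 0], c + offsets[:, 1]]
            ok = ~bad
            if ok.sum() < 6:
                invalid[r, c] = True
                continue
            sol, *_ = np.linalg.lstsq(A_full[ok], z[ok], rcond=None)
            coefs[:, r, c] = sol
        invalid |= dem.nodata_mask
    return coefs, invalid


def _surface_grids(
    dem: RasterGrid, scale: ScaleSpec, params: list[str]
) -> dict[str, RasterGrid]:
    coefs, invalid = quadratic_coefficient_grids(dem, scale)
    a, b, c, d, e, _f = coefs
    g2 = d * d + e * e
    flat = g2 < FLAT_GRADIENT**2
    out: dict[str, RasterGrid] = {}

    def grid(vals: np.ndarray, extra_mask: np.ndarray | None = None) -> RasterGrid:
        mask = invalid.copy()
        if extra_mask is not None:
            mask |= extra_mask
        vals = np.where(mask, np.nan, vals)
        return RasterGrid(vals, dem.cell_size, dem.origin, mask)

    with np.errstate(divide="ignore", invalid="ignore"):
        if "slope" in params:
            out["slope"] = grid(np.arctan(np.sqrt(g2)))
        if "aspect" in params:
            asp = np.degrees(np.arctan2(-d, -e)) % 360.0
            out["aspect"] = grid(np.where(asp >= 360.0, 0.0, asp), flat)
        num_long = a * d * d + b * e * e + c * d * e
        num_cross = a * e * e + b * d * d - c * d * e
        disc = np.sqrt((a - b) ** 2 + c * c)
        if "long" in params:
            out["long"] = grid(-2.0 * num_long / g2, flat)
        if "cross" in params:
            out["cross"] = grid(-2.0 * num_cross / g2, flat)
        if "profile" in params:
            out["profile"] = grid(-2.0 * num_long / (g2 * (1.0 + g2) ** 1.5), flat)
        if "plan" in params:
            out["plan"] = grid(2.0 * num_cross / g2**1.5, flat)
        if "min" in params:
            out["min"] = grid(a + b - disc)
        if "max" in params:
            out["max"] = grid(a + b + disc)
    return out


def _aspect_grid_fine(dem: RasterGrid) -> np.ndarray:
    """Cellwise downslope azimuth (deg) from the finest (3x3) fit; NaN if flat."""
    scale = ScaleSpec(radius_m=1.5 * dem.cell_size, cell_size=dem.cell_size)
    coefs, invalid = quadratic_coefficient_grids(dem, scale)
    d, e = coefs[3], coefs[4]
    asp = np.degrees(np.arctan2(-d, -e)) % 360.0
    asp = np.where(asp >= 360.0, 0.0, asp)
    asp[invalid | (d * d + e * e < FLAT_GRADIENT**2)] = np.nan
    return asp


def convergence_index(dem: RasterGrid, scale: ScaleSpec) -> RasterGrid:
    """Convergence index over the circular search radius.

    For every neighbor cell within the radius, take the absolute angular
    difference (wrapped to [0, 180]) between that cell's downslope aspect
    and the azimuth from that cell toward the center; the convergence
    index is the neighborhood mean minus 90.  Range [-90, +90]; -90 at the
    center of a symmetric pit (all flow converges), ~0 on an inclined
    plane, +90 on a symmetric peak.  Cells whose whole neighborhood is
    flat are masked.
    """
    asp = _aspect_grid_fine(dem)
    offsets = _window_offsets(scale, include_center=False)
    h = scale.half_width
    pad = np.full((dem.shape[0] + 2 * h, dem.shape[1] + 2 * h), np.nan)
    pad[h:-h, h:-h] = asp
    total = np.zeros(dem.shape)
    count = np.zeros(dem.shape)
    nrow, ncol = dem.shape
    for di, dj in offsets:
        neigh = pad[h + di : h + di + nrow, h + dj : h + dj + ncol]
        # azimuth from the neighbor toward the center cell
        azim = np.degrees(np.arctan2(-dj, di)) % 360.0
        diff = np.abs(neigh - azim) % 360.0
        diff = np.where(diff > 180.0, 360.0 - diff, diff)
        ok = np.isfinite(diff)
        total += np.where(ok, diff, 0.0)
        count += ok
    mask = count == 0
    mask[:h, :] = mask[-h:, :] = True
    mask[:, :h] = mask[:, -h:] = True
    mask |= dem.nodata_mask
    with np.errstate(invalid="ignore"):
        ci = np.where(mask, np.nan, total / np.maximum(count, 1) - 90.0)
    return RasterGrid(ci, dem.cell_size, dem.origin, mask)


def terrain_ruggedness(dem: RasterGrid, scale: ScaleSpec) -> RasterGrid:
    """Terrain ruggedness index: RMS elevation difference to the neighborhood.

    TRI = sqrt(mean over unmasked cells within the radius, center
    excluded, of (z_i - z_center)^2).  Zero on a constant DEM; scales
    linearly with the DEM (homogeneous of degree 1).
    """
    offsets = _window_offsets(scale, include_center=False)
    h = scale.half_width
    kernel = np.zeros((2 * h + 1, 2 * h + 1))
    kernel[offsets[:, 0] + h, offsets[:, 1] + h] = 1.0
    z = np.where(dem.nodata_mask, 0.0, dem.values)
    valid = (~dem.nodata_mask).astype(float)
    s1 = ndimage.correlate(z, kernel, mode="constant", cval=0.0)
    s2 = ndimage.correlate(z * z, kernel, mode="constant", cval=0.0)
    n = ndimage.correlate(valid, kernel, mode="constant", cval=0.0)
    zc = dem.values
    mask = (n == 0) | dem.nodata_mask
    mask[:h, :] = mask[-h:, :] = True
    mask[:, :h] = mask[:, -h:] = True
    with np.errstate(invalid="ignore"):
        msq = (s2 - 2.0 * zc * s1 + n * zc * zc) / np.maximum(n, 1)
        tri = np.sqrt(np.maximum(msq, 0.0))
    tri = np.where(mask, np.nan, tri)
    return RasterGrid(tri, dem.cell_size, dem.origin, mask)


def multiscale_stack(
    dem: RasterGrid,
    params: list[str] | tuple[str, ...] = MULTISCALE_PARAMS,
    radii: list[float] | tuple[float, ...] = DEFAULT_RADII,
) -> PredictorStack:
    """One predictor layer per (parameter, search radius).

    Layer ids are ``"param@radius"`` with the radius in meters (integral
    radii printed without decimals).  Border cells within
    floor(radius/cell_size) cells of the grid edge are masked in the
    corresponding layer.  Raises if any radius is below the cell size.
    """
    unknown = [p for p in params if p not in MULTISCALE_PARAMS]
    if unknown:
        raise ValueError(f"unknown terrain parameters {unknown}; choose from {MULTISCALE_PARAMS}")
    stack = PredictorStack()
    surf_params = [p for p in params if p not in ("ci", "tri")]
    for radius in radii:
        scale = ScaleSpec(radius_m=float(radius), cell_size=dem.cell_size)
        rlabel = f"{int(radius)}" if float(radius).is_integer() else f"{radius}"
        if surf_params:
            grids = _surface_grids(dem, scale, surf_params)
            for p in surf_params:
                stack.add(f"{p}@{rlabel}", grids[p])
        if "ci" in params:
            stack.add(f"ci@{rlabel}", convergence_index(dem, scale))
        if "tri" in params:
            stack.add(f"tri@{rlabel}", terrain_ruggedness(dem, scale))
    return stack
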
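"""Seeded synthetic landscapes with known informative structure.

The field data this pipeline was designed for (transect-sampled SOC
stocks of a dissected tropical mountain landscape, with predictors from
a 30 m DEM and a Landsat scene) is not deposited, so the test bed is a
generator that emulates its statistical shape:

* a rugged DEM — ridge/valley sinusoids plus smoothed fractal noise —
  on 30 m cells;
* red/NIR/SWIR bands that are monotone functions of elevation with a
  planted bare-soil line, so the spectral chain (soil-line fit, PVI,
  TSAVI, NDVI, NDMI) is exercised end to end;
* stand-in predictor fields (smoothed random fields with controllable
  correlation to the DEM) that play the statistical role of the many
  additional GIS terrain variables, letting the predictor count grow
  toward the study's ~236;
* a transect sampling design (20 transects x 3 slope positions = 60
  points by default) and a response built from a small set of known
  informative predictors plus Gaussian noise, affinely mapped into the
  observed SOC-stock range of 0.2-17.7 kg m^-2.

The response noise defaults to the weak-signal regime (true R^2 = 0.5)
and every output is reproducible from the spec seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import PredictorStack, RasterGrid
from .samples import RESPONSE, SampleTable
from .spectral import SoilLine, ndmi, ndvi, pvi, tsavi, fit_soil_line
from .terrain import multiscale_stack

__all__ = [
    "LandscapeSpec",
    "ResponseSpec",
    "TruthRecord",
    "generate_dem",
    "generate_bands",
    "generate_standin_predictors",
    "generate_samples",
    "generate_landscape_stack",
]

MIN_SHAPE = 50


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of the synthetic DEM."""

    shape: tuple[int, int] = (80, 80)
    cell_size: float = 30.0
    relief_amplitude: float = 600.0  # total relief in m
    n_ridges: int = 3
    roughness: float = 0.4  # fraction of relief carried by fractal noise
    base_elevation: float = 1900.0
    seed: int = 0


@dataclass(frozen=True)
class ResponseSpec:
    """Recipe for the synthetic SOC-stock response.

    ``informative`` names the predictor layers that truly drive the
    response, with one linear weight each (applied to the standardized
    layer); ``interactions`` optionally adds weighted products of two
    layers.  ``noise_sd`` is the additive Gaussian noise on the linear
    predictor scale; when None it is set from ``target_r2`` so the
    population R^2 of the truth equals the target (default 0.5, the
    weak-signal regime).  The response is affinely mapped so the sampled
    stocks span ``response_range`` (kg m^-2).
    """

    informative: tuple[str, ...]
    weights: tuple[float, ...]
    interactions: tuple[tuple[str, str, float], ...] = ()
    noise_sd: float | None = None
    target_r2: float = 0.5
    response_range: tuple[float, float] = (0.2, 17.7)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.informative) != len(self.weights):
            raise ValueError("informative ids and weights differ in length")


@dataclass
class TruthRecord:
    """What actually generated the response, for recovery scoring."""

    informative: list[str]
    weights: list[float]
    interactions: list[tuple[str, str, float]]
    noise_sd: float
    signal_sd: float
    population_r2: float
    affine_scale: float
    affine_offset: float


def _smoothed_noise(shape: tuple[int, int], rng: np.random.Generator, sigma_cells: float) -> np.ndarray:
    """Zero-mean unit-sd Gaussian field smoothed to a correlation length."""
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=sigma_cells, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def generate_dem(spec: LandscapeSpec) -> RasterGrid:
    """Ridge/valley sinusoids plus smoothed fractal noise, seeded.

    Raises if the grid is below 50x50 cells (too small for the coarsest
    multi-scale derivatives).
    """
    nrow, ncol = spec.shape
    if nrow < MIN_SHAPE or ncol < MIN_SHAPE:
        raise ValueError(f"landscape shape {spec.shape} below minimum {MIN_SHAPE}x{MIN_SHAPE}")
    rng = np.random.default_rng(spec.seed)
    y, x = np.mgrid[0:nrow, 0:ncol].astype(float)
    x *= spec.cell_size
    y *= spec.cell_size
    extent = max(nrow, ncol) * spec.cell_size
    ridges = np.zeros(spec.shape)
    for _ in range(max(spec.n_ridges, 0)):
        theta = rng.uniform(0, np.pi)
        wavelength = extent / rng.uniform(1.0, 2.5)
        phase = rng.uniform(0, 2 * np.pi)
        ridges += np.sin(2 * np.pi * (np.cos(theta) * x + np.sin(theta) * y) / wavelength + phase)
    if spec.n_ridges > 0 and ridges.std() > 0:
        ridges = ridges / ridges.std()
    rough = _smoothed_noise(spec.shape, rng, sigma_cells=2.0)
    z = (1.0 - spec.roughness) * ridges + spec.roughness * rough
    if z.std() > 0:
        z = (z - z.min()) / np.ptp(z)  # [0, 1]
    z = spec.base_elevation + spec.relief_amplitude * z
    return RasterGrid(z, spec.cell_size, origin=(0.0, nrow * spec.cell_size))


def generate_bands(
    dem: RasterGrid,
    seed: int = 0,
    *,
    soil_line: SoilLine = SoilLine(0.71, 0.11),
    band_noise_sd: float = 0.004,
    veg_amplitude: float = 0.25,
) -> PredictorStack:
    """Red/NIR/SWIR1 reflectance bands tied to the terrain.

    Red reflectance decreases monotonically with elevation; NIR is the
    planted soil line applied to red, lifted by a vegetation-cover field
    (a smoothed seeded pattern damped above the tree line) so bare-soil
    cells lie on the line and :func:`socmap.spectral.fit_soil_line` can
    recover it; SWIR1 decreases with vegetation moisture.  With
    ``band_noise_sd`` = 0 the vegetation modulation collapses to its
    deterministic elevation profile, so every band — and hence NDVI — is
    a pure function of elevation.
    """
    rng = np.random.default_rng(seed)
    z = dem.values
    e = (z - z.min()) / (np.ptp(z) if np.ptp(z) > 0 else 1.0)
    red = 0.28 - 0.18 * e
    treeline = np.clip((0.95 - e) / 0.6, 0.0, 1.0)
    if band_noise_sd > 0:
        m = np.clip(0.5 + 0.6 * _smoothed_noise(dem.shape, rng, 3.0), 0.0, 1.0) ** 2
        red = red + band_noise_sd * rng.standard_normal(dem.shape)
    else:
        m = np.ones(dem.shape)
    uplift = veg_amplitude * treeline * m
    nir = soil_line.beta1 * red + soil_line.beta0 + uplift
    swir1 = np.clip(0.30 + 0.05 * e - 0.5 * uplift, 0.01, None)
    if band_noise_sd > 0:
        nir = nir + 0.5 * band_noise_sd * np.abs(rng.standard_normal(dem.shape))
        swir1 = swir1 + band_noise_sd * rng.standard_normal(dem.shape)
    stack = PredictorStack()
    for name, vals in (("red", red), ("nir", nir), ("swir1", swir1)):
        stack.add(name, RasterGrid(vals, dem.cell_size, dem.origin, dem.nodata_mask.copy()))
    return stack


def generate_standin_predictors(
    dem: RasterGrid,
    n: int,
    seed: int = 0,
    *,
    dem_correlation: float = 0.3,
    sigma_cells: float = 3.0,
    prefix: str = "standin",
) -> PredictorStack:
    """Smoothed random fields with controllable correlation to the DEM.

    Stand-ins for additional GIS terrain variables (wetness indices,
    openness, insolation...) that share the spatial smoothness and
    partial elevation-dependence of real terrain predictors without
    reimplementing them; used to inflate the predictor count for stress
    tests.
    """
    if not 0 <= dem_correlation <= 1:
        raise ValueError("dem_correlation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    z = dem.values
    zstd = (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)
    stack = PredictorStack()
    width = len(str(max(n, 1)))
    for i in range(n):
        fld = _smoothed_noise(dem.shape, rng, sigma_cells)
        vals = dem_correlation * zstd + np.sqrt(1 - dem_correlation**2) * fld
        stack.add(
            f"{prefix}_{i + 1:0{width}d}",
            RasterGrid(vals, dem.cell_size, dem.origin, dem.nodata_mask.copy()),
        )
    return stack


def generate_samples(
    stack: PredictorStack,
    design: dict,
    response_spec: ResponseSpec,
) -> tuple[SampleTable, TruthRecord]:
    """Transect-design sample points with a known-truth response.

    ``design`` takes ``n_transects`` (default 20) and
    ``positions_per_transect`` (default 3).  Each transect runs from a
    high-elevation cell toward a nearby low cell; one position is drawn
    at random within the upper, middle and foot thirds of the line,
    emulating a ridge-to-valley slope-position design.  The response is
    the weighted sum of the informative predictor values at the sample
    points (standardized over the sample, plus any interaction products)
    with additive Gaussian noise, affinely mapped so the sampled values
    span the target SOC-stock range.
    """
    n_transects = int(design.get("n_transects", 20))
    positions = int(design.get("positions_per_transect", 3))
    missing = [p for p in response_spec.informative if p not in stack]
    for a, b, _w in response_spec.interactions:
        missing += [p for p in (a, b) if p not in stack]
    if missing:
        raise ValueError(f"response references missing predictors: {sorted(set(missing))}")
    rng = np.random.default_rng(response_spec.seed)

    valid = np.ones(stack.shape, dtype=bool)
    for _pid, grid in stack.items():
        valid &= ~grid.nodata_mask
    if not valid.any():
        raise ValueError("no cell is valid across all layers")
    dem_like = stack[response_spec.informative[0]] if "altitude" not in stack else stack["altitude"]
    elev = dem_like.values
    rows, cols = np.nonzero(valid)
    order = np.argsort(elev[rows, cols])
    lows, highs = (rows[order[: len(order) // 4]], cols[order[: len(order) // 4]]), (
        rows[order[-len(order) // 4 :]],
        cols[order[-len(order) // 4 :]],
    )

    ref = stack[stack.predictor_ids[0]]
    pts: list[tuple[float, float]] = []
    for _t in range(n_transects):
        hi = rng.integers(len(highs[0]))
        lo = rng.integers(len(lows[0]))
        r0, c0 = int(highs[0][hi]), int(highs[1][hi])
        r1, c1 = int(lows[0][lo]), int(lows[1][lo])
        for pos in range(positions):
            frac = (pos + rng.uniform(0.1, 0.9)) / positions
            r = int(round(r0 + frac * (r1 - r0)))
            c = int(round(c0 + frac * (c1 - c0)))
            if not valid[r, c]:  # fall back to the nearest valid transect end
                r, c = (r0, c0) if frac < 0.5 else (r1, c1)
            pts.append(ref.cell_center(r, c))

    cells = [ref.cell_of(x, y) for x, y in pts]

    def sampled_std(pid: str) -> np.ndarray:
        vals = np.array([stack[pid].values[r, c] for r, c in cells])
        sd = vals.std()
        return (vals - vals.mean()) / (sd if sd > 0 else 1.0)

    # the truth is defined on the sampled values (standardized over the
    # sample, so each weight contributes its nominal share of signal
    # variance under the realized sampling design)
    signal = np.zeros(len(cells))
    for pid, w in zip(response_spec.informative, response_spec.weights):
        signal += w * sampled_std(pid)
    for a, b, w in response_spec.interactions:
        signal += w * (sampled_std(a) * sampled_std(b))
    signal_sd = float(signal.std())
    if response_spec.noise_sd is not None:
        noise_sd = float(response_spec.noise_sd)
    else:
        r2 = response_spec.target_r2
        if not 0 < r2 < 1:
            raise ValueError("target_r2 must be in (0, 1)")
        noise_sd = signal_sd * float(np.sqrt((1 - r2) / r2))
    population_r2 = signal_sd**2 / (signal_sd**2 + noise_sd**2) if signal_sd > 0 else 0.0

    raw = signal + noise_sd * rng.standard_normal(len(signal))
    lo_t, hi_t = response_spec.response_range
    span = np.ptp(raw)
    scale = (hi_t - lo_t) / (span if span > 0 else 1.0)
    offset = lo_t - raw.min() * scale
    response = raw * scale + offset

    data = {"x": [p[0] for p in pts], "y": [p[1] for p in pts], RESPONSE: response}
    flagged = np.zeros(len(pts), dtype=bool)
    for pid, grid in stack.items():
        vals = np.array([grid.values[r, c] for r, c in cells])
        hit = np.array([grid.nodata_mask[r, c] for r, c in cells])
        vals[hit] = np.nan
        flagged |= hit
        data[pid] = vals
    table = SampleTable(pd.DataFrame(data), stack.predictor_ids, flagged=flagged)
    truth = TruthRecord(
        informative=list(response_spec.informative),
        weights=[float(w) for w in response_spec.weights],
        interactions=[(a, b, float(w)) for a, b, w in response_spec.interactions],
        noise_sd=noise_sd,
        signal_sd=signal_sd,
        population_r2=population_r2,
        affine_scale=float(scale),
        affine_offset=float(offset),
    )
    return table, truth


def generate_landscape_stack(
    lspec: LandscapeSpec,
    *,
    radii: Sequence[float] = (45.0, 135.0, 225.0),
    params: Sequence[str] = ("slope", "plan", "profile", "min", "max", "ci", "tri"),
    n_standins: int = 0,
    with_spectral: bool = True,
) -> PredictorStack:
    """DEM-derived, spectral and stand-in predictors as one aligned stack.

    Convenience assembly for tests, the CLI and the acceptance study:
    altitude + the requested multi-scale terrain layers + (optionally)
    the four vegetation/moisture indices from synthetic bands + stand-in
    fields.  Seeds for the bands and stand-ins are children of the
    landscape seed.
    """
    dem = generate_dem(lspec)
    stack = PredictorStack({"altitude": dem})
    stack.update(multiscale_stack(dem, list(params), list(radii)))
    if with_spectral:
        bands = generate_bands(dem, seed=lspec.seed + 1)
        red, nir, swir1 = bands["red"], bands["nir"], bands["swir1"]
        line = fit_soil_line(red.values, nir.values)
        stack.add("ndvi", ndvi(red, nir))
        stack.add("ndmi", ndmi(nir, swir1))
        stack.add("pvi", pvi(red, nir, line))
        stack.add("tsavi", tsavi(red, nir, line))
    if n_standins > 0:
        stack.update(generate_standin_predictors(dem, n_standins, seed=lspec.seed + 2))
    return stack
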
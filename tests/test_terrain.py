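"""Multi-scale terrain derivatives against analytic surfaces."""

import numpy as np
import pytest

import socmap as sm
from socmap.raster import RasterGrid
from socmap.terrain import ScaleSpec, convergence_index, multiscale_stack, terrain_ruggedness

from conftest import make_quadratic_dem

CS = 30.0


def closed_form_derivatives(coeffs, x0, y0):
    """Analytic slope/aspect/curvatures of a global quadratic at (x0, y0).

    Recentered at the probe point, z(x0+u, y0+v) has local coefficients
    a, b, c unchanged and gradient (d', e') = (2a x0 + c y0 + d,
    2b y0 + c x0 + e); the derivatives follow from the local quadratic.
    """
    a, b, c, d, e, _f = coeffs
    dd = 2 * a * x0 + c * y0 + d
    ee = 2 * b * y0 + c * x0 + e
    g2 = dd * dd + ee * ee
    out = {"slope": np.arctan(np.sqrt(g2))}
    out["aspect"] = np.nan if g2 == 0 else np.degrees(np.arctan2(-dd, -ee)) % 360
    disc = np.sqrt((a - b) ** 2 + c * c)
    out["min"] = a + b - disc
    out["max"] = a + b + disc
    if g2 > 0:
        nl = a * dd * dd + b * ee * ee + c * dd * ee
        nc = a * ee * ee + b * dd * dd - c * dd * ee
        out["long"] = -2 * nl / g2
        out["cross"] = -2 * nc / g2
        out["profile"] = -2 * nl / (g2 * (1 + g2) ** 1.5)
        out["plan"] = 2 * nc / g2**1.5
    return out


class TestQuadraticFit:
    def test_constant_window(self):
        s = sm.fit_quadratic_surface(np.full((3, 3), 5.0), CS)
        assert s.f == pytest.approx(5.0, abs=1e-12)
        for v in (s.a, s.b, s.c, s.d, s.e):
            assert v == pytest.approx(0.0, abs=1e-14)

    def test_pure_x_squared(self):
        n = 5
        dem, x, y = make_quadratic_dem((0.01, 0, 0, 0, 0, 0), n=n, cell_size=CS)
        s = sm.fit_quadratic_surface(dem.values, CS)
        assert s.a == pytest.approx(0.01, abs=1e-10)
        for v in (s.b, s.c, s.d, s.e, s.f):
            assert v == pytest.approx(0.0, abs=1e-10)

    def test_full_quadratic_recovered(self):
        coeffs = (0.002, 0.003, -0.001, 0.1, -0.2, 3.0)
        dem, _, _ = make_quadratic_dem(coeffs, n=7, cell_size=CS)
        s = sm.fit_quadratic_surface(dem.values, CS)
        np.testing.assert_allclose([s.a, s.b, s.c, s.d, s.e, s.f], coeffs, atol=1e-10)

    def test_too_few_unmasked_cells(self):
        w = np.full((3, 3), np.nan)
        w[0, 0] = w[1, 1] = w[2, 2] = 1.0
        with pytest.raises(ValueError, match="6"):
            sm.fit_quadratic_surface(w, CS)


class TestSlopeAspectConventions:
    def test_east_rising_plane_faces_west(self):
        dem, _, _ = make_quadratic_dem((0, 0, 0, 0.1, 0, 0), n=5, cell_size=CS)
        s = sm.fit_quadratic_surface(dem.values, CS)
        assert sm.terrain.slope(s) == pytest.approx(np.arctan(0.1), abs=1e-12)
        assert sm.terrain.aspect(s) == pytest.approx(270.0, abs=1e-9)

    def test_north_falling_plane_faces_north(self):
        dem, _, _ = make_quadratic_dem((0, 0, 0, 0, -0.1, 0), n=5, cell_size=CS)
        s = sm.fit_quadratic_surface(dem.values, CS)
        assert sm.terrain.aspect(s) == pytest.approx(0.0, abs=1e-9)

    def test_flat_surface_masks_aspect(self):
        s = sm.fit_quadratic_surface(np.full((3, 3), 2.0), CS)
        assert sm.terrain.slope(s) == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(sm.terrain.aspect(s))


class TestCurvatures:
    def test_plane_has_zero_curvatures(self):
        dem, _, _ = make_quadratic_dem((0, 0, 0, 0.05, -0.02, 1.0), n=5, cell_size=CS)
        s = sm.fit_quadratic_surface(dem.values, CS)
        for v in sm.curvatures(s).values():
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_bowl_principal_curvatures(self):
        s = sm.terrain.QuadraticSurface(0.001, 0.001, 0, 0.01, 0, 0)
        c = sm.curvatures(s)
        assert c["minimum"] == pytest.approx(0.002)
        assert c["maximum"] == pytest.approx(0.002)

    def test_anisotropic_principal_curvatures(self):
        alpha, beta = 0.004, 0.001
        s = sm.terrain.QuadraticSurface(alpha, beta, 0, 0.02, 0.01, 0)
        c = sm.curvatures(s)
        assert c["minimum"] == pytest.approx(alpha + beta - abs(alpha - beta))
        assert c["maximum"] == pytest.approx(alpha + beta + abs(alpha - beta))

    def test_gradient_dependent_curvatures_masked_when_flat(self):
        s = sm.terrain.QuadraticSurface(0.001, 0.002, 0, 0, 0, 5)
        c = sm.curvatures(s)
        for k in ("plan", "profile", "longitudinal", "cross_sectional"):
            assert np.isnan(c[k])
        assert np.isfinite(c["minimum"]) and np.isfinite(c["maximum"])


class TestAnalyticSuite:
    @pytest.mark.parametrize("radius", [45.0, 135.0, 615.0])
    def test_quadratic_dem_matches_closed_forms_at_all_radii(self, radius):
        """The quadratic is scale-invariant: every radius must agree."""
        rng = np.random.default_rng(11)
        n = 51
        for _ in range(5):
            coeffs = tuple(rng.uniform(-1, 1, 6) * [1e-3, 1e-3, 1e-3, 0.3, 0.3, 10])
            dem, x, y = make_quadratic_dem(coeffs, n=n, cell_size=CS)
            stack = multiscale_stack(
                dem, ["slope", "aspect", "plan", "profile", "long", "cross", "min", "max"],
                [radius],
            )
            h = int(radius // CS)
            rlab = f"{int(radius)}"
            sl = stack[f"slope@{rlab}"]
            probe_rc = [(n // 2, n // 2), (h + 1, h + 1), (n - h - 2, h + 2)]
            for r, c in probe_rc:
                want = closed_form_derivatives(coeffs, x[r, c], y[r, c])
                for param in ("slope", "aspect", "plan", "profile", "long", "cross", "min", "max"):
                    got = stack[f"{param}@{rlab}"].values[r, c]
                    if param == "aspect" and np.isnan(want["aspect"]):
                        assert np.isnan(got)
                    else:
                        assert got == pytest.approx(want[param], abs=1e-8), (param, r, c)

    def test_outputs_invariant_under_dem_constant_shift(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal((50, 50)).cumsum(axis=0)
        dem0 = RasterGrid(z, CS)
        dem1 = RasterGrid(z + 500.0, CS)
        for param in ("slope", "min", "tri", "ci"):
            s0 = multiscale_stack(dem0, [param], [45.0])[f"{param}@45"]
            s1 = multiscale_stack(dem1, [param], [45.0])[f"{param}@45"]
            np.testing.assert_allclose(
                s0.values[~s0.nodata_mask], s1.values[~s1.nodata_mask], atol=1e-9
            )


class TestConvergenceIndex:
    def test_pit_plane_peak(self):
        n = 51
        rows, cols = np.mgrid[0:n, 0:n].astype(float)
        x = (cols - n // 2) * CS
        y = (n // 2 - rows) * CS
        dist = np.hypot(x, y)
        scale = ScaleSpec(135.0, CS)
        pit = convergence_index(RasterGrid(0.1 * dist, CS), scale)
        assert pit.values[n // 2, n // 2] == pytest.approx(-90.0, abs=1.0)
        peak = convergence_index(RasterGrid(-0.1 * dist, CS), scale)
        assert peak.values[n // 2, n // 2] == pytest.approx(90.0, abs=1.0)
        plane = convergence_index(RasterGrid(0.05 * x + 0.02 * y, CS), scale)
        assert plane.values[n // 2, n // 2] == pytest.approx(0.0, abs=1.0)

    def test_all_flat_neighborhood_masked(self):
        flat = RasterGrid(np.zeros((50, 50)), CS)
        out = convergence_index(flat, ScaleSpec(45.0, CS))
        assert out.nodata_mask.all()


class TestTerrainRuggedness:
    def test_constant_dem_gives_zero(self):
        out = terrain_ruggedness(RasterGrid(np.full((50, 50), 3.0), CS), ScaleSpec(45.0, CS))
        assert np.all(out.values[~out.nodata_mask] == 0.0)

    def test_tilted_plane_enumerated_neighbors(self):
        dem, x, _ = make_quadratic_dem((0, 0, 0, 1.0, 0, 0), n=9, cell_size=CS)
        out = terrain_ruggedness(dem, ScaleSpec(45.0, CS))
        # 3x3 neighborhood of z = x: squared diffs {0,0,900x6}
        assert out.values[4, 4] == pytest.approx(np.sqrt(675), abs=1e-9)

    def test_homogeneous_of_degree_one(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal((50, 50))
        t1 = terrain_ruggedness(RasterGrid(z, CS), ScaleSpec(75.0, CS))
        t3 = terrain_ruggedness(RasterGrid(3 * z, CS), ScaleSpec(75.0, CS))
        np.testing.assert_allclose(
            t3.values[~t3.nodata_mask], 3 * t1.values[~t1.nodata_mask], rtol=1e-10
        )


class TestMultiscaleStack:
    def test_layer_ids_one_param_three_radii(self):
        dem = RasterGrid(np.random.default_rng(0).standard_normal((50, 50)), CS)
        stack = multiscale_stack(dem, ["slope"], [45.0, 135.0, 225.0])
        assert stack.predictor_ids == ["slope@45", "slope@135", "slope@225"]

    def test_default_radii_are_twenty_scales(self):
        assert len(sm.DEFAULT_RADII) == 20
        assert sm.DEFAULT_RADII[0] == 45.0
        assert sm.DEFAULT_RADII[-1] == 615.0

    def test_border_mask_width_at_radius_615(self):
        dem = RasterGrid(np.random.default_rng(1).standard_normal((50, 50)), CS)
        layer = multiscale_stack(dem, ["slope"], [615.0])["slope@615"]
        assert layer.nodata_mask[:20, :].all()
        assert layer.nodata_mask[:, -20:].all()
        assert not layer.nodata_mask[20:-20, 20:-20].all()

    def test_radius_below_cell_size_rejected(self):
        dem = RasterGrid(np.zeros((50, 50)), CS)
        with pytest.raises(ValueError):
            multiscale_stack(dem, ["slope"], [10.0])

    def test_nodata_cells_handled_by_masked_refit(self):
        dem, _, _ = make_quadratic_dem((0.001, 0.002, 0, 0.05, 0.01, 0), n=21, cell_size=CS)
        mask = np.zeros(dem.shape, dtype=bool)
        mask[10, 10] = True
        holey = RasterGrid(np.where(mask, -9999, dem.values), CS, dem.origin, mask)
        layer = multiscale_stack(holey, ["slope"], [45.0])["slope@45"]
        clean = multiscale_stack(dem, ["slope"], [45.0])["slope@45"]
        assert layer.nodata_mask[10, 10]
        # neighbors refit on their unmasked subset still match the analytic
        # surface exactly (quadratic is exactly representable)
        assert layer.values[10, 11] == pytest.approx(clean.values[10, 11], abs=1e-9)
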
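"""Shared fixtures: tiny rasters, quadratic DEMs and the recovery study."""

from __future__ import annotations

import numpy as np
import pytest

import socmap as sm
from socmap.raster import RasterGrid

#: Seeds of the shipped synthetic recovery study (landscape, stand-ins, response).
RECOVERY_SEEDS = (7, 8, 9)
PLAN_SEED = 1


def make_quadratic_dem(coeffs, n=51, cell_size=30.0):
    """DEM whose surface is a global quadratic in map meters.

    ``coeffs`` = (a, b, c, d, e, f) of z = a x^2 + b y^2 + c x y + d x +
    e y + f with x east / y north, origin at the grid center.
    """
    a, b, c, d, e, f = coeffs
    rows, cols = np.mgrid[0:n, 0:n].astype(float)
    x = (cols - n // 2) * cell_size
    y = (n // 2 - rows) * cell_size
    z = a * x * x + b * y * y + c * x * y + d * x + e * y + f
    return RasterGrid(z, cell_size, origin=(-(n // 2) * cell_size - cell_size / 2,
                                            (n // 2) * cell_size + cell_size / 2)), x, y


@pytest.fixture(scope="session")
def recovery_study():
    """The shipped weak-signal recovery fixture.

    60 transect samples over 50 near-independent noise fields of which 3
    drive a linear response at population R^2 = 0.5; normalized table and
    the shared 5x10 fold plan.
    """
    s_land, s_pred, s_resp = RECOVERY_SEEDS
    lspec = sm.LandscapeSpec(seed=s_land)
    dem = sm.generate_dem(lspec)
    stack = sm.generate_standin_predictors(
        dem, 50, seed=s_pred, dem_correlation=0.0, sigma_cells=0.5
    )
    informative = ("standin_05", "standin_17", "standin_33")
    rspec = sm.ResponseSpec(informative=informative, weights=(1.0, 1.0, 1.0), seed=s_resp)
    table, truth = sm.generate_samples(stack, {}, rspec)
    ntab, record = sm.normalize(table.valid())
    plan = sm.make_folds(len(ntab), k=10, repeats=5, seed=PLAN_SEED)
    return {
        "stack": stack,
        "table": ntab,
        "record": record,
        "plan": plan,
        "informative": informative,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def recovery_sfs_trace(recovery_study):
    """Ridge-learner sFS on the recovery fixture (shared across tests)."""
    spec = sm.default_spec("ridge", seed=1)
    ranking = sm.rank_individual_predictors(
        spec, recovery_study["table"], recovery_study["plan"]
    )
    return sm.simple_forward_selection(
        spec,
        recovery_study["table"],
        recovery_study["plan"],
        ranking.best,
        delta=2e-3,
        ranking=ranking,
    )
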
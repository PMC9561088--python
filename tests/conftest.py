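import numpy as np
import pandas as pd
import pytest

from enmecotype.raster import Affine, RasterGrid, EnvStack
from enmecotype.synth import (EcotypeTruth, LandscapeSpec, gen_layers,
                              make_scenario, plant_suitability, snap_optima,
                              sample_study, _elevation_field)


@pytest.fixture
def unit_transform():
    """1-degree cells, upper-left corner at (0, 4): a 4x4 grid spans x 0..4, y 0..4."""
    return Affine(a=1.0, c=0.0, e=-1.0, f=4.0)


@pytest.fixture
def small_grid(unit_transform):
    values = np.arange(16, dtype=float).reshape(4, 4)
    return RasterGrid(values, unit_transform)


@pytest.fixture
def small_stack(unit_transform):
    a = RasterGrid(np.arange(16, dtype=float).reshape(4, 4), unit_transform)
    b = RasterGrid(np.arange(16, dtype=float).reshape(4, 4)[::-1].copy(),
                   unit_transform)
    nod = np.arange(16, dtype=float).reshape(4, 4).copy()
    nod[0, 0] = np.nan
    c = RasterGrid(nod, unit_transform)
    return EnvStack(
        layers={"a": a, "b": b, "c": c},
        groups={"a": "climatic", "b": "soil", "c": "vegetation_landcover"},
        kind={"a": "continuous", "b": "continuous", "c": "continuous"},
    )


@pytest.fixture(scope="session")
def tiny_scenario():
    """Desk-scale planted scenario, small enough for per-module tests.

    32x32 grid, 2 drivers + 1 rough decoy, 2 ecotypes x 2 districts.
    """
    spec = LandscapeSpec(
        shape=(32, 32),
        layer_names=("drv1", "drv2", "noise1"),
        groups={"drv1": "climatic", "drv2": "climatic", "noise1": "soil"},
        categorical_name=None,
        smooth_sigma=2.0,
        smooth_sigma_overrides={"noise1": 0.5},
        seed=11,
    )
    stack = gen_layers(spec)
    truth = snap_optima(stack, EcotypeTruth(
        drivers=("drv1", "drv2"),
        optima={"E1": (1.2, 1.2), "E2": (-1.2, -1.2)},
        widths=(0.3, 0.3),
    ))
    suit = plant_suitability(stack, truth)
    table, labels, occ = sample_study(
        stack, suit, n_districts_per_ecotype=2, villages_per_district=2,
        seed=11, elevation=_elevation_field(spec),
    )
    return {"stack": stack, "truth": truth, "suitability": suit,
            "table": table, "labels": labels, "occ": occ}


@pytest.fixture(scope="session")
def default_scenario():
    """The packaged 64x64 scenario at seed 1 (shared across tests)."""
    return make_scenario(seed=1)


@pytest.fixture
def toy_maxent():
    """20-background-cell, 2-feature problem with a fitted model."""
    from enmecotype.maxent import fit_maxent

    rng = np.random.default_rng(3)
    bg = rng.uniform(0, 1, (20, 2))
    pres = rng.uniform(0.4, 1, (5, 2))
    x = np.vstack([bg, pres])
    pidx = np.arange(20, 25)
    model = fit_maxent(x, pidx, bm=1.0)
    return {"bg": bg, "pres": pres, "x": x, "pidx": pidx, "model": model}
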
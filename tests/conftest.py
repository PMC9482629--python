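"""Shared fixtures: one demo world and one solved scenario, reused across
the suite to keep runtime down."""
import numpy as np
import pytest

from soyshift import ScenarioSpec, build_compliance, generate_world, split_accounts
from soyshift.config import Drivers
from soyshift.model import (calibrate, diff_land, model_cells, run_baseline,
                            run_counterfactual)

DEMO_SEED = 1


@pytest.fixture(scope="session")
def world():
    return generate_world(random_seed=DEMO_SEED)


@pytest.fixture(scope="session")
def asm_setup(world):
    """Calibrated model under the moratorium scenario at the >=50% threshold."""
    spec = ScenarioSpec(name="ASM", threshold="ge50", forest_definition="A")
    comp = build_compliance(world.municipalities, world.trader_exports,
                            world.roster, spec)
    fp = split_accounts(world.municipalities, comp, spec, world.config)
    cells = model_cells(fp, world.land_cells, world.config)
    params = calibrate(world.sam, cells, world.config)
    return spec, params


@pytest.fixture(scope="session")
def exchange_toy_params():
    """Two regions, each producing one good from labour alone, with
    identical Cobb-Douglas preferences (0.6, 0.4): the competitive
    equilibrium has a closed form."""
    import pandas as pd

    from soyshift.config import Elasticities, WorldConfig
    from soyshift.model import calibrate
    from soyshift.world import build_sam_from_shares

    el = Elasticities(income={"default": 1.0}, supernumerary_share=1.0,
                      armington_dom={"default": 1.0},
                      armington_src_scale=1.0)
    cfg = WorldConfig(regions=["R1", "R2"], sectors=["goodA", "goodB"],
                      crop_sectors=[], pasture_sector="_none_p",
                      forest_sector="_none_f", n_municipalities=2,
                      n_companies=2, elasticities=el)
    cells = pd.DataFrame(columns=["cell_id", "base_cell_id", "region",
                                  "biome", "aez_id", "compliant",
                                  "forest_ha", "other_natural_ha",
                                  "pasture_ha", "cropland_ha"])
    a = np.zeros((2, 2, 2))
    t = np.zeros((2, 2, 2))
    t[0, 0, :] = 1.0   # goodA sourced from R1 everywhere
    t[1, 1, :] = 1.0   # goodB from R2
    c = np.array([[0.6, 0.6], [0.4, 0.4]])
    sam = build_sam_from_shares(cfg, cells, a, t, c, labor_of_nonland=1.0)
    return cfg, calibrate(sam, cells, cfg, el)


@pytest.fixture(scope="session")
def solved_pair(world, asm_setup):
    """Baseline and counterfactual equilibria plus their land-change table."""
    _, params = asm_setup
    drivers = Drivers()
    base = run_baseline(params, drivers, world.config)
    covered = list(params.cells.loc[params.cells["compliant"], "cell_id"])
    z0 = np.concatenate([base.z, np.zeros(len(covered))])
    cf = run_counterfactual(params, drivers, world.config, covered, z0=z0)
    table = diff_land(base, cf, covered_cells=covered)
    return base, cf, table
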
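"""Equilibrium core: calibration identities, replication, closed-form
oracles, policy constraint behaviour."""
import copy

import numpy as np
import pytest

from soyshift.config import Drivers
from soyshift.model import (CalibrationError, Shocks, apply_zdsp, calibrate,
                            diff_land, replication_check, run_baseline,
                            run_counterfactual, solve)

# ---------------------------------------------------------------------------
# analytic exchange toy
# ---------------------------------------------------------------------------


def test_exchange_toy_benchmark_ratio(exchange_toy_params):
    _, params = exchange_toy_params
    # Cobb-Douglas shares fix the benchmark output value ratio at 0.6/0.4
    assert params.y0[0, 0] / params.y0[1, 1] == pytest.approx(1.5, abs=1e-9)
    rep = replication_check(params)
    assert rep["max_residual"] < 1e-8


def test_exchange_toy_matches_closed_form(exchange_toy_params):
    """A 20% labour endowment shock in region 2: the relative price of
    good A rises to exactly 1.2 and quantities scale with endowments."""
    _, params = exchange_toy_params
    sh = Shocks(endow_labor=np.array([1.0, 1.2]))
    eq = solve(params, sh)
    assert eq.q[0, 0] / params.y0[0, 0] == pytest.approx(1.0, abs=1e-8)
    assert eq.q[1, 1] / params.y0[1, 1] == pytest.approx(1.2, abs=1e-8)
    assert eq.p[0, 0] / eq.p[1, 1] == pytest.approx(1.2, abs=1e-8)
    assert abs(eq.walras) < 1e-8


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def test_calibration_shares_equal_value_shares(asm_setup):
    """CES/CD share coefficients are benchmark value shares: they lie in
    [0, 1] and sum to one within every nest."""
    _, params = asm_setup
    va0 = params.lab0 + params.cap0
    for c in range(params.nc):
        r = params.cell_region[c]
        va0[r, params.sectors.index(params.forest_sector)] += 0
    # cost shares per activity sum to 1 (intermediates + value added)
    interm = params.io0.sum(axis=0)
    land = np.zeros_like(params.y0)
    for c in range(params.nc):
        r = params.cell_region[c]
        land[r, params.sectors.index(params.forest_sector)] += params.val_f0[c]
        land[r, params.sectors.index(params.pasture_sector)] += params.val_p0[c]
        for k, crop in enumerate(params.crops):
            land[r, params.sectors.index(crop)] += params.val_c0[c, k]
    total = interm + params.lab0 + params.cap0 + land
    assert np.allclose(total, params.y0, rtol=1e-8)
    # LES marginal budget shares sum to one
    assert np.allclose(params.beta.sum(axis=0), 1.0, atol=1e-12)


def test_replication_on_mini_world(asm_setup):
    _, params = asm_setup
    rep = replication_check(params)
    assert rep["passed"] and rep["max_residual"] < 1e-8
    # deterministic across invocations
    rep2 = replication_check(params)
    assert rep["worst_equations"] == rep2["worst_equations"]


def test_replication_negative_control(asm_setup):
    """A perturbed share coefficient breaks replication and is flagged."""
    _, params = asm_setup
    bad = copy.deepcopy(params)
    bad.lab0 = bad.lab0 * 1.05
    rep = replication_check(bad)
    assert not rep["passed"]
    assert rep["max_residual"] > 1e-4


def test_zero_value_nest_raises(world):
    from soyshift.model import model_cells
    from soyshift import ScenarioSpec, build_compliance, split_accounts
    spec = ScenarioSpec(name="ASM", threshold="ge50")
    comp = build_compliance(world.municipalities, world.trader_exports,
                            world.roster, spec)
    fp = split_accounts(world.municipalities, comp, spec, world.config)
    cells = model_cells(fp, world.land_cells, world.config)
    cells = cells.copy()
    cells.loc[:, "pasture_ha"] = 0.0   # grazing livestock loses its nest
    with pytest.raises(CalibrationError, match="zero"):
        calibrate(world.sam, cells, world.config)


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------


def test_zero_shocks_reproduce_benchmark(asm_setup):
    _, params = asm_setup
    eq = solve(params)
    assert np.allclose(eq.p, 1.0, atol=1e-9)
    assert np.allclose(eq.q, params.y0, rtol=1e-9)
    assert eq.iterations == 0


def test_homogeneity_doubling_numeraire(world, asm_setup, solved_pair):
    """Doubling the numeraire doubles every price and leaves all real
    quantities and land areas unchanged."""
    _, params = asm_setup
    base, _, _ = solved_pair
    from soyshift.model import shocks_from_drivers
    sh = shocks_from_drivers(params, Drivers(), world.config)
    eq2 = solve(params, sh, numeraire_scale=2.0)
    assert np.allclose(eq2.p, 2.0 * base.p, rtol=1e-7)
    assert np.allclose(eq2.w, 2.0 * base.w, rtol=1e-7)
    assert np.allclose(eq2.q, base.q, rtol=1e-7)
    assert np.allclose(eq2.areas["forest_ha"], base.areas["forest_ha"],
                       rtol=1e-7)


def test_walras_law_on_shocked_run(solved_pair):
    base, cf, _ = solved_pair
    assert abs(base.walras) < 1e-8
    assert abs(cf.walras) < 1e-8


def test_land_adding_up_each_cell(asm_setup, solved_pair):
    _, params = asm_setup
    total0 = (params.area_f0 + params.area_o0 + params.area_p0
              + params.area_c0.sum(axis=1))
    for eq in solved_pair[:2]:
        tot = (eq.areas["forest_ha"] + eq.areas["other_natural_ha"]
               + eq.areas["pasture_ha"] + eq.areas["cropland_ha"]).to_numpy()
        assert np.allclose(tot, total0, rtol=1e-6)


def test_oilseed_demand_driver_expands_soy_and_clears_forest(world, asm_setup):
    """A pure oilseed demand shock raises Brazilian oilseed area and
    converts forest somewhere in Brazil."""
    _, params = asm_setup
    drv = Drivers.zero()
    drv.biofuel_demand = {"CHNROW": 2.0}
    eq = run_baseline(params, drv, world.config)
    bra = params.cell_region == 0
    osd_area0 = params.area_c0[bra, 0].sum()
    osd_area = eq.areas.loc[bra, "crop_oilseeds_ha"].sum()
    assert osd_area > osd_area0
    d_forest = eq.areas.loc[bra, "forest_ha"].to_numpy() - params.area_f0[bra]
    assert d_forest.min() < 0


# ---------------------------------------------------------------------------
# the conversion freeze
# ---------------------------------------------------------------------------


def test_empty_coverage_is_noop(world, asm_setup):
    _, params = asm_setup
    drv = Drivers()
    base = run_baseline(params, drv, world.config)
    cf = run_counterfactual(params, drv, world.config, [])
    assert np.allclose(cf.p, base.p, atol=1e-9)
    assert np.allclose(cf.areas["forest_ha"], base.areas["forest_ha"],
                       atol=1e-9)


def test_freeze_holds_restricted_cover_exactly(asm_setup, solved_pair):
    _, params = asm_setup
    _, cf, _ = solved_pair
    covered = params.cells["compliant"].to_numpy()
    got = cf.areas.loc[covered, "forest_ha"].to_numpy()
    target = params.area_f0[covered]
    assert np.allclose(got, target, rtol=1e-8)
    assert (cf.subsidy["subsidy_wedge"] >= -1e-10).all()


def test_freeze_raises_covered_agricultural_rents(asm_setup, solved_pair):
    """Halting conversion makes agricultural land scarcer inside covered
    cells: crop and pasture rents weakly exceed the unconstrained run."""
    _, params = asm_setup
    base, cf, _ = solved_pair
    covered = params.cells["compliant"].to_numpy()
    assert (cf.rr_c[covered] >= base.rr_c[covered] - 1e-10).all()
    assert (cf.rr_p[covered] >= base.rr_p[covered] - 1e-10).all()


def test_freeze_world_price_and_uncovered_expansion(asm_setup, solved_pair):
    """Leakage channels: the commodity's world price weakly rises and
    uncovered agricultural area weakly expands."""
    _, params = asm_setup
    base, cf, table = solved_pair
    osd = params.sectors.index("oilseeds")
    assert (cf.p[:, osd] >= base.p[:, osd] - 1e-12).all()
    t = table.table
    assert (t.loc[~t["covered"], "d_cropland"]
            + t.loc[~t["covered"], "d_pasture"] > -1e-9).all()
    # displaced clearing: uncovered forest deltas are non-positive
    assert (t.loc[~t["covered"], "d_forest"] <= 1e-9).all()


def test_unknown_covered_cell_raises(asm_setup):
    _, params = asm_setup
    with pytest.raises(KeyError):
        apply_zdsp(params, ["BRA:Nowhere:AEZ1:ZDC"])


# ---------------------------------------------------------------------------
# differencing
# ---------------------------------------------------------------------------


def test_diff_identical_equilibria_is_zero(solved_pair):
    base, _, _ = solved_pair
    tab = diff_land(base, base, covered_cells=[])
    assert np.allclose(tab.table.filter(like="d_").to_numpy(), 0.0)


def test_diff_additivity_exact(solved_pair):
    _, _, table = solved_pair
    assert table.delta_global == pytest.approx(
        table.delta_zdsp + table.delta_no_zdsp, abs=1e-12)


def test_diff_partition_follows_footprint(asm_setup, solved_pair):
    _, params = asm_setup
    _, _, table = solved_pair
    covered = set(params.cells.loc[params.cells["compliant"], "cell_id"])
    t = table.table
    assert set(t.loc[t["covered"], "cell_id"]) == covered


def test_diff_mismatched_dimensions_raise(solved_pair, asm_setup):
    base, cf, _ = solved_pair
    clipped = copy.deepcopy(cf)
    clipped.areas = cf.areas.iloc[:-1]
    with pytest.raises(ValueError, match="dimension"):
        diff_land(base, clipped)
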
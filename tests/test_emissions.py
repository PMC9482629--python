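"""Emission-factor assembly and transition attribution."""
import numpy as np
import pandas as pd
import pytest

from soyshift.emissions import (CO2_PER_C, COVERS, EFAssumptions,
                                build_ef_matrix, emissions_from_deltas,
                                synthetic_carbon_stocks,
                                transitions_from_deltas)
from soyshift.model import LandChangeTable


def _stocks(cell="c1", forest=100.0, other=20.0, pasture=8.0, crop=5.0,
            dom=0.0, soil=0.0):
    rows = []
    for cover, bio in zip(COVERS, (forest, other, pasture, crop)):
        rows.append({"cell_id": cell, "cover": cover, "biomass_c": bio,
                     "dom_c": dom, "soil_c": soil})
    return pd.DataFrame(rows)


_BARE = EFAssumptions(sequestration_rate=0.0, wood_product_fraction=0.0,
                      fire_fraction=0.0, include_foregone_sequestration=False)


def test_zero_stocks_zero_matrix():
    efm = build_ef_matrix(_stocks(forest=0, other=0, pasture=0, crop=0),
                          _BARE)
    assert np.allclose(efm.table["total"], 0.0)


def test_stoichiometric_conversion():
    """Forest 100 t C/ha to cropland 10 t C/ha with no other components:
    factor is (100 - 10) x 44/12."""
    efm = build_ef_matrix(_stocks(forest=100.0, crop=10.0), _BARE)
    assert efm.factor("c1", "forest", "cropland") == pytest.approx(
        90.0 * CO2_PER_C)
    assert efm.factor("c1", "forest", "forest") == 0.0


def test_components_sum_to_total_random_config():
    rng = np.random.default_rng(0)
    stocks = _stocks(forest=rng.uniform(80, 160), other=rng.uniform(10, 40),
                     pasture=rng.uniform(4, 12), crop=rng.uniform(2, 8),
                     dom=5.0, soil=30.0)
    a = EFAssumptions(sequestration_rate=rng.uniform(1, 5),
                      wood_product_fraction=0.12, fire_fraction=0.4)
    efm = build_ef_matrix(stocks, a)
    comp_cols = [c for c in efm.table.columns if c != "total"]
    assert np.allclose(efm.table[comp_cols].sum(axis=1),
                       efm.table["total"], atol=1e-9)


def test_negative_stock_rejected():
    bad = _stocks()
    bad.loc[0, "biomass_c"] = -1.0
    with pytest.raises(ValueError, match="negative"):
        build_ef_matrix(bad)


def test_regrowth_discount_asymmetric_by_default():
    efm = build_ef_matrix(_stocks(), EFAssumptions(
        sequestration_rate=0.0, wood_product_fraction=0.0, fire_fraction=0.0,
        include_foregone_sequestration=False, regrowth_discount=0.5))
    fwd = efm.factor("c1", "forest", "cropland")
    rev = efm.factor("c1", "cropland", "forest")
    assert rev == pytest.approx(-0.5 * fwd)
    sym = build_ef_matrix(_stocks(), EFAssumptions(
        sequestration_rate=0.0, wood_product_fraction=0.0, fire_fraction=0.0,
        include_foregone_sequestration=False, symmetric=True))
    assert sym.factor("c1", "cropland", "forest") == pytest.approx(
        -sym.factor("c1", "forest", "cropland"))


# ---------------------------------------------------------------------------
# transition attribution
# ---------------------------------------------------------------------------


def test_transitions_simple_deforestation():
    flows = dict(((a, b), h) for a, b, h
                 in transitions_from_deltas(-10.0, 0.0, 4.0, 6.0))
    assert flows[("forest", "pasture")] == pytest.approx(4.0)
    assert flows[("forest", "cropland")] == pytest.approx(6.0)


def test_transitions_internal_transfers_first():
    # forest grows while grassland shrinks: internal natural transfer
    flows = dict(((a, b), h) for a, b, h
                 in transitions_from_deltas(5.0, -5.0, 0.0, 0.0))
    assert flows == {("other_natural", "forest"): pytest.approx(5.0)}
    # pasture to cropland intensification path
    flows = dict(((a, b), h) for a, b, h
                 in transitions_from_deltas(0.0, 0.0, -3.0, 3.0))
    assert flows == {("pasture", "cropland"): pytest.approx(3.0)}


def test_transitions_mixed_signs_split_proportionally():
    flows = dict(((a, b), h) for a, b, h
                 in transitions_from_deltas(5.0, -2.0, -1.0, -2.0))
    assert flows[("other_natural", "forest")] == pytest.approx(2.0)
    assert flows[("pasture", "forest")] == pytest.approx(1.0)
    assert flows[("cropland", "forest")] == pytest.approx(2.0)


def test_transitions_nonconserving_rejected():
    with pytest.raises(ValueError, match="conserve"):
        transitions_from_deltas(-10.0, 0.0, 0.0, 5.0)


# ---------------------------------------------------------------------------
# valuation
# ---------------------------------------------------------------------------


def _delta_table(d_forest, d_pasture, d_cropland, cell="c1", region="BRA"):
    df = pd.DataFrame([{
        "cell_id": cell, "region": region, "biome": "Amazon",
        "covered": False, "d_forest": d_forest, "d_other_natural":
        -(d_forest + d_pasture + d_cropland), "d_pasture": d_pasture,
        "d_cropland": d_cropland}])
    return LandChangeTable(table=df, policy_region="BRA")


def test_zero_deltas_zero_report():
    efm = build_ef_matrix(_stocks(), _BARE)
    rep = emissions_from_deltas(_delta_table(0.0, 0.0, 0.0), efm)
    assert rep.total_kt == 0.0


def test_ten_kha_at_three_hundred_tonnes():
    """10 kha of forest-to-cropland at 300 t CO2e/ha is 3,000 kt CO2e."""
    bio = 300.0 / CO2_PER_C + 5.0  # forest stock giving a 300 t/ha factor
    efm = build_ef_matrix(_stocks(forest=bio, crop=5.0), _BARE)
    table = LandChangeTable(table=pd.DataFrame([{
        "cell_id": "c1", "region": "BRA", "biome": "Amazon", "covered": False,
        "d_forest": -10.0, "d_other_natural": 0.0, "d_pasture": 0.0,
        "d_cropland": 10.0}]), policy_region="BRA")
    rep = emissions_from_deltas(table, efm)
    assert rep.total_kt == pytest.approx(3000.0)


def test_linearity_doubling_deltas():
    efm = build_ef_matrix(_stocks(dom=3.0, soil=25.0),
                          EFAssumptions(symmetric=True))
    r1 = emissions_from_deltas(_delta_table(-4.0, 1.5, 2.5), efm)
    r2 = emissions_from_deltas(_delta_table(-8.0, 3.0, 5.0), efm)
    assert r2.total_kt == pytest.approx(2 * r1.total_kt)


def test_global_equals_sum_of_regions(solved_pair):
    _, _, table = solved_pair
    cells = table.table.rename(columns={})
    stocks = synthetic_carbon_stocks(
        cells.assign(biome=cells["biome"]), seed=0)
    efm = build_ef_matrix(stocks, EFAssumptions(symmetric=True))
    rep = emissions_from_deltas(table, efm)
    assert rep.by_region.sum() == pytest.approx(rep.total_kt)


def test_avoided_deforestation_saves_emissions(solved_pair):
    """Net global avoided deforestation with forest-dominant carbon
    stocks gives a negative (saving) emissions delta."""
    _, _, table = solved_pair
    assert table.delta_global > 0
    stocks = synthetic_carbon_stocks(table.table, seed=1)
    efm = build_ef_matrix(stocks, EFAssumptions(symmetric=True))
    rep = emissions_from_deltas(table, efm)
    assert rep.total_kt < 0
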
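"""Footprint construction: market shares, thresholds, account splitting."""
import numpy as np
import pandas as pd
import pytest

from soyshift.config import WorldConfig
from soyshift.footprint import (ComplianceMap, ScenarioSpec,
                                apply_forest_definition, assign_cell,
                                build_compliance, classify_municipality,
                                committed_share, coverage_stats,
                                resolve_scenario_companies, scenario_grid,
                                split_accounts)


def _exports(rows):
    return pd.DataFrame(rows, columns=["muni_id", "company_id",
                                       "destination", "volume_t"])


@pytest.mark.parametrize("committed,expected", [
    ({"A", "B"}, 0.80), (set(), 0.0), ({"A", "B", "C"}, 1.0),
])
def test_committed_share_arithmetic(committed, expected):
    exp = _exports([("M1", "A", "EU", 50.0), ("M1", "B", "China", 30.0),
                    ("M1", "C", "OtherDest", 20.0)])
    assert committed_share(exp, committed) == pytest.approx(expected)


def test_committed_share_zero_volume_is_undefined():
    exp = _exports([("M1", "A", "EU", 0.0)])
    assert np.isnan(committed_share(exp, {"A"}))
    assert classify_municipality(committed_share(exp, {"A"}), "gt0") is False


@pytest.mark.parametrize("share,threshold,expected", [
    (0.80, "ge75", True), (0.50, "ge50", True), (0.75, "ge75", True),
    (0.7499, "ge75", False), (0.0, "gt0", False), (1e-9, "gt0", True),
])
def test_threshold_boundaries(share, threshold, expected):
    assert classify_municipality(share, threshold) is expected


def test_destination_rule_covers_entire_supply_chain():
    """One tonne to the EU commits a company everywhere."""
    exp = _exports([("M1", "X", "EU", 1.0), ("M2", "X", "China", 999.0),
                    ("M2", "Y", "China", 10.0)])
    roster = pd.DataFrame({"name": ["X", "Y"], "company_id": ["X", "Y"]})
    spec = ScenarioSpec(name="custom", destination_rule=["EU"])
    assert resolve_scenario_companies(spec, exp, roster) == {"X"}
    spec_union = ScenarioSpec(name="custom", destination_rule=["EU", "China"])
    assert resolve_scenario_companies(spec_union, exp, roster) == {"X", "Y"}


def test_destination_rule_empty_and_unknown():
    exp = _exports([("M1", "X", "China", 5.0)])
    roster = pd.DataFrame({"name": ["X"], "company_id": ["X"]})
    spec = ScenarioSpec(name="custom", destination_rule=["EU"])
    with pytest.raises(ValueError, match="unknown destination"):
        resolve_scenario_companies(spec, exp, roster)
    exp2 = _exports([("M1", "X", "China", 5.0), ("M2", "Y", "EU", 0.1)])
    roster2 = pd.DataFrame({"name": ["X", "Y"], "company_id": ["X", "Y"]})
    assert resolve_scenario_companies(spec, exp2, roster2) == {"Y"}


def test_assign_cell_rules():
    assert assign_cell({"AEZ5": 0.7, "AEZ6": 0.3},
                       {"Cerrado": 1.0}) == ("AEZ5", "Cerrado")
    # biome resolved by stringency priority, not area
    assert assign_cell({"AEZ5": 1.0},
                       {"Amazon": 0.2, "Cerrado": 0.8})[1] == "Amazon"
    assert assign_cell({"AEZ9": 1.0}, {"Other": 1.0}) == ("AEZ9", "Other")
    with pytest.raises(ValueError):
        assign_cell({}, {"Amazon": 1.0})


@pytest.mark.parametrize("biome,definition,expected", [
    ("Amazon", "B", 100.0),   # definition B reduces to A inside the Amazon
    ("Cerrado", "B", 130.0),
    ("Cerrado", "A", 100.0),
    ("Amazon", "A", 100.0),
])
def test_forest_definitions(biome, definition, expected):
    muni = {"biome": biome, "forest_A_ha": 100.0, "forest_B_ha": 130.0}
    assert apply_forest_definition(muni, definition) == expected


def _hand_world():
    """Five municipalities with round numbers for hand enumeration."""
    cols = ["muni_id", "biome", "aez_id", "forest_A_ha", "forest_B_ha",
            "other_natural_ha", "cropland_ha", "pasture_ha", "soy_area_ha",
            "soy_production_t", "maize2_area_ha", "cattle_heads"]
    rows = [
        ("M1", "Amazon", "AEZ5", 100.0, 100.0, 10.0, 20.0, 30.0, 10.0, 3e4, 2.0, 1e4),
        ("M2", "Amazon", "AEZ5", 50.0, 50.0, 5.0, 10.0, 15.0, 5.0, 1.5e4, 1.0, 5e3),
        ("M3", "Cerrado", "AEZ5", 30.0, 45.0, 5.0, 40.0, 35.0, 25.0, 7.5e4, 8.0, 2e4),
        ("M4", "Cerrado", "AEZ6", 20.0, 30.0, 4.0, 30.0, 25.0, 15.0, 4.5e4, 5.0, 1e4),
        ("M5", "Other", "AEZ6", 10.0, 12.0, 2.0, 15.0, 20.0, 5.0, 1.5e4, 1.0, 8e3),
    ]
    return pd.DataFrame(rows, columns=cols)


def _compliance(flags):
    return ComplianceMap(table=pd.DataFrame(
        {"muni_id": [f"M{i+1}" for i in range(5)],
         "share": [1.0 if f else 0.0 for f in flags],
         "compliant": flags}))


def test_split_accounts_hand_enumeration():
    """M1 compliant, M2 not, both in Amazon/AEZ5: cells must match the
    hand-computed enumeration exactly."""
    cfg = WorldConfig(random_seed=0)
    munis = _hand_world()
    comp = _compliance([True, False, True, False, False])
    spec = ScenarioSpec(name="GlobalZDC", threshold="ge50",
                        forest_definition="A")
    cells = split_accounts(munis, comp, spec, cfg).set_index("cell_id")
    c = cells.loc["BRA:Amazon:AEZ5:ZDC"]
    assert c["forest_ha"] == pytest.approx(100.0)
    assert c["other_natural_ha"] == pytest.approx(10.0)  # 110 natural - 100
    assert c["crop_oilseeds_ha"] == pytest.approx(10.0)
    assert c["crop_coarse_grains_ha"] == pytest.approx(10.0)
    c2 = cells.loc["BRA:Amazon:AEZ5:NonZDC"]
    assert c2["forest_ha"] == pytest.approx(50.0)
    c3 = cells.loc["BRA:Cerrado:AEZ5:ZDC"]
    assert c3["forest_ha"] == pytest.approx(30.0)   # definition A
    assert c3["other_natural_ha"] == pytest.approx(20.0)  # 45+5 - 30
    # national conservation
    assert cells["pasture_ha"].sum() == pytest.approx(125.0)
    assert cells["cropland_ha"].sum() == pytest.approx(115.0)


def test_split_accounts_definition_b_moves_grassland():
    cfg = WorldConfig(random_seed=0)
    munis = _hand_world()
    comp = _compliance([False, False, True, False, False])
    spec = ScenarioSpec(name="GlobalZDC", threshold="ge50",
                        forest_definition="B")
    cells = split_accounts(munis, comp, spec, cfg).set_index("cell_id")
    c3 = cells.loc["BRA:Cerrado:AEZ5:ZDC"]
    assert c3["forest_ha"] == pytest.approx(45.0)       # forest + grassland
    assert c3["other_natural_ha"] == pytest.approx(5.0)


def test_split_accounts_all_compliant_leaves_no_uncovered_area():
    cfg = WorldConfig(random_seed=0)
    cells = split_accounts(_hand_world(), _compliance([True] * 5),
                           ScenarioSpec(name="GlobalZDC"), cfg)
    assert cells["compliant"].all()


def test_coverage_stats_hand_and_monotone(world):
    spec = ScenarioSpec(name="GlobalZDC", threshold="ge75")
    cov = coverage_stats(world.municipalities, world.trader_exports,
                         world.roster, spec)
    assert ((cov >= 0) & (cov <= 1)).all().all()
    for col in cov.columns:
        assert cov.loc["gt0", col] >= cov.loc["ge50", col] >= \
            cov.loc["ge75", col]


def test_compliant_sets_nest_by_threshold(world):
    sets = {}
    for t in ("gt0", "ge50", "ge75"):
        spec = ScenarioSpec(name="GlobalZDC", threshold=t)
        comp = build_compliance(world.municipalities, world.trader_exports,
                                world.roster, spec)
        sets[t] = comp.compliant_ids()
    assert sets["ge75"] <= sets["ge50"] <= sets["gt0"]


def test_asm_restricted_to_amazon(world):
    spec = ScenarioSpec(name="ASM", threshold="gt0")
    comp = build_compliance(world.municipalities, world.trader_exports,
                            world.roster, spec)
    biome = dict(zip(world.municipalities["muni_id"],
                     world.municipalities["biome"]))
    assert all(biome[m] == "Amazon" for m in comp.compliant_ids())


def test_scenario_grid_enumerates_30_unique_runs():
    grid = scenario_grid()
    keys = {(s.name, s.threshold, s.forest_definition) for s in grid}
    assert len(grid) == 30 and len(keys) == 30
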
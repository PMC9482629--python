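"""Spatial footprint of zero-deforestation supply-chain policy scenarios.

A scenario names the committed traders (explicitly, or through a
destination rule such as "every company exporting to the EU"), a market
share threshold (>0%, >=50%, >=75%) deciding whether a municipality is
effectively covered, and a forest definition (A: forest only; B: forest
plus natural grassland outside the Amazon). The footprint stage
classifies municipalities, then splits land and output accounts into
biome x AEZ x compliance model cells while conserving national totals.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import WorldConfig
from .world import asm_companies, global_zdc_companies, _crop_areas

logger = logging.getLogger(__name__)

THRESHOLDS = ("gt0", "ge50", "ge75")
SCENARIOS = ("ASM", "GlobalZDC", "EU", "China", "EU_and_China")
FOREST_DEFINITIONS = ("A", "B")

#: marker for municipalities with no exported volume (treated non-compliant)
UNDEFINED_SHARE = float("nan")


@dataclass
class ScenarioSpec:
    """A policy configuration: who is committed, where, and how strictly.

    Exactly one of ``committed_companies`` (explicit roster by name) or
    ``destination_rule`` (list of destination markets; every company with
    any export there is committed across its entire supply chain) must be
    set for custom scenarios; the five named scenarios configure
    themselves.
    """

    name: str
    threshold: str = "ge75"
    forest_definition: str = "A"
    committed_companies: list | None = None
    destination_rule: list | None = None
    applies_in_biomes: list | None = None   # None = all biomes
    include_asm: bool = False  # destination scenarios keep the ASM in the Amazon

    def __post_init__(self):
        if self.threshold not in THRESHOLDS:
            raise ValueError(f"unknown threshold {self.threshold!r}")
        if self.forest_definition not in FOREST_DEFINITIONS:
            raise ValueError(f"unknown forest definition "
                             f"{self.forest_definition!r}")
        if self.name in SCENARIOS:
            self._configure_named()
        if (self.committed_companies is None) == (self.destination_rule is None):
            raise ValueError("set exactly one of committed_companies / "
                             "destination_rule")

    def _configure_named(self):
        if self.name == "ASM":
            self.committed_companies = asm_companies()
            self.applies_in_biomes = ["Amazon"]
        elif self.name == "GlobalZDC":
            self.committed_companies = sorted(
                set(asm_companies()) | set(global_zdc_companies()))
            self.applies_in_biomes = None
            self.include_asm = True
        elif self.name == "EU":
            self.destination_rule = ["EU"]
            self.include_asm = True
        elif self.name == "China":
            self.destination_rule = ["China"]
            self.include_asm = True
        elif self.name == "EU_and_China":
            self.destination_rule = ["EU", "China"]
            self.include_asm = True


def scenario_grid():
    """The full 5 x 3 x 2 = 30 scenario grid, enumerated without duplicates."""
    return [ScenarioSpec(name=n, threshold=t, forest_definition=d)
            for n in SCENARIOS for t in THRESHOLDS for d in FOREST_DEFINITIONS]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def committed_share(exports_of_muni: pd.DataFrame, committed: set) -> float:
    """Committed-trader share of a municipality's exported volume, in [0, 1].

    Returns the undefined marker (NaN) when the municipality exports
    nothing; such municipalities are treated as non-compliant.
    """
    total = exports_of_muni["volume_t"].sum()
    if total <= 0:
        logger.debug("municipality with zero exported volume")
        return UNDEFINED_SHARE
    mask = exports_of_muni["company_id"].isin(committed)
    return float(exports_of_muni.loc[mask, "volume_t"].sum() / total)


def classify_municipality(share: float, threshold: str) -> bool:
    """Apply a market-share threshold: strict for gt0, inclusive for 50/75."""
    if threshold not in THRESHOLDS:
        raise ValueError(f"unknown threshold {threshold!r}")
    if share is None or np.isnan(share):
        return False
    return {"gt0": share > 0.0,
            "ge50": share >= 0.5,
            "ge75": share >= 0.75}[threshold]


def resolve_scenario_companies(spec: ScenarioSpec,
                               trader_exports: pd.DataFrame,
                               roster: pd.DataFrame) -> set:
    """Company ids committed under a scenario.

    Destination rules cover a company's *entire* supply chain: any export
    to a named destination commits all of its purchases everywhere.
    """
    name_to_id = dict(zip(roster["name"], roster["company_id"]))
    if spec.destination_rule is not None:
        known = set(trader_exports["destination"].unique())
        for d in spec.destination_rule:
            if d not in known:
                raise ValueError(f"unknown destination label {d!r}")
        mask = trader_exports["destination"].isin(spec.destination_rule)
        ids = set(trader_exports.loc[mask, "company_id"].unique())
        return ids
    return {name_to_id[n] for n in spec.committed_companies
            if n in name_to_id}


def _amazon_roster_ids(roster: pd.DataFrame) -> set:
    asm = set(asm_companies())
    return set(roster.loc[roster["name"].isin(asm), "company_id"])


@dataclass
class ComplianceMap:
    """Per-municipality committed market share and compliance flag."""

    table: pd.DataFrame = field(repr=False)  # muni_id, share, compliant
    n_zero_export: int = 0

    def compliant_ids(self):
        return set(self.table.loc[self.table["compliant"], "muni_id"])


def build_compliance(munis: pd.DataFrame, trader_exports: pd.DataFrame,
                     roster: pd.DataFrame, spec: ScenarioSpec) -> ComplianceMap:
    """Classify every municipality under a scenario specification.

    The committed roster may be biome-scoped: the moratorium applies only
    inside the Amazon; destination scenarios add the moratorium roster on
    top of the destination-rule roster within the Amazon.
    """
    committed = resolve_scenario_companies(spec, trader_exports, roster)
    amazon_extra = _amazon_roster_ids(roster) if spec.include_asm else set()
    by_muni = dict(tuple(trader_exports.groupby("muni_id")))
    rows, n_zero = [], 0
    for _, muni in munis.iterrows():
        mid, biome = muni["muni_id"], muni["biome"]
        exp = by_muni.get(mid)
        roster_here = committed | (amazon_extra if biome == "Amazon" else set())
        in_scope = (spec.applies_in_biomes is None
                    or biome in spec.applies_in_biomes)
        if exp is None or exp["volume_t"].sum() <= 0:
            share, n_zero = UNDEFINED_SHARE, n_zero + 1
        else:
            share = committed_share(exp, roster_here)
        flag = in_scope and classify_municipality(share, spec.threshold)
        rows.append({"muni_id": mid, "share": share, "compliant": bool(flag)})
    if n_zero:
        logger.info("%d municipalities with zero exports treated as "
                    "non-compliant", n_zero)
    return ComplianceMap(table=pd.DataFrame(rows), n_zero_export=n_zero)


# ---------------------------------------------------------------------------
# spatial assignment and forest definitions
# ---------------------------------------------------------------------------

_BIOME_PRIORITY = {"Amazon": 0, "Cerrado": 1, "Other": 2}


def assign_cell(aez_intersections: dict, biome_intersections: dict):
    """Resolve a split municipality to one (AEZ, biome).

    AEZ by largest intersection; biome by policy stringency priority
    (Amazon, then Cerrado, then Other) among biomes with any overlap.
    """
    if not aez_intersections or not biome_intersections:
        raise ValueError("no candidate AEZ/biome intersections")
    aez = max(sorted(aez_intersections), key=lambda k: aez_intersections[k])
    candidates = [b for b, f in biome_intersections.items() if f > 0]
    if not candidates:
        raise ValueError("no biome with positive intersection")
    biome = min(candidates, key=lambda b: _BIOME_PRIORITY.get(b, 99))
    return aez, biome


def apply_forest_definition(muni, definition: str) -> float:
    """Restricted natural cover of a municipality under a forest definition.

    A: mapped forest only, everywhere. B: forest in the Amazon, forest
    plus natural grassland elsewhere.
    """
    if definition == "A":
        return float(muni["forest_A_ha"])
    if definition == "B":
        if muni["biome"] == "Amazon":
            return float(muni["forest_A_ha"])
        return float(muni["forest_B_ha"])
    raise ValueError(f"unknown forest definition {definition!r}")


# ---------------------------------------------------------------------------
# account splitting
# ---------------------------------------------------------------------------


def split_accounts(munis: pd.DataFrame, compliance: ComplianceMap,
                   spec: ScenarioSpec, config: WorldConfig) -> pd.DataFrame:
    """Split municipalities into biome x AEZ x compliance model cells.

    The cell's ``forest_ha`` is the *restricted* cover under the
    scenario's forest definition; ``other_natural_ha`` is the remaining
    natural cover. National totals of every cover, soy area/production
    and crop areas are conserved exactly.
    """
    flags = dict(zip(compliance.table["muni_id"],
                     compliance.table["compliant"]))
    bra = config.regions[0]
    m = munis.copy()
    m["compliant"] = m["muni_id"].map(flags).fillna(False)
    m["restricted"] = [apply_forest_definition(r, spec.forest_definition)
                       for _, r in m.iterrows()]
    m["natural_total"] = (m["forest_B_ha"] + m["other_natural_ha"])
    m["other_nat_model"] = m["natural_total"] - m["restricted"]
    rows = []
    for (biome, aez, comp), g in m.groupby(["biome", "aez_id", "compliant"],
                                           sort=True):
        tag = "ZDC" if comp else "NonZDC"
        crop = _crop_areas(g["cropland_ha"].sum(), g["soy_area_ha"].sum(),
                           config)
        rows.append({
            "cell_id": f"{bra}:{biome}:{aez}:{tag}",
            "base_cell_id": f"{bra}:{biome}:{aez}",
            "region": bra, "biome": biome, "aez_id": aez,
            "compliant": bool(comp),
            "forest_ha": g["restricted"].sum(),
            "other_natural_ha": g["other_nat_model"].sum(),
            "pasture_ha": g["pasture_ha"].sum(),
            "cropland_ha": g["cropland_ha"].sum(),
            "soy_area_ha": g["soy_area_ha"].sum(),
            "soy_production_t": g["soy_production_t"].sum(),
            **{f"crop_{c}_ha": a for c, a in crop.items()},
        })
    cells = pd.DataFrame(rows)
    # conservation check (exact up to float additivity)
    nat_tot = m["natural_total"].sum()
    split_tot = (cells["forest_ha"] + cells["other_natural_ha"]).sum()
    for tot, ref in [
            (split_tot, nat_tot),
            (cells["pasture_ha"].sum(), m["pasture_ha"].sum()),
            (cells["cropland_ha"].sum(), m["cropland_ha"].sum()),
            (cells["soy_area_ha"].sum(), m["soy_area_ha"].sum())]:
        if ref > 0 and abs(tot - ref) / ref > 1e-10:
            raise AssertionError("account split lost a national total")
    return cells


def coverage_stats(munis: pd.DataFrame, trader_exports: pd.DataFrame,
                   roster: pd.DataFrame, spec: ScenarioSpec,
                   thresholds=THRESHOLDS) -> pd.DataFrame:
    """Shares of national soy/cropland/pasture/forest inside compliant
    municipalities, per threshold; non-increasing in threshold stringency."""
    out = []
    nat = {
        "soy_area": munis["soy_area_ha"].sum(),
        "cropland": munis["cropland_ha"].sum(),
        "pasture": munis["pasture_ha"].sum(),
        "forest": munis["forest_A_ha"].sum(),
    }
    for t in thresholds:
        s = ScenarioSpec(name=spec.name, threshold=t,
                         forest_definition=spec.forest_definition)
        comp = build_compliance(munis, trader_exports, roster, s)
        ids = comp.compliant_ids()
        sub = munis[munis["muni_id"].isin(ids)]
        out.append({
            "threshold": t,
            "soy_area": sub["soy_area_ha"].sum() / nat["soy_area"],
            "cropland": sub["cropland_ha"].sum() / nat["cropland"],
            "pasture": sub["pasture_ha"].sum() / nat["pasture"],
            "forest": sub["forest_A_ha"].sum() / nat["forest"],
        })
    df = pd.DataFrame(out).set_index("threshold")
    order = [t for t in ("gt0", "ge50", "ge75") if t in df.index]
    for col in df.columns:
        vals = df.loc[order, col].to_numpy()
        if np.any(np.diff(vals) > 1e-12):
            raise AssertionError(f"coverage share of {col} increased with "
                                 f"threshold stringency")
    return df
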
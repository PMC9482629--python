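"""Land-use-change GHG accounting via a per-transition emission-factor
matrix.

Each (cell, from-cover, to-cover) transition carries a factor in
t CO2e/ha assembled from carbon-stock differences (above+below-ground
biomass, dead organic matter, soil carbon) plus foregone forest
sequestration over a 30-year horizon, a wood-product storage credit and
a non-CO2 (fire) term. Stocks are inputs — synthetic biome-typical
values by default, never hard-coded into the accounting.

Counterfactual differencing works on *net* cover deltas (a comparative-
static model yields net areas, not gross flows): deltas are attributed
to transitions along the land nest (natural vs agricultural first, then
pasture vs cropland) and valued with a symmetric factor matrix, so that
avoided clearing counts the full avoided emission rather than a
discounted regrowth. The asymmetric (regrowth-discounted) matrix is the
default for within-run transition accounting.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = ["EFAssumptions", "EmissionFactorMatrix", "EmissionsReport",
           "synthetic_carbon_stocks", "build_ef_matrix",
           "transitions_from_deltas", "emissions_from_deltas"]

CO2_PER_C = 44.0 / 12.0
COVERS = ("forest", "other_natural", "pasture", "cropland")


@dataclass
class EFAssumptions:
    """Emission-factor assembly assumptions (units noted per field)."""

    sequestration_rate: float = 3.0   # t CO2e/ha/yr foregone if forest cleared
    sequestration_horizon: float = 30.0  # years
    wood_product_fraction: float = 0.10  # biomass C stored in wood products
    fire_fraction: float = 0.5           # share of clearing by fire
    nonco2_per_fire_c: float = 0.35      # t CO2e per t C burned (CH4 + N2O)
    regrowth_discount: float = 0.5       # credit discount for reverse moves
    symmetric: bool = False              # reverse factor = -forward if True
    include_foregone_sequestration: bool = True

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


# biome-typical mean carbon stocks, t C/ha: (biomass, dead organic matter
# fraction of biomass, soil)
_STOCK_PROFILES = {
    "Amazon":  {"forest": (150, 40), "other_natural": (35, 25),
                "pasture": (8, 25), "cropland": (5, 20)},
    "Cerrado": {"forest": (60, 35), "other_natural": (20, 25),
                "pasture": (8, 22), "cropland": (5, 18)},
    "Other":   {"forest": (80, 38), "other_natural": (22, 25),
                "pasture": (8, 22), "cropland": (5, 18)},
    "BAP":     {"forest": (120, 38), "other_natural": (25, 25),
                "pasture": (8, 22), "cropland": (5, 18)},
    "USCAN":   {"forest": (70, 45), "other_natural": (15, 30),
                "pasture": (6, 28), "cropland": (4, 25)},
    "EU":      {"forest": (90, 42), "other_natural": (18, 28),
                "pasture": (6, 26), "cropland": (4, 22)},
    "CHNROW":  {"forest": (100, 38), "other_natural": (18, 25),
                "pasture": (6, 22), "cropland": (4, 18)},
}
_DOM_FRACTION = 0.08


def _stock_profile(biome):
    if biome in _STOCK_PROFILES:
        return _STOCK_PROFILES[biome]
    for key in _STOCK_PROFILES:
        if key in str(biome):
            return _STOCK_PROFILES[key]
    return _STOCK_PROFILES["Other"]


def synthetic_carbon_stocks(cells: pd.DataFrame, seed: int = 0,
                            noise: float = 0.08) -> pd.DataFrame:
    """Per-cell, per-cover carbon stocks drawn around biome-typical means.

    Columns: cell_id, cover, biomass_c, dom_c, soil_c (t C/ha).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _, cell in cells.iterrows():
        prof = _stock_profile(cell.get("biome", cell.get("region", "Other")))
        for cover in COVERS:
            bio, soil = prof[cover]
            f = float(np.exp(rng.normal(0.0, noise)))
            rows.append({
                "cell_id": cell["cell_id"], "cover": cover,
                "biomass_c": bio * f, "dom_c": bio * f * _DOM_FRACTION,
                "soil_c": soil * f,
            })
    return pd.DataFrame(rows)


@dataclass
class EmissionFactorMatrix:
    """Factors in t CO2e/ha by (cell_id, from-cover, to-cover) with a
    component breakdown; the diagonal (no transition) is zero."""

    table: pd.DataFrame
    assumptions: EFAssumptions = field(default_factory=EFAssumptions)

    def factor(self, cell_id, frm, to) -> float:
        if frm == to:
            return 0.0
        key = (cell_id, frm, to)
        try:
            return float(self.table.loc[key, "total"])
        except KeyError:
            raise KeyError(f"unmapped transition {key}") from None


_COMPONENTS = ["biomass", "dead_organic_matter", "soil",
               "foregone_sequestration", "wood_product_credit", "non_co2"]


def build_ef_matrix(carbon_stocks: pd.DataFrame,
                    assumptions: EFAssumptions | None = None
                    ) -> EmissionFactorMatrix:
    """Assemble the per-transition factor matrix from carbon stocks.

    Forward transitions (carbon-losing) emit the full stock difference
    plus foregone sequestration, fire non-CO2 and minus the wood-product
    credit. Reverse (carbon-gaining) transitions sequester; by default
    the credit is discounted (``regrowth_discount``), with
    ``symmetric=True`` it mirrors the forward factor exactly.
    """
    a = assumptions or EFAssumptions()
    if (carbon_stocks[["biomass_c", "dom_c", "soil_c"]] < 0).any().any():
        raise ValueError("negative carbon stock")
    stocks = carbon_stocks.set_index(["cell_id", "cover"])
    rows = []
    for cell_id in carbon_stocks["cell_id"].unique():
        for frm in COVERS:
            for to in COVERS:
                if frm == to or (cell_id, frm) not in stocks.index \
                        or (cell_id, to) not in stocks.index:
                    continue
                s0, s1 = stocks.loc[(cell_id, frm)], stocks.loc[(cell_id, to)]
                comp = _transition_components(s0, s1, frm, to, a)
                rows.append({"cell_id": cell_id, "from": frm, "to": to,
                             **comp, "total": sum(comp.values())})
    table = pd.DataFrame(rows).set_index(["cell_id", "from", "to"])
    if not np.isfinite(table.to_numpy()).all():
        raise ValueError("non-finite emission factor")
    return EmissionFactorMatrix(table=table, assumptions=a)


def _transition_components(s0, s1, frm, to, a: EFAssumptions) -> dict:
    d_bio = (s0["biomass_c"] - s1["biomass_c"]) * CO2_PER_C
    d_dom = (s0["dom_c"] - s1["dom_c"]) * CO2_PER_C
    d_soil = (s0["soil_c"] - s1["soil_c"]) * CO2_PER_C
    carbon_losing = d_bio + d_dom + d_soil >= 0
    comp = dict.fromkeys(_COMPONENTS, 0.0)
    if carbon_losing:
        comp["biomass"] = d_bio
        comp["dead_organic_matter"] = d_dom
        comp["soil"] = d_soil
        if frm == "forest":
            if a.include_foregone_sequestration:
                comp["foregone_sequestration"] = \
                    a.sequestration_rate * a.sequestration_horizon
            comp["wood_product_credit"] = \
                -a.wood_product_fraction * s0["biomass_c"] * CO2_PER_C
            comp["non_co2"] = (a.fire_fraction * s0["biomass_c"]
                               * a.nonco2_per_fire_c)
    else:
        scale = 1.0 if a.symmetric else a.regrowth_discount
        comp["biomass"] = d_bio * scale
        comp["dead_organic_matter"] = d_dom * scale
        comp["soil"] = d_soil * scale
        if a.symmetric and to == "forest":
            if a.include_foregone_sequestration:
                comp["foregone_sequestration"] = \
                    -a.sequestration_rate * a.sequestration_horizon
            comp["wood_product_credit"] = \
                a.wood_product_fraction * s1["biomass_c"] * CO2_PER_C
            comp["non_co2"] = -(a.fire_fraction * s1["biomass_c"]
                                * a.nonco2_per_fire_c)
    return comp


# ---------------------------------------------------------------------------
# transition attribution from net deltas
# ---------------------------------------------------------------------------


def transitions_from_deltas(d_forest, d_other_natural, d_pasture,
                            d_cropland, tol=1e-9) -> list:
    """Attribute net cover deltas of one cell to transition flows.

    Returns ``[(from, to, ha), ...]`` with positive ha in the actual
    conversion direction. Attribution follows the land nest: mixed signs
    within natural (forest/other natural) or within agriculture
    (pasture/cropland) become internal transfers first; the remaining
    single-signed natural-vs-agricultural gap becomes cross-nest flows
    split proportionally. Deltas must net to ~zero (fixed cell area).
    """
    d = {"forest": float(d_forest), "other_natural": float(d_other_natural),
         "pasture": float(d_pasture), "cropland": float(d_cropland)}
    total = sum(d.values())
    scale = max(sum(abs(v) for v in d.values()), 1.0)
    if abs(total) > 1e-6 * scale:
        raise ValueError("cover deltas do not conserve cell area")
    flows = []

    def internal(a, b):
        if d[a] < -tol and d[b] > tol:
            t = min(-d[a], d[b])
            flows.append((a, b, t))
            d[a] += t
            d[b] -= t
        elif d[b] < -tol and d[a] > tol:
            t = min(-d[b], d[a])
            flows.append((b, a, t))
            d[b] += t
            d[a] -= t

    internal("forest", "other_natural")
    internal("pasture", "cropland")
    sources = [c for c in ("forest", "other_natural", "pasture", "cropland")
               if d[c] < -tol]
    sinks = [c for c in ("forest", "other_natural", "pasture", "cropland")
             if d[c] > tol]
    src_tot = -sum(d[c] for c in sources)
    for s in sources:
        for t in sinks:
            flows.append((s, t, (-d[s]) * d[t] / src_tot))
    return [(a, b, h) for a, b, h in flows if h > tol]


@dataclass
class EmissionsReport:
    """Emission deltas in kt CO2e by cell and aggregates.

    Sign convention: avoided deforestation yields a negative delta
    (emission savings).
    """

    by_cell: pd.DataFrame
    by_region: pd.Series
    total_kt: float
    components_kt: dict


def emissions_from_deltas(land_change_table,
                          ef_matrix: EmissionFactorMatrix) -> EmissionsReport:
    """Value a land-change table's net deltas with the factor matrix.

    Deltas are in kha and factors in t CO2e/ha, so products are kt CO2e.
    For counterfactual differencing pass a matrix built with
    ``symmetric=True`` so avoided clearing counts in full.
    """
    t = land_change_table.table
    rows = []
    comp_tot = dict.fromkeys(_COMPONENTS, 0.0)
    for _, r in t.iterrows():
        flows = transitions_from_deltas(
            r["d_forest"], r["d_other_natural"], r["d_pasture"],
            r["d_cropland"])
        kt = 0.0
        for frm, to, ha in flows:
            fac = ef_matrix.table.loc[(r["cell_id"], frm, to)]
            kt += ha * float(fac["total"])
            for c in _COMPONENTS:
                comp_tot[c] += ha * float(fac[c])
        rows.append({"cell_id": r["cell_id"], "region": r["region"],
                     "delta_kt": kt})
    by_cell = pd.DataFrame(rows)
    by_region = by_cell.groupby("region")["delta_kt"].sum()
    return EmissionsReport(by_cell=by_cell, by_region=by_region,
                           total_kt=float(by_cell["delta_kt"].sum()),
                           components_kt=comp_tot)
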
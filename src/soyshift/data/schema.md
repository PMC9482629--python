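# World directory schema

A generated world is a directory of plain-text tables.

## municipalities.csv
| column | meaning |
|---|---|
| muni_id | municipality identifier (M0000, ...) |
| biome | Amazon / Cerrado / Other |
| aez_id | agro-ecological zone (AEZ5, AEZ6, ...) |
| forest_A_ha | forest under definition A (forest only), kha |
| forest_B_ha | forest under definition B (adds natural grassland outside the Amazon), kha; equals forest_A_ha inside the Amazon |
| other_natural_ha | remaining natural cover, kha |
| cropland_ha | total cropland, kha |
| pasture_ha | pasture, kha |
| soy_area_ha | soybean area, kha (<= cropland_ha) |
| soy_production_t | soybean production, t |
| maize2_area_ha | second-harvest maize area, kha (<= soy_area_ha) |
| cattle_heads | cattle headcount |

## trader_exports.csv
| column | meaning |
|---|---|
| muni_id | sourcing municipality |
| company_id | exporter (see company_roster.csv) |
| destination | EU / China / OtherDest |
| volume_t | exported volume, t; per-municipality totals never exceed soy_production_t |

## company_roster.csv
company_id, name, asm_member (moratorium signatory), global_zdc (global
pledge), weight (size), primary_dest, prop_<destination> (destination
propensities, sum to 1).

## land_cells.csv
One row per model land cell: `cell_id` (`BRA:<biome>:<AEZ>` or
`<region>:all`), region, biome, aez_id, and physical areas in kha:
forest_ha (definition A), grassland_ha (definition-B increment),
other_natural_ha, pasture_ha, cropland_ha, crop_<sector>_ha.

## sam.csv
Square balanced social accounting matrix (currency units, benchmark year
2011, all benchmark prices 1). Account labels:
`A|region|sector` activities, `F|lab|region` / `F|cap|region` factors,
`L|cell_id|sector` land by cell and renting sector, `H|region`
households. Row sum equals column sum per account (relative 1e-8).

## config.yaml
The WorldConfig that generated the world (seed included), sufficient to
regenerate it exactly.
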
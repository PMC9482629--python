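# Methods

`soyshift` quantifies how much of the deforestation avoided by
zero-deforestation soy supply-chain policies (ZDSPs) in Brazil is offset
by leakage — displaced forest clearing elsewhere in Brazil and abroad —
using a counterfactual applied general-equilibrium (AGE) analysis run
entirely on a synthetic, seeded mini-world. This note documents the
model, the synthetic data, the numerical choices, and what the passing
checks do and do not establish about real data.

## The counterfactual design

Every scenario is evaluated as the difference between two medium-run
(five-year) simulations from the same 2011-style benchmark:

* **baseline** — the economy responds to exogenous drivers (endowment
  growth, sectoral TFP, biofuel and food/feed demand shifts) with no
  land-use restriction anywhere;
* **counterfactual** — same drivers, but in every covered biome-AEZ cell
  the restricted natural cover is frozen at its benchmark area through
  an endogenous retention subsidy.

Land-change deltas (counterfactual − baseline) are decomposed into
covered cells (gross avoided deforestation), uncovered domestic cells
(domestic leakage) and foreign cells (cross-border leakage, split into a
neighbouring-frontier block and the rest of the world). The leakage
rate is displaced clearing as a percentage of gross avoided
deforestation; global, covered and uncovered deltas satisfy the
accounting identity `global = covered + uncovered` exactly on every
table.

## The equilibrium model

A levels-form multi-region CGE, calibrated to a balanced social
accounting matrix (SAM) with all benchmark prices normalised to 1:

* **Production**: Leontief intermediates over two-level Armington
  composites (domestic vs imports, elasticity σ_D per commodity;
  across import sources, σ_M = 2 σ_D), Cobb-Douglas value added over
  labour, capital and — for crops, grazing livestock and forestry — a
  CES land composite across the cells of the region (σ_land-mobility,
  default 5).
* **Land supply**: each cell's fixed area moves along a nested CET:
  natural cover vs agricultural land (σ_nat, region-specific, default
  0.25–0.4), forest vs other natural within natural (σ_natsplit, 0.05 —
  the forest/grassland mix is not a strongly market-driven margin),
  pasture vs cropland within agriculture (σ_agpast, 0.5), and crops
  within cropland (σ_crop, 1.0). The nesting separates the decision to
  convert forest to agriculture from the decision to move pasture into
  cropland.
* **Hectare accounting**: the allocation at each nest is the
  revenue-maximising CET allocation renormalised so that child areas
  sum *exactly* to the parent area (the relative allocation is
  unchanged; see `soyshift.nests.cet_allocate(preserve_total=True)`).
  A pure CET cannot conserve physical hectares off-benchmark; physical
  conservation is the binding requirement for land accounting, so it
  wins. Land adding-up holds to 1e-6 at every nest on every run.
* **Unmanaged land**: other natural cover earns a reservation rent (a
  shadow price, no value flow) set at 30% of the cell's forest rent per
  hectare at benchmark and indexed to the regional consumer price index
  thereafter, i.e. constant in real terms. Without the indexation,
  economy-wide TFP growth deflates goods prices against a nominal
  constant and land drifts into natural cover for purely monetary
  reasons; indexation also preserves homogeneity degree zero.
* **Intensification**: crop yields respond to the real (CPI-deflated)
  own price with elasticity 0.25, a land-augmenting margin that damps
  area responses.
* **Demand**: a linear expenditure system calibrated to per-commodity
  income elasticities (crops 0.4, livestock 0.7, processed food 0.6,
  forestry 0.5, services 1.15) with a 50% supernumerary budget share.
* **Policy instrument**: a constraint swap — covered-cell restricted
  area exogenous, retention subsidy endogenous (a multiplicative wedge
  on the forest rent entering the allocation, financed lump-sum from
  the regional household so income effects net out). Mathematically
  equivalent to iterating on a subsidy, numerically cleaner.
* **Closure**: fixed regional labour and capital endowments (mobile
  across sectors, immobile across regions — a deliberate medium-run
  choice), endogenous trade balances, numeraire = primary-factor price
  index of the first region. One labour-market equation is dropped by
  Walras' law and its residual reported as a diagnostic (< 1e-8 at
  every solution).

The system (~100–150 unknowns in logs at the default aggregation) is
solved by damped Newton with a forward-difference Jacobian and
backtracking line search, to residual 1e-10; failures raise with the
residual trace rather than returning a bad state. Benchmark
replication (zero shocks reproduce the SAM exactly) holds to ~1e-12 and
is checked by `replication_check`.

Forest definition B (forest plus natural grassland outside the Amazon)
is folded into the model's "forest" account when footprint cells are
built: `forest` always means the scenario's *restricted* cover, and
`other_natural` the remaining natural cover. This keeps the freeze a
single-account constraint.

## The synthetic world

The generator emulates the structure of the real data layer, not its
values: a municipality table (biome, AEZ, land covers under two forest
definitions, soy area/production, second-harvest maize, cattle), a
trader-level export table with destination markets (committed majors
carrying the real moratorium/global-pledge roster names, shipped as
editable YAML; synthetic independents), and a SAM whose land rents are
imputed proportional to cell area times a biome productivity factor and
then RAS-balanced to micro-consistency (per-account relative residual
1e-12).

Key structural knobs and defaults, chosen once as study conditions:

* 5 regions (BRA, BAP, USCAN, EU, CHN+ROW) × 6 sectors; the 11-region ×
  18-sector aggregation of the full-scale analysis is available as the
  `paper_aggregation()` preset. The 5×6 default solves in well under a
  second, which is what makes the 30-run grid and 50-draw sweep
  desk-scale.
* 40 municipalities, 12 companies (6 committed), 2 AEZs,
  `destination_segmentation` 0.85, 35% of soy consumed domestically.
* Drivers for 2011→2016: endowment growth 3–18% by region (China
  highest), TFP +2% agriculture, +8% forestry (plantation
  intensification — this is what pushes the forest-conversion margin
  toward clearing, as observed in the study window), +5% elsewhere,
  biofuel feedstock demand +25%/+15% in North America/EU, food and feed
  demand +5% generally and +30% in China. These are synthetic
  stand-ins for the macro/productivity/biofuel driver tables of the
  real study; they are chosen to reproduce the *direction and rough
  relative pattern* of observed land-use change (baseline deforestation
  in all Brazilian biomes and the frontier neighbours, crop expansion
  on existing farmland in North America), not its levels.

What the synthetic world does **not** emulate: real municipal
geography (AEZ/biome assignment is generated, not overlaid), actual
trader market shares, GTAP value flows, or observed deforestation
totals. Consequently all simulation-based checks are property checks
(signs, orderings, invariants, mechanism demonstrations); the published
headline magnitudes enter only through exact arithmetic on the bundled
fixture of printed numbers, which the leakage module recomputes.

## Scenarios and footprints

Five scenarios (moratorium-only; plus global voluntary pledges; and
import-regulation scenarios for the EU, China, and both — the
destination rules commit a company's *entire* supply chain on any
export to the named market), three market-share thresholds (>0%, ≥50%,
≥75%, inclusive at 50/75 and strict at 0), and two forest definitions:
a 30-database grid. Municipalities with zero exports are non-compliant
under every threshold (no buyer leverage) and counted in the log.
Account splitting into biome × AEZ × compliance cells conserves every
national total to 1e-10.

## Emissions

Land-cover transition factors (t CO2e/ha) are assembled per cell from
synthetic biome-typical carbon stocks (biomass, dead organic matter,
soil; stocks are inputs, drawn around configurable means) plus foregone
forest sequestration over a 30-year horizon, a wood-product storage
credit and a fire non-CO2 term. Net cover deltas from the
comparative-static model are attributed to transitions along the land
nest (mixed signs within natural or within agriculture become internal
transfers first; the remaining natural-vs-agricultural gap is split
proportionally). Counterfactual differencing uses the symmetric factor
configuration so avoided clearing counts the full avoided emission; the
default asymmetric (regrowth-discounted) matrix is for within-run
transition accounting.

## The segmentation experiment

The destination-market-segmentation mechanism — displaced Brazilian
production absorbed by existing North American farmland because both
compete in the Chinese market, while the frontier neighbours mostly
serve the EU — is demonstrated in a controlled stylized world rather
than the default generated one. In the full mini-world the channel is
real but masked by parallel general-equilibrium channels (a common
world-price effect on all land rents and second-order re-sourcing in
the EU market) and by the RAS adjustment of benchmark shares.
`segmentation_experiment` therefore builds twin benchmarks *exactly*
from prescribed sourcing shares (`build_sam_from_shares`, a
Perron-vector construction that needs no balancing), identical in
everything except the crop-trade pattern, with the policy country's
frontier cell fully covered and a spare-land absorber that has almost
no forest to convert. Cross-border leakage in the segmented world is
then unambiguously below the unsegmented twin (≈0.7% vs ≈1.1% of gross
avoided deforestation at the default drivers).

## Sensitivity sweep

A Monte-Carlo sweep (default 50 seeded draws, uniform ±50% multipliers
on σ_nat, σ_agpast, σ_crop, σ_land-mobility, the Armington elasticities
and the yield elasticity) replaces the Gaussian-quadrature systematic
sensitivity analysis common in this model family: simpler, and exactly
reproducible from a seed. Reported per draw: leakage rates and net
global avoided deforestation; summarised by mean, 5–95% interval and
the sign-stability share.

## Numerical choices and degenerate inputs

* Solver tolerance 1e-10 (relative, log-space residuals); invariant
  tests at 1e-6 unless the quantity is exact by construction.
* Zero-benchmark activities, factors, or land slots are masked out of
  the unknown vector (their price indices pinned at 1), keeping the
  Jacobian regular for degenerate toys such as the two-region exchange
  economy.
* Thin destination links (propensity < 0.04) are dropped from trader
  portfolios — real export rosters are sparse, and without sparsity a
  destination rule trivially covers every company.
* The published "<2 kha" spillover is stored as 2 with an upper-bound
  flag; the printed "238 kha ≈ 23% of 847" inconsistency is stored with
  an ambiguous flag and excluded from checks.
* Annualisation uses the 5-year 2011→2016 window (409/5 = 81.8 ≈ 82
  kha/yr matches the published annual figure; a 6-year divisor does
  not).

## Known limitations

* The calibrated elasticities of the original model family are not
  public at desk scale; defaults here are documented placeholders and
  every simulation conclusion is therefore a property of the stated
  configuration, guarded by the sensitivity sweep.
* Leakage rates in the demo world (~5–15% domestic) are smaller than
  the published ~50% because the synthetic world's uncovered frontier
  is less exposed than Brazil's; the rates' arithmetic, signs and
  orderings — not their levels — are the tested claims.
* One global numeraire, no capital mobility across regions, no
  recursive multi-year dynamics, no GEMPACK-style percent-change mode.
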
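"""Configuration objects shared across the pipeline.

The defaults here define the demo "mini-world": a 5-region x 6-sector
aggregation of the world soy economy that solves in well under a second,
with Brazil's land market subdivided into biome x agro-ecological-zone
cells. The full 11-region x 18-sector aggregation used in the source
study of record is available as a preset (``paper_aggregation``).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

# Canonical mini-world region codes. BRA must come first (policy country).
DEFAULT_REGIONS = ["BRA", "BAP", "USCAN", "EU", "CHNROW"]

# 11-region aggregation preset (policy country first).
PAPER_REGIONS = [
    "BRA", "BOL", "ARG", "PRY", "RLA", "USCAN",
    "EU28", "CHN", "MYIDN", "SSA", "ROW",
]

DEFAULT_SECTORS = [
    "oilseeds", "coarse_grains", "grazing_livestock",
    "forestry", "processed_food", "mfg_services",
]

PAPER_SECTORS = [
    "paddy_rice", "wheat", "coarse_grains", "oilseeds", "raw_sugar",
    "grazing_livestock", "nongrazing_livestock", "forestry",
    "extractive", "processed_livestock", "vegetable_oils",
    "processed_rice", "processed_sugar", "other_processed_food",
    "chemicals", "manufactures", "services", "other_crops",
]

BIOMES = ["Amazon", "Cerrado", "Other"]
DESTINATIONS = ["EU", "China", "OtherDest"]


@dataclass
class Elasticities:
    """Behavioural parameters of the equilibrium model.

    All transformation/substitution elasticities are non-negative.
    Values are documented placeholders in the range used by nested
    land-supply CGE models; the sensitivity sweep varies them.
    """

    # land-supply transformation (CET) elasticities, by region code;
    # missing regions fall back to "default"
    sigma_nat: dict = field(default_factory=lambda: {
        "default": 0.25, "BRA": 0.30, "BAP": 0.40, "USCAN": 0.05,
        "EU": 0.05, "CHNROW": 0.10,
    })
    sigma_agpast: float = 0.5     # pasture vs cropland
    sigma_crop: float = 1.0       # across crops within cropland
    sigma_natsplit: float = 0.05  # forest vs other natural (near-fixed mix)
    sigma_landmob: float = 5.0    # land mobility across cells within a sector
    # Armington elasticities by sector; missing -> "default"
    armington_dom: dict = field(default_factory=lambda: {
        "default": 2.0, "oilseeds": 4.0, "coarse_grains": 4.0,
    })
    armington_src_scale: float = 2.0   # sigma across sources = scale * sigma_dom
    # income elasticities of final demand by sector
    income: dict = field(default_factory=lambda: {
        "default": 1.0, "oilseeds": 0.4, "coarse_grains": 0.4,
        "grazing_livestock": 0.7, "forestry": 0.5,
        "processed_food": 0.6, "mfg_services": 1.15,
    })
    yield_elast: float = 0.25          # land-augmenting yield response to own price
    supernumerary_share: float = 0.5   # LES discretionary-income share at benchmark
    reservation_rent_othernat: float = 1.0  # exogenous rent index of unmanaged cover

    def get_sigma_nat(self, region: str) -> float:
        return self.sigma_nat.get(region, self.sigma_nat["default"])

    def get_armington(self, sector: str) -> float:
        return self.armington_dom.get(sector, self.armington_dom["default"])

    def get_income(self, sector: str) -> float:
        return self.income.get(sector, self.income["default"])


@dataclass
class WorldConfig:
    """Parameters of the synthetic mini-world generator."""

    regions: list = field(default_factory=lambda: list(DEFAULT_REGIONS))
    sectors: list = field(default_factory=lambda: list(DEFAULT_SECTORS))
    n_municipalities: int = 40
    n_companies: int = 12
    n_committed: int = 6          # companies carrying zero-deforestation pledges
    n_aez: int = 2
    random_seed: int = 0
    # how strongly BRA/USCAN exports concentrate on China and BAP on the EU
    destination_segmentation: float = 0.85
    # soy consumed domestically (excluded from the Trase-style export table)
    domestic_use_fraction: float = 0.35
    destinations: list = field(default_factory=lambda: list(DESTINATIONS))
    # biome mix of municipalities (Amazon, Cerrado, Other); None = default
    biome_probabilities: list | None = None
    elasticities: Elasticities = field(default_factory=Elasticities)
    # sector roles (which sectors rent which land cover)
    crop_sectors: list = field(default_factory=lambda: ["oilseeds", "coarse_grains"])
    pasture_sector: str = "grazing_livestock"
    forest_sector: str = "forestry"

    def __post_init__(self):
        if len(self.regions) < 2 or len(self.sectors) < 2:
            raise ValueError("need at least 2 regions and 2 sectors")
        if self.n_municipalities < 2 or self.n_companies < 2:
            raise ValueError("need at least 2 municipalities and 2 companies")
        if not 0.0 <= self.destination_segmentation <= 1.0:
            raise ValueError("destination_segmentation must be in [0, 1]")
        if not 0.0 <= self.domestic_use_fraction < 1.0:
            raise ValueError("domestic_use_fraction must be in [0, 1)")
        if self.n_aez < 1:
            raise ValueError("n_aez must be >= 1")
        if self.biome_probabilities is not None:
            p = self.biome_probabilities
            if len(p) != 3 or min(p) < 0 or abs(sum(p) - 1.0) > 1e-9:
                raise ValueError("biome_probabilities must be 3 "
                                 "non-negative values summing to 1")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_sectors(self) -> int:
        return len(self.sectors)

    @property
    def land_sectors(self) -> list:
        return list(self.crop_sectors) + [self.pasture_sector, self.forest_sector]

    @property
    def aez_ids(self) -> list:
        return [f"AEZ{i + 5}" for i in range(self.n_aez)]

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "WorldConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        el = d.pop("elasticities", None)
        cfg = cls(**d)
        if el is not None:
            cfg.elasticities = Elasticities(**el)
        return cfg


def paper_aggregation(**overrides) -> WorldConfig:
    """The 11-region x 18-sector aggregation as a preset configuration."""
    kwargs = dict(
        regions=list(PAPER_REGIONS),
        sectors=list(PAPER_SECTORS),
        crop_sectors=["paddy_rice", "wheat", "coarse_grains", "oilseeds",
                      "raw_sugar", "other_crops"],
        pasture_sector="grazing_livestock",
        forest_sector="forestry",
        n_municipalities=60,
    )
    kwargs.update(overrides)
    return WorldConfig(**kwargs)


@dataclass
class Drivers:
    """Exogenous 2011->2016 medium-run drivers (proportional changes).

    The five-year horizon matches the study window; each indicator is
    understood as a 3-year-centred average change (2010-12 to 2015-17).
    """

    # labour/capital endowment growth per region (income & population growth)
    endowment_growth: dict = field(default_factory=lambda: {
        "default": 0.08, "BRA": 0.08, "BAP": 0.10, "USCAN": 0.06,
        "EU": 0.03, "CHNROW": 0.18,
    })
    # Hicks-neutral TFP growth: agriculture, forestry, and the rest.
    # Forestry productivity outpaces crops (plantation intensification),
    # which depresses natural-forest rents at the conversion margin.
    tfp_growth_ag: float = 0.02
    tfp_growth_forestry: float = 0.08
    tfp_growth_nonag: float = 0.05
    # biofuel demand wedge: proportional bump to benchmark oilseed final
    # demand, per region (oilseed-processing feedstock demand shift)
    biofuel_demand: dict = field(default_factory=lambda: {
        "USCAN": 0.25, "EU": 0.15,
    })
    # food/feed demand shift: dietary upgrading and feed demand growth,
    # as a proportional bump to benchmark final demand for crops,
    # livestock and processed food (the Chinese protein-demand boom of
    # the study window dominates)
    food_demand: dict = field(default_factory=lambda: {
        "default": 0.05, "CHNROW": 0.30,
    })
    horizon_years: int = 5

    def get_food_demand(self, region: str) -> float:
        return self.food_demand.get(region,
                                    self.food_demand.get("default", 0.0))

    def get_growth(self, region: str) -> float:
        return self.endowment_growth.get(
            region, self.endowment_growth.get("default", 0.0))

    @classmethod
    def zero(cls) -> "Drivers":
        return cls(endowment_growth={"default": 0.0}, tfp_growth_ag=0.0,
                   tfp_growth_forestry=0.0, tfp_growth_nonag=0.0,
                   biofuel_demand={}, food_demand={})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Drivers":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))
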
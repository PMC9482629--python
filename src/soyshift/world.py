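"""Synthetic mini-world generator.

Produces a micro-consistent stand-in for the data layer of the real
analysis — a municipality table (land covers, soy production), a
trader-level export table with destination markets, a balanced social
accounting matrix (SAM) with land rents disaggregated by biome-AEZ cell,
and a land-cell table — all from a seeded :class:`~soyshift.config.WorldConfig`,
with no downloads. Everything downstream (footprints, calibration,
counterfactuals) runs off these tables.

The generator is deterministic under a fixed seed and exposes the
structural knobs the analysis depends on, most importantly
``destination_segmentation``: how strongly Brazilian and North American
soy exports concentrate on the Chinese market while the Bolivia/
Argentina/Paraguay (BAP) block serves the EU.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import BIOMES, WorldConfig

__all__ = [
    "SocialAccountingMatrix", "World", "balance_matrix", "balance_sam",
    "generate_municipalities", "default_company_roster",
    "generate_trader_exports", "generate_land_cells", "generate_sam",
    "build_sam_from_shares", "generate_world", "write_world", "read_world",
]

# ---------------------------------------------------------------------------
# biproportional (RAS) balancing
# ---------------------------------------------------------------------------


def balance_matrix(raw, row_targets, col_targets, tol=1e-10, max_iter=2000):
    """Biproportional (RAS) fit of a non-negative matrix to given margins.

    Zeros are preserved exactly. Raises if the zero pattern makes a
    target infeasible (a zero row/column with a positive target) or if
    the iteration does not converge.
    """
    m = np.array(raw, dtype=float)
    u = np.asarray(row_targets, dtype=float)
    v = np.asarray(col_targets, dtype=float)
    if np.any(m < 0):
        raise ValueError("matrix must be non-negative")
    if not np.isclose(u.sum(), v.sum(), rtol=1e-9):
        raise ValueError("row and column targets must share a grand total")
    for i, (rs, t) in enumerate(zip(m.sum(axis=1), u)):
        if rs == 0 and t > 0:
            raise ValueError(f"infeasible zero pattern: row {i} is all zero "
                             f"but has positive target")
    for j, (cs, t) in enumerate(zip(m.sum(axis=0), v)):
        if cs == 0 and t > 0:
            raise ValueError(f"infeasible zero pattern: column {j} is all "
                             f"zero but has positive target")
    scale = max(u.sum(), 1.0)
    for _ in range(max_iter):
        rs = m.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(rs > 0, u / rs, 1.0)
        m *= r[:, None]
        cs = m.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(cs > 0, v / cs, 1.0)
        m *= c[None, :]
        res = max(np.abs(m.sum(axis=1) - u).max(),
                  np.abs(m.sum(axis=0) - v).max()) / scale
        if res < tol:
            return m
    raise RuntimeError(f"RAS did not converge: residual {res:.3e} after "
                       f"{max_iter} iterations")


def balance_sam(raw, tol=1e-12, max_iter=20000):
    """Balance a square value matrix so each row sum equals its column sum.

    The margin itself is unknown, so alternate RAS-style row/column
    scaling toward the running average margin. Linear in the input
    (doubling the raw matrix doubles the result) and a no-op on an
    already balanced matrix.
    """
    m = np.array(raw, dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError("SAM must be square")
    total = m.sum()
    if total <= 0:
        raise ValueError("SAM must have positive total")
    for _ in range(max_iter):
        rs, cs = m.sum(axis=1), m.sum(axis=0)
        # per-account relative residual, so small accounts are tight too
        denom = np.maximum(0.5 * (rs + cs), total * 1e-9)
        res = (np.abs(rs - cs) / denom).max()
        if res < tol:
            return m
        t = 0.5 * (rs + cs)
        with np.errstate(invalid="ignore", divide="ignore"):
            m *= np.where(rs > 0, t / rs, 1.0)[:, None]
        cs = m.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            m *= np.where(cs > 0, t / cs, 1.0)[None, :]
    raise RuntimeError(f"SAM balancing did not converge: residual {res:.3e}")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


class SocialAccountingMatrix:
    """Square matrix of benchmark value flows between labelled accounts.

    Labels: ``A|region|sector`` activities, ``F|lab/cap|region`` factors,
    ``L|cell_id|use`` land by biome-AEZ cell and renting sector,
    ``H|region`` households.
    """

    def __init__(self, df: pd.DataFrame):
        if list(df.index) != list(df.columns):
            raise ValueError("SAM rows and columns must carry the same labels")
        self.df = df

    @property
    def accounts(self):
        return list(self.df.index)

    def value(self, row, col):
        return float(self.df.loc[row, col])

    def balance_residual(self) -> float:
        rs = self.df.sum(axis=1).to_numpy()
        cs = self.df.sum(axis=0).to_numpy()
        return float(np.abs(rs - cs).max() / self.df.to_numpy().sum())

    def check_balanced(self, tol=1e-8):
        res = self.balance_residual()
        if res > tol:
            raise ValueError(f"SAM out of balance: residual {res:.3e}")

    def land_accounts(self):
        return [a for a in self.accounts if a.startswith("L|")]

    def to_csv(self, path):
        self.df.to_csv(path)

    @classmethod
    def from_csv(cls, path):
        return cls(pd.read_csv(path, index_col=0))


@dataclass
class World:
    config: WorldConfig
    municipalities: pd.DataFrame
    roster: pd.DataFrame
    trader_exports: pd.DataFrame
    land_cells: pd.DataFrame
    sam: SocialAccountingMatrix


# ---------------------------------------------------------------------------
# municipality layer
# ---------------------------------------------------------------------------

# Dirichlet mean cover shares by biome:
# (forest, grassland, other_natural, cropland, pasture)
_BIOME_COVER = {
    "Amazon":  np.array([0.55, 0.00, 0.10, 0.12, 0.23]),
    "Cerrado": np.array([0.18, 0.17, 0.05, 0.32, 0.28]),
    "Other":   np.array([0.22, 0.08, 0.08, 0.30, 0.32]),
}
_BIOME_PROB = np.array([0.35, 0.40, 0.25])
# biome-level cropland rent productivity factors used to impute land rents
_BIOME_PRODUCTIVITY = {"Amazon": 0.7, "Cerrado": 1.0, "Other": 0.9}


def generate_municipalities(config: WorldConfig) -> pd.DataFrame:
    """Seeded municipality table with biome, AEZ, land covers and soy."""
    rng = np.random.default_rng(config.random_seed)
    n = config.n_municipalities
    probs = np.asarray(config.biome_probabilities
                       if config.biome_probabilities is not None
                       else _BIOME_PROB, dtype=float)
    biomes = rng.choice(BIOMES, size=n, p=probs)
    # guarantee every biome with positive probability occurs
    for i, b in enumerate(BIOMES):
        if probs[i] > 0 and b not in biomes:
            biomes[i % n] = b
    aezs = rng.choice(config.aez_ids, size=n)
    rows = []
    for i in range(n):
        biome = str(biomes[i])
        total = float(rng.lognormal(np.log(200.0), 0.5))  # kha
        mean = _BIOME_COVER[biome]
        conc = np.where(mean > 0, mean * 40.0, 0.0)
        pos = conc > 0
        shares = np.zeros(5)
        shares[pos] = rng.dirichlet(conc[pos])
        forest, grass, other_nat, cropland, pasture = shares * total
        if biome == "Amazon":
            grass = 0.0  # definition B adds nothing inside the Amazon
        soy_frac = rng.beta(5, 3) if biome == "Cerrado" else rng.beta(3, 4)
        soy_area = soy_frac * cropland
        soy_yield = float(np.clip(rng.normal(3.0, 0.3), 2.0, 4.0))  # t/ha
        maize2 = soy_area * rng.uniform(0.2, 0.6)
        rows.append({
            "muni_id": f"M{i:04d}",
            "biome": biome,
            "aez_id": str(aezs[i]),
            "forest_A_ha": forest,
            "forest_B_ha": forest + grass,
            "other_natural_ha": other_nat,
            "cropland_ha": cropland,
            "pasture_ha": pasture,
            "soy_area_ha": soy_area,
            "soy_production_t": soy_area * soy_yield * 1e3,  # kha * t/ha * 1e3
            "maize2_area_ha": maize2,
            "cattle_heads": pasture * rng.uniform(0.5, 1.5) * 1e3,
        })
    df = pd.DataFrame(rows)
    _validate_municipalities(df)
    return df


def _validate_municipalities(df: pd.DataFrame):
    area_cols = ["forest_A_ha", "forest_B_ha", "other_natural_ha",
                 "cropland_ha", "pasture_ha", "soy_area_ha",
                 "maize2_area_ha"]
    if (df[area_cols] < 0).any().any():
        raise ValueError("negative area in municipality table")
    if (df["soy_area_ha"] > df["cropland_ha"] * (1 + 1e-12)).any():
        raise ValueError("soy area exceeds cropland")
    if (df["maize2_area_ha"] > df["soy_area_ha"] * (1 + 1e-12)).any():
        raise ValueError("second-harvest maize exceeds soy area")
    if (df["forest_B_ha"] < df["forest_A_ha"] - 1e-12).any():
        raise ValueError("forest definition B must include definition A")


# ---------------------------------------------------------------------------
# trader layer
# ---------------------------------------------------------------------------

def _load_roster_yaml(name):
    import yaml
    path = Path(__file__).parent / "data" / name
    with open(path) as fh:
        return yaml.safe_load(fh)["companies"]


def asm_companies():
    """Roster of the Amazon Soy Moratorium signatories (configuration data)."""
    return _load_roster_yaml("asm_companies.yaml")


def global_zdc_companies():
    """Traders with global voluntary zero-deforestation pledges."""
    return _load_roster_yaml("global_zdc_companies.yaml")


def default_company_roster(config: WorldConfig) -> pd.DataFrame:
    """Company roster: pledge flags, size weights, destination propensities.

    Committed names are drawn from the shipped moratorium / global-pledge
    rosters; the remainder are synthetic independent traders. Destination
    propensities interpolate between a common base mix and a one-hot
    primary destination as ``destination_segmentation`` goes to 1.
    """
    rng = np.random.default_rng(config.random_seed + 1)
    asm = asm_companies()
    gzdc = set(global_zdc_companies())
    n_committed = min(config.n_committed, config.n_companies - 1, len(asm))
    # put globally pledged majors first so small rosters stay interesting
    ordered = [c for c in asm if c in gzdc] + [c for c in asm if c not in gzdc]
    names = ordered[:n_committed]
    names += [f"Independent Trader {k + 1}"
              for k in range(config.n_companies - n_committed)]
    dests = list(config.destinations)
    # committed majors serve the big import markets (China-leaning, the
    # policy country's concentration pattern); independents are mostly
    # regional traders serving residual markets
    base_major = np.array([{"EU": 0.30, "China": 0.55}.get(d, 0.15)
                           for d in dests])
    base_major /= base_major.sum()
    base_indep = np.array([{"EU": 0.15, "China": 0.15}.get(d, 0.70)
                           for d in dests])
    base_indep /= base_indep.sum()
    seg = config.destination_segmentation
    min_share = 0.04  # destination links thinner than this do not exist
    rows = []
    for j, name in enumerate(names):
        committed = j < n_committed
        weight = float(rng.lognormal(0.0, 0.4)) * (2.0 if committed else 1.0)
        if committed:
            # mostly China-primary, a minority EU-primary
            primary = "EU" if ("EU" in dests and j % 3 == 0) else (
                "China" if "China" in dests else dests[j % len(dests)])
        else:
            pw = np.array([{"EU": 0.2, "China": 0.2}.get(d, 0.6)
                           for d in dests])
            primary = dests[rng.choice(len(dests), p=pw / pw.sum())]
        base = base_major if committed else base_indep
        onehot = np.array([1.0 if d == primary else 0.0 for d in dests])
        prop = (1.0 - seg) * base + seg * onehot
        prop = np.where(prop >= min_share, prop, 0.0)
        prop /= prop.sum()
        rows.append({
            "company_id": f"C{j:03d}",
            "name": name,
            "asm_member": name in asm,
            "global_zdc": name in gzdc,
            "weight": weight,
            "primary_dest": primary,
            **{f"prop_{d}": p for d, p in zip(dests, prop)},
        })
    return pd.DataFrame(rows)


def generate_trader_exports(munis: pd.DataFrame, config: WorldConfig,
                            roster: pd.DataFrame | None = None) -> pd.DataFrame:
    """Trase-style table: per-municipality trader export volumes by destination.

    Volumes per municipality never exceed its soy production (a
    ``domestic_use_fraction`` stays off the export market). Moratorium
    members are over-represented in Amazon municipalities.
    """
    if roster is None:
        roster = default_company_roster(config)
    if len(roster) == 0:
        raise ValueError("empty company roster")
    rng = np.random.default_rng(config.random_seed + 2)
    dests = list(config.destinations)
    prop = roster[[f"prop_{d}" for d in dests]].to_numpy()
    weights = roster["weight"].to_numpy()
    asm_flag = roster["asm_member"].to_numpy()
    rows = []
    for _, muni in munis.iterrows():
        exported = muni["soy_production_t"] * (1 - config.domestic_use_fraction)
        exported *= rng.uniform(0.9, 1.0)
        if exported <= 0:
            continue
        w = weights.copy()
        if muni["biome"] == "Amazon":
            w = w * np.where(asm_flag, 2.5, 1.0)
        else:
            w = w * np.where(asm_flag, 1.0, 2.5)
        k = int(rng.integers(1, min(4, len(roster)) + 1))
        active = rng.choice(len(roster), size=k, replace=False,
                            p=w / w.sum())
        shares = rng.dirichlet(np.ones(k) * 1.2)
        for idx, s in zip(active, shares):
            vol = exported * s
            for d, frac in zip(dests, prop[idx]):
                if vol * frac > 0:
                    rows.append({
                        "muni_id": muni["muni_id"],
                        "company_id": roster["company_id"].iloc[idx],
                        "destination": d,
                        "volume_t": vol * frac,
                    })
    df = pd.DataFrame(rows)
    cap = munis.set_index("muni_id")["soy_production_t"]
    per_muni = df.groupby("muni_id")["volume_t"].sum()
    if (per_muni > cap.loc[per_muni.index] * (1 + 1e-9)).any():
        raise AssertionError("per-municipality export volume exceeds production")
    return df


# ---------------------------------------------------------------------------
# land cells
# ---------------------------------------------------------------------------

# foreign single-cell cover profile per unit of region size:
# (forest, other_natural, pasture, cropland, oilseed share of cropland)
_FOREIGN_PROFILES = {
    "BAP":    (900.0, 200.0, 500.0, 400.0, 0.45),
    "USCAN":  (60.0, 700.0, 300.0, 800.0, 0.35),
    "EU":     (150.0, 100.0, 150.0, 450.0, 0.10),
    "CHNROW": (250.0, 400.0, 450.0, 900.0, 0.15),
}
_FOREIGN_FALLBACK = (200.0, 300.0, 300.0, 500.0, 0.2)


def _match_profile(region: str):
    for key, prof in _FOREIGN_PROFILES.items():
        if key in region or region in key:
            return prof
    if any(t in region for t in ("BOL", "ARG", "PRY")):
        return _FOREIGN_PROFILES["BAP"]
    if "CHN" in region or "ROW" in region:
        return _FOREIGN_PROFILES["CHNROW"]
    if "EU" in region:
        return _FOREIGN_PROFILES["EU"]
    return _FOREIGN_FALLBACK


def _crop_areas(cropland, soy_area, config: WorldConfig):
    """Split cropland area across crop sectors; oilseeds carry the soy area."""
    crops = config.crop_sectors
    out = {}
    others = [c for c in crops if c != "oilseeds"]
    if "oilseeds" in crops:
        out["oilseeds"] = soy_area
        rest = max(cropland - soy_area, 0.0)
    else:
        rest = cropland
    for c in others:
        out[c] = rest / len(others) if others else 0.0
    return out


def generate_land_cells(config: WorldConfig,
                        munis: pd.DataFrame) -> pd.DataFrame:
    """Physical land areas per model cell (kha).

    Brazil gets one cell per (biome, AEZ) present in the municipality
    table; every other region one aggregate cell. ``forest_ha`` is
    definition-A forest; ``grassland_ha`` is the extra cover that
    definition B restricts outside the Amazon.
    """
    rows = []
    bra = config.regions[0]
    grouped = munis.assign(grass=munis["forest_B_ha"] - munis["forest_A_ha"])
    for (biome, aez), g in grouped.groupby(["biome", "aez_id"], sort=True):
        crop = _crop_areas(g["cropland_ha"].sum(), g["soy_area_ha"].sum(),
                           config)
        rows.append({
            "cell_id": f"{bra}:{biome}:{aez}",
            "region": bra, "biome": biome, "aez_id": aez,
            "forest_ha": g["forest_A_ha"].sum(),
            "grassland_ha": g["grass"].sum(),
            "other_natural_ha": g["other_natural_ha"].sum(),
            "pasture_ha": g["pasture_ha"].sum(),
            "cropland_ha": g["cropland_ha"].sum(),
            **{f"crop_{c}_ha": a for c, a in crop.items()},
        })
    for region in config.regions[1:]:
        f, on, pa, cl, osd_share = _match_profile(region)
        scale = _region_size(region) / 1000.0
        cl_s, soy = cl * scale, cl * scale * osd_share
        crop = _crop_areas(cl_s, soy, config)
        rows.append({
            "cell_id": f"{region}:all",
            "region": region, "biome": region, "aez_id": "all",
            "forest_ha": f * scale, "grassland_ha": 0.0,
            "other_natural_ha": on * scale, "pasture_ha": pa * scale,
            "cropland_ha": cl_s,
            **{f"crop_{c}_ha": a for c, a in crop.items()},
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# social accounting matrix
# ---------------------------------------------------------------------------

_REGION_SIZES = {"BRA": 1000.0, "BAP": 300.0, "USCAN": 2000.0, "EU": 2200.0,
                 "CHNROW": 2600.0, "BOL": 60.0, "ARG": 180.0, "PRY": 60.0,
                 "RLA": 400.0, "EU28": 2200.0, "CHN": 2000.0, "MYIDN": 300.0,
                 "SSA": 350.0, "ROW": 1500.0}


def _region_size(region):
    return _REGION_SIZES.get(region, 800.0)


def _is_food(sector):
    return "processed" in sector or "vegetable" in sector


def _output_weights(config, rng):
    """Benchmark output value shares per (region, sector)."""
    w = {}
    for r in config.regions:
        ag_boost = 1.8 if r in (config.regions[0], "BAP", "BOL", "ARG",
                                "PRY") else 1.0
        row = {}
        for s in config.sectors:
            if s in config.crop_sectors:
                base = 0.07 * ag_boost * (1.6 if s == "oilseeds" else 1.0)
            elif s == config.pasture_sector:
                base = 0.06 * ag_boost
            elif s == config.forest_sector:
                base = 0.03
            elif _is_food(s):
                base = 0.15
            else:
                base = 0.55
            row[s] = base * float(np.exp(rng.normal(0.0, 0.08)))
        tot = sum(row.values())
        w[r] = {s: v / tot for s, v in row.items()}
    return w


def _trade_shares(config, sector, dst):
    """Import sourcing shares for ``sector`` bought in ``dst`` (sums to 1
    over sources != dst).

    For the land-based tradables (crops and grazing livestock) the
    sourcing pattern is shaped by ``destination_segmentation``: the
    policy country and the North American exporter concentrate on the
    Chinese market while the BAP block concentrates on the EU, partly
    disconnecting BAP producers from the market where displaced supply
    is re-sourced.
    """
    sources = [r for r in config.regions if r != dst]
    base = np.array([_region_size(r) for r in sources])
    ag_tradable = sector in config.crop_sectors or \
        sector == config.pasture_sector
    if ag_tradable:
        exp_w = {"BRA": 4.0, "BAP": 12.0, "USCAN": 2.0, "BOL": 8.0,
                 "ARG": 10.0, "PRY": 8.0}
        base = base * np.array([exp_w.get(r, 0.3) for r in sources])
        seg = config.destination_segmentation
        if "CHN" in dst or dst == "ROW":
            target = np.array([{"BRA": 0.55, "USCAN": 0.43}.get(r, 0.0)
                               for r in sources])
        elif "EU" in dst:
            target = np.array(
                [0.85 if r in ("BAP", "BOL", "ARG", "PRY") else
                 {"BRA": 0.08, "USCAN": 0.05}.get(r, 0.0) for r in sources])
        else:
            target = None
        base = base / base.sum()
        if target is not None and target.sum() > 0:
            target = target + 0.01  # keep all links open
            base = (1 - seg) * base + seg * target / target.sum()
    shares = base / base.sum()
    return dict(zip(sources, shares))


_SOY_EXPORTERS = ("BRA", "BAP", "USCAN", "BOL", "ARG", "PRY")


def _domestic_share(config, sector, region=None):
    if sector in config.crop_sectors:
        # world crop trade concentrates in a few importing markets; the
        # exporting regions consume their own crop almost exclusively
        if region is not None:
            if any(t in region for t in _SOY_EXPORTERS):
                return 0.93
            if "CHN" in region or "ROW" in region:
                return 0.35
            if "EU" in region:
                return 0.45
        return 0.60
    if sector == config.forest_sector:
        return 0.85
    if _is_food(sector):
        return 0.80
    if sector == config.pasture_sector:
        if region is not None:
            if any(t in region for t in _SOY_EXPORTERS):
                return 0.95
            if "CHN" in region or "ROW" in region:
                return 0.60
        return 0.88
    return 0.92


def _land_va_share(config, sector):
    if sector in config.crop_sectors:
        return 0.20
    if sector == config.pasture_sector:
        return 0.15
    if sector == config.forest_sector:
        return 0.40
    return 0.0


def generate_sam(config: WorldConfig, munis: pd.DataFrame,
                 land_cells: pd.DataFrame | None = None,
                 tol=1e-12) -> SocialAccountingMatrix:
    """Balanced SAM with land payments disaggregated by biome-AEZ cell.

    Land rents per cell are imputed proportional to physical area times a
    biome productivity factor, then the whole matrix is RAS-balanced to
    micro-consistency (row sum == column sum per account).
    """
    if land_cells is None:
        land_cells = generate_land_cells(config, munis)
    rng = np.random.default_rng(config.random_seed + 3)
    R, S = config.regions, config.sectors
    weights = _output_weights(config, rng)

    acts = [f"A|{r}|{s}" for r in R for s in S]
    facs = [f"F|lab|{r}" for r in R] + [f"F|cap|{r}" for r in R]
    land_rows = []
    for _, cell in land_cells.iterrows():
        for s in config.land_sectors:
            if _cell_use_area(cell, s, config) > 0:
                land_rows.append(f"L|{cell['cell_id']}|{s}")
    hhs = [f"H|{r}" for r in R]
    accounts = acts + facs + land_rows + hhs
    m = pd.DataFrame(0.0, index=accounts, columns=accounts)

    y = {(r, s): _region_size(r) * weights[r][s] for r in R for s in S}
    va_total = {r: 0.0 for r in R}
    for r in R:
        for s in S:
            out = y[(r, s)]
            interm_share = 0.60 if _is_food(s) else (
                0.35 if s in config.land_sectors else 0.45)
            interm, va = out * interm_share, out * (1 - interm_share)
            va_total[r] += va
            # intermediate purchases: weighted by seller output share with
            # a strong crop/livestock affinity for food processors
            wvec = {}
            for i in S:
                aff = 3.0 if (_is_food(s) and i in config.land_sectors) else 1.0
                wvec[i] = weights[r][i] * aff
            tot = sum(wvec.values())
            for i in S:
                v = interm * wvec[i] / tot
                dom = _domestic_share(config, i, r)
                m.loc[f"A|{r}|{i}", f"A|{r}|{s}"] += v * dom
                tsh = _trade_shares(config, i, r)
                for src, sh in tsh.items():
                    m.loc[f"A|{src}|{i}", f"A|{r}|{s}"] += v * (1 - dom) * sh
            # factors
            land_sh = _land_va_share(config, s)
            land_v = va * land_sh
            rest = va - land_v
            m.loc[f"F|lab|{r}", f"A|{r}|{s}"] = rest * 0.55
            m.loc[f"F|cap|{r}", f"A|{r}|{s}"] = rest * 0.45
            if land_v > 0:
                cells_r = land_cells[land_cells["region"] == r]
                areas = np.array([_cell_use_area(c, s, config)
                                  for _, c in cells_r.iterrows()])
                prod = np.array([
                    _BIOME_PRODUCTIVITY.get(c["biome"], 0.9)
                    for _, c in cells_r.iterrows()])
                wcell = areas * prod
                if wcell.sum() <= 0:
                    continue
                wcell = wcell / wcell.sum()
                for (_, c), sh in zip(cells_r.iterrows(), wcell):
                    if sh > 0:
                        m.loc[f"L|{c['cell_id']}|{s}", f"A|{r}|{s}"] = \
                            land_v * sh
    # factor and land incomes accrue to the regional household
    for r in R:
        m.loc[f"H|{r}", f"F|lab|{r}"] = m.loc[f"F|lab|{r}"].sum() or 1.0
        m.loc[f"H|{r}", f"F|cap|{r}"] = m.loc[f"F|cap|{r}"].sum() or 1.0
    for lr in land_rows:
        region = lr.split("|")[1].split(":")[0]
        m.loc[f"H|{region}", lr] = m.loc[lr].sum()
    # household consumption
    for r in R:
        yhh = va_total[r]
        csh = {}
        for s in S:
            if s in config.crop_sectors:
                base = 0.02
            elif s in (config.pasture_sector,):
                base = 0.03
            elif s == config.forest_sector:
                base = 0.01
            elif _is_food(s):
                base = 0.22
            else:
                base = 0.60
            csh[s] = base * float(np.exp(rng.normal(0.0, 0.05)))
        tot = sum(csh.values())
        for s in S:
            v = yhh * csh[s] / tot
            dom = _domestic_share(config, s, r)
            m.loc[f"A|{r}|{s}", f"H|{r}"] += v * dom
            for src, sh in _trade_shares(config, s, r).items():
                m.loc[f"A|{src}|{s}", f"H|{r}"] += v * (1 - dom) * sh

    balanced = balance_sam(m.to_numpy(), tol=tol)
    sam = SocialAccountingMatrix(
        pd.DataFrame(balanced, index=accounts, columns=accounts))
    sam.check_balanced(1e-8)
    return sam


def _cell_use_area(cell, sector, config: WorldConfig):
    """Physical area (kha) of the cover rented by ``sector`` in a cell."""
    if sector in config.crop_sectors:
        return float(cell.get(f"crop_{sector}_ha", 0.0))
    if sector == config.pasture_sector:
        return float(cell["pasture_ha"])
    if sector == config.forest_sector:
        return float(cell["forest_ha"])
    return 0.0


def build_sam_from_shares(config: WorldConfig, land_cells: pd.DataFrame,
                          io_shares, trade, cons_shares,
                          land_va_shares=None, labor_of_nonland=0.55,
                          scale=1000.0) -> SocialAccountingMatrix:
    """Construct an exactly micro-consistent SAM from prescribed shares.

    Useful for controlled experiments and analytic toys where the
    benchmark trade pattern must be hit exactly (no RAS adjustment).

    Parameters
    ----------
    io_shares : array [S, R, S]
        ``io_shares[i, r, s]`` is the value share of the commodity-i
        composite in the unit cost of activity (r, s); the residual is
        value added.
    trade : array [S, R, R]
        ``trade[i, src, dst]`` sourcing shares of commodity i bought in
        dst (including the domestic diagonal); columns sum to 1.
    cons_shares : array [S, R]
        household budget shares per region (columns sum to 1).

    Output levels are the Perron vector of the implied circular-flow
    operator (value conservation makes it column-stochastic), so every
    market clears exactly at benchmark prices of 1.
    """
    R, S = config.n_regions, config.n_sectors
    a = np.asarray(io_shares, float)
    t = np.asarray(trade, float)
    c = np.asarray(cons_shares, float)
    if not np.allclose(t.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("trade shares must sum to 1 over sources")
    if not np.allclose(c.sum(axis=0), 1.0, atol=1e-10):
        raise ValueError("consumption shares must sum to 1")
    v = 1.0 - a.sum(axis=0)          # [R,S] value-added share
    if (v <= 0).any():
        raise ValueError("intermediate shares leave no value added")
    # circular-flow operator on the stacked output vector
    U = np.zeros((R * S, R * S))
    for i in range(S):
        for src in range(R):
            for dst in range(R):
                for s in range(S):
                    U[src * S + i, dst * S + s] = t[i, src, dst] * (
                        a[i, dst, s] + v[dst, s] * c[i, dst])
    q = np.full(R * S, 1.0)
    for _ in range(10000):
        q_new = U @ q
        q_new *= scale * R / q_new.sum()
        if np.abs(q_new - q).max() < 1e-13 * scale:
            q = q_new
            break
        q = q_new
    q = q.reshape(R, S)

    regions, sectors = config.regions, config.sectors
    acts = [f"A|{r}|{s}" for r in regions for s in sectors]
    facs = [f"F|lab|{r}" for r in regions] + [f"F|cap|{r}" for r in regions]
    land_rows = []
    for _, cell in land_cells.iterrows():
        for s in config.land_sectors:
            if s in sectors and _cell_use_area(cell, s, config) > 0:
                land_rows.append(f"L|{cell['cell_id']}|{s}")
    hhs = [f"H|{r}" for r in regions]
    accounts = acts + facs + land_rows + hhs
    m = pd.DataFrame(0.0, index=accounts, columns=accounts)

    for d, r in enumerate(regions):
        for s_i, s in enumerate(sectors):
            out = q[d, s_i]
            for i in range(S):
                for src in range(R):
                    val = t[i, src, d] * a[i, d, s_i] * out
                    if val > 0:
                        m.loc[f"A|{regions[src]}|{sectors[i]}",
                              f"A|{r}|{s}"] += val
            va = v[d, s_i] * out
            land_sh = (land_va_shares or {}).get(s, _land_va_share(config, s))
            land_v = va * land_sh if s in config.land_sectors else 0.0
            rest = va - land_v
            m.loc[f"F|lab|{r}", f"A|{r}|{s}"] = rest * labor_of_nonland
            m.loc[f"F|cap|{r}", f"A|{r}|{s}"] = rest * (1 - labor_of_nonland)
            if land_v > 0:
                cells_r = land_cells[land_cells["region"] == r]
                areas = np.array([_cell_use_area(cc, s, config)
                                  for _, cc in cells_r.iterrows()])
                if areas.sum() <= 0:
                    raise ValueError(f"no land for {s} in {r}")
                for (_, cc), ar in zip(cells_r.iterrows(), areas):
                    if ar > 0:
                        m.loc[f"L|{cc['cell_id']}|{s}", f"A|{r}|{s}"] = \
                            land_v * ar / areas.sum()
    for d, r in enumerate(regions):
        m.loc[f"H|{r}", f"F|lab|{r}"] = m.loc[f"F|lab|{r}"].sum()
        m.loc[f"H|{r}", f"F|cap|{r}"] = m.loc[f"F|cap|{r}"].sum()
        yr = float((v[d] * q[d]).sum())
        for i in range(S):
            for src in range(R):
                val = c[i, d] * t[i, src, d] * yr
                if val > 0:
                    m.loc[f"A|{regions[src]}|{sectors[i]}", f"H|{r}"] += val
    for lr in land_rows:
        region = lr.split("|")[1].split(":")[0]
        m.loc[f"H|{region}", lr] = m.loc[lr].sum()
    balanced = balance_sam(m.to_numpy(), tol=1e-13)
    sam = SocialAccountingMatrix(
        pd.DataFrame(balanced, index=m.index, columns=m.columns))
    sam.check_balanced(1e-8)
    return sam


# ---------------------------------------------------------------------------
# orchestration and IO
# ---------------------------------------------------------------------------


def generate_world(config: WorldConfig | None = None, **overrides) -> World:
    """Generate the complete synthetic world from a configuration."""
    if config is None:
        config = WorldConfig(**overrides)
    munis = generate_municipalities(config)
    roster = default_company_roster(config)
    exports = generate_trader_exports(munis, config, roster)
    cells = generate_land_cells(config, munis)
    sam = generate_sam(config, munis, cells)
    return World(config=config, municipalities=munis, roster=roster,
                 trader_exports=exports, land_cells=cells, sam=sam)


def write_world(world: World, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    world.config.to_yaml(d / "config.yaml")
    world.municipalities.to_csv(d / "municipalities.csv", index=False)
    world.roster.to_csv(d / "company_roster.csv", index=False)
    world.trader_exports.to_csv(d / "trader_exports.csv", index=False)
    world.land_cells.to_csv(d / "land_cells.csv", index=False)
    world.sam.to_csv(d / "sam.csv")


def read_world(directory) -> World:
    d = Path(directory)
    config = WorldConfig.from_yaml(d / "config.yaml")
    return World(
        config=config,
        municipalities=pd.read_csv(d / "municipalities.csv"),
        roster=pd.read_csv(d / "company_roster.csv"),
        trader_exports=pd.read_csv(d / "trader_exports.csv"),
        land_cells=pd.read_csv(d / "land_cells.csv"),
        sam=SocialAccountingMatrix.from_csv(d / "sam.csv"),
    )
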
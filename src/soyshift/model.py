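"""Medium-run applied general-equilibrium core with nested land supply.

The model is a levels-form multi-region CGE benchmarked on the synthetic
SAM. Each region produces every sector with Leontief intermediates over
Armington composites and Cobb-Douglas value added (labour, capital and —
for crops, grazing livestock and forestry — a CES land composite across
biome-AEZ cells). Land within each cell moves along a nested CET:

    total cell area
      └─ natural cover  vs  agricultural land        (sigma_nat)
          ├─ forest vs other natural                 (sigma_natsplit)
          └─ pasture vs cropland                     (sigma_agpast)
                └─ individual crops                  (sigma_crop)

separating the forest-conversion decision from the pasture-to-cropland
decision. Households follow a linear expenditure system calibrated to
per-commodity income elasticities. A zero-deforestation policy freezes
the restricted cover of covered cells at its benchmark area through an
endogenous subsidy on retaining that cover (constraint swap: area
exogenous, subsidy endogenous).

Physical hectares add up exactly at every nest level: the CET allocation
is renormalised to the parent area (see :func:`soyshift.nests.cet_allocate`).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import Drivers, Elasticities, WorldConfig
from .world import SocialAccountingMatrix

__all__ = [
    "ModelParams", "Shocks", "Equilibrium", "LandChangeTable",
    "SolverError", "CalibrationError", "calibrate", "replication_check",
    "solve", "apply_zdsp", "run_baseline", "run_counterfactual",
    "diff_land", "shocks_from_drivers", "model_cells",
]

COVERS = ["forest", "other_natural", "pasture", "cropland"]

#: benchmark reservation rent of unmanaged natural cover, as a fraction of
#: the cell's forest rent per hectare (shadow price only — no value flow)
RESERVATION_RENT_FRACTION = 0.3


class CalibrationError(ValueError):
    pass


class SolverError(RuntimeError):
    def __init__(self, msg, trace=None):
        super().__init__(msg)
        self.trace = trace or []


# ---------------------------------------------------------------------------
# parameter container
# ---------------------------------------------------------------------------


@dataclass
class ModelParams:
    """Calibrated benchmark data and behavioural parameters (all value
    units; benchmark price indices are 1)."""

    regions: list
    sectors: list
    crops: list
    pasture_sector: str
    forest_sector: str
    elasticities: Elasticities
    # benchmark flows
    y0: np.ndarray          # [R,S] output values
    io0: np.ndarray         # [S,R,S] composite intermediate use (i by (r,s))
    m0: np.ndarray          # [S,R,R] sourcing (i, src, dst); diag = domestic
    hh0: np.ndarray         # [S,R] household consumption of composites
    lab0: np.ndarray        # [R,S]
    cap0: np.ndarray        # [R,S]
    L0: np.ndarray          # [R]
    K0: np.ndarray          # [R]
    # LES
    beta: np.ndarray        # [S,R] marginal budget shares
    gamma: np.ndarray       # [S,R] subsistence quantities (value units)
    # land: cell tables
    cells: pd.DataFrame     # cell_id, region, compliant, biome ...
    cell_region: np.ndarray            # [C] region index
    area_f0: np.ndarray                # [C] restricted (forest) cover, kha
    area_o0: np.ndarray                # [C] other natural, kha
    area_p0: np.ndarray                # [C] pasture, kha
    area_c0: np.ndarray                # [C,K] crop areas, kha
    val_f0: np.ndarray                 # [C] benchmark land rent values
    val_p0: np.ndarray
    val_c0: np.ndarray                 # [C,K]
    val_o0: np.ndarray                 # [C] pseudo-value of reservation cover

    @property
    def nr(self):
        return len(self.regions)

    @property
    def ns(self):
        return len(self.sectors)

    @property
    def nc(self):
        return len(self.cells)

    @property
    def nk(self):
        return len(self.crops)

    def region_index(self, name):
        return self.regions.index(name)


@dataclass
class Shocks:
    """Proportional exogenous changes applied over the medium run."""

    tfp: np.ndarray | None = None          # [R,S] multipliers (1 = none)
    endow_labor: np.ndarray | None = None  # [R] multipliers
    endow_capital: np.ndarray | None = None
    demand_shift: np.ndarray | None = None  # [S,R] additive LES-gamma bump

    @classmethod
    def zero(cls, params: "ModelParams") -> "Shocks":
        return cls(tfp=np.ones((params.nr, params.ns)),
                   endow_labor=np.ones(params.nr),
                   endow_capital=np.ones(params.nr),
                   demand_shift=np.zeros((params.ns, params.nr)))

    def filled(self, params):
        z = Shocks.zero(params)
        return Shocks(
            tfp=self.tfp if self.tfp is not None else z.tfp,
            endow_labor=(self.endow_labor if self.endow_labor is not None
                         else z.endow_labor),
            endow_capital=(self.endow_capital if self.endow_capital is not None
                           else z.endow_capital),
            demand_shift=(self.demand_shift if self.demand_shift is not None
                          else z.demand_shift))


def shocks_from_drivers(params: ModelParams, drivers: Drivers,
                        config: WorldConfig) -> Shocks:
    """Translate medium-run drivers into model shocks."""
    R, S = params.nr, params.ns
    tfp = np.ones((R, S))
    land_sectors = set(config.land_sectors)
    for ri, r in enumerate(params.regions):
        for si, s in enumerate(params.sectors):
            if s == config.forest_sector:
                g = drivers.tfp_growth_forestry
            elif s in land_sectors:
                g = drivers.tfp_growth_ag
            else:
                g = drivers.tfp_growth_nonag
            tfp[ri, si] = 1.0 + g
    growth = np.array([1.0 + drivers.get_growth(r) for r in params.regions])
    shift = np.zeros((S, R))
    if "oilseeds" in params.sectors:
        osd = params.sectors.index("oilseeds")
        for r, frac in drivers.biofuel_demand.items():
            if r in params.regions:
                shift[osd, params.region_index(r)] += \
                    frac * params.hh0[osd, params.region_index(r)]
    food_like = [si for si, s in enumerate(params.sectors)
                 if (s in land_sectors and s != config.forest_sector)
                 or "processed" in s or "vegetable" in s]
    for ri, r in enumerate(params.regions):
        frac = drivers.get_food_demand(r)
        for si in food_like:
            shift[si, ri] += frac * params.hh0[si, ri]
    return Shocks(tfp=tfp, endow_labor=growth, endow_capital=growth,
                  demand_shift=shift)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def model_cells(footprint_cells: pd.DataFrame, land_cells: pd.DataFrame,
                config: WorldConfig) -> pd.DataFrame:
    """Combine Brazilian compliance cells with foreign aggregate cells."""
    bra = config.regions[0]
    foreign = land_cells[land_cells["region"] != bra].copy()
    foreign["base_cell_id"] = foreign["cell_id"]
    foreign["compliant"] = False
    # foreign restricted cover is plain forest; no grassland adjustment
    cols = ["cell_id", "base_cell_id", "region", "biome", "aez_id",
            "compliant", "forest_ha", "other_natural_ha", "pasture_ha",
            "cropland_ha"] + [f"crop_{c}_ha" for c in config.crop_sectors]
    fp = footprint_cells.copy()
    for c in cols:
        if c not in fp.columns:
            fp[c] = 0.0
        if c not in foreign.columns:
            foreign[c] = 0.0
    return pd.concat([fp[cols], foreign[cols]], ignore_index=True)


def calibrate(sam: SocialAccountingMatrix, cells: pd.DataFrame,
              config: WorldConfig,
              elasticities: Elasticities | None = None) -> ModelParams:
    """Read benchmark flows off the SAM and build calibrated parameters.

    SAM land accounts are at base-cell level; their value is split across
    compliance cells in proportion to physical area. Raises
    :class:`CalibrationError` for structurally impossible nests (an
    active sector with no value added, or a land-using sector with
    positive output but no land rent anywhere in its region).
    """
    el = elasticities if elasticities is not None else config.elasticities
    sam.check_balanced(1e-8)
    df = sam.df
    regions, sectors = list(config.regions), list(config.sectors)
    R, S = len(regions), len(sectors)
    ridx = {r: i for i, r in enumerate(regions)}
    sidx = {s: i for i, s in enumerate(sectors)}
    acts = {(r, s): f"A|{r}|{s}" for r in regions for s in sectors}

    y0 = np.zeros((R, S))
    for (r, s), a in acts.items():
        y0[ridx[r], sidx[s]] = df.loc[a].sum()
    io0 = np.zeros((S, R, S))
    m0 = np.zeros((S, R, R))
    for i in sectors:
        for src in regions:
            row = f"A|{src}|{i}"
            for dst in regions:
                v_users = sum(df.loc[row, acts[(dst, s)]] for s in sectors)
                v_hh = df.loc[row, f"H|{dst}"]
                m0[sidx[i], ridx[src], ridx[dst]] = v_users + v_hh
                for s in sectors:
                    io0[sidx[i], ridx[dst], sidx[s]] += \
                        df.loc[row, acts[(dst, s)]]
    hh0 = np.zeros((S, R))
    for i in sectors:
        for r in regions:
            hh0[sidx[i], ridx[r]] = sum(
                df.loc[f"A|{src}|{i}", f"H|{r}"] for src in regions)
    lab0 = np.zeros((R, S))
    cap0 = np.zeros((R, S))
    for (r, s), a in acts.items():
        lab0[ridx[r], sidx[s]] = df.loc[f"F|lab|{r}", a]
        cap0[ridx[r], sidx[s]] = df.loc[f"F|cap|{r}", a]
    L0 = lab0.sum(axis=1)
    K0 = cap0.sum(axis=1)

    # --- land accounts ---
    land_rows = sam.land_accounts()
    base_val = {}  # (base_cell_id, use) -> value
    for a in land_rows:
        _, cell_id, use = a.split("|")
        base_val[(cell_id, use)] = df.loc[a].sum()
    cells = cells.reset_index(drop=True)
    C, crops = len(cells), list(config.crop_sectors)
    K = len(crops)
    cell_region = np.array([ridx[r] for r in cells["region"]], dtype=int)
    area_f0 = cells["forest_ha"].to_numpy(float)
    area_o0 = cells["other_natural_ha"].to_numpy(float)
    area_p0 = cells["pasture_ha"].to_numpy(float)
    area_c0 = np.column_stack([
        cells[f"crop_{c}_ha"].to_numpy(float) for c in crops]) \
        if K else np.zeros((C, 0))
    # split base-cell SAM values by area share
    val_f0 = np.zeros(C)
    val_p0 = np.zeros(C)
    val_c0 = np.zeros((C, K))

    def _area(j, use):
        if use == config.forest_sector:
            return area_f0[j]
        if use == config.pasture_sector:
            return area_p0[j]
        return area_c0[j, crops.index(use)]

    for (base_id, use), val in base_val.items():
        members = [j for j in range(C)
                   if cells["base_cell_id"].iloc[j] == base_id]
        tot = sum(_area(j, use) for j in members)
        if tot <= 0:
            if val > 1e-9:
                raise CalibrationError(
                    f"land value for {base_id}/{use} but zero area")
            continue
        for j in members:
            share = _area(j, use) / tot
            if use == config.forest_sector:
                val_f0[j] = val * share
            elif use == config.pasture_sector:
                val_p0[j] = val * share
            else:
                val_c0[j, crops.index(use)] = val * share
    # reservation pseudo-value of unmanaged natural cover
    with np.errstate(invalid="ignore", divide="ignore"):
        rho_f = np.where(area_f0 > 0, val_f0 / np.maximum(area_f0, 1e-300), 0.0)
    fallback = np.where(area_p0 > 0, val_p0 / np.maximum(area_p0, 1e-300), 0.0)
    rho_res = RESERVATION_RENT_FRACTION * np.where(rho_f > 0, rho_f, fallback)
    val_o0 = rho_res * area_o0

    # --- structural checks ---
    for (r, s), a in acts.items():
        ri, si = ridx[r], sidx[s]
        if y0[ri, si] > 1e-9 and lab0[ri, si] + cap0[ri, si] <= 0:
            raise CalibrationError(f"activity {a} has output but no value "
                                   f"added")
    for s in config.land_sectors:
        if s not in sectors:
            continue
        for r in regions:
            ri = ridx[r]
            if y0[ri, sidx[s]] <= 1e-9:
                continue
            mask = cell_region == ri
            if s == config.forest_sector:
                tot = val_f0[mask].sum()
            elif s == config.pasture_sector:
                tot = val_p0[mask].sum()
            else:
                tot = val_c0[mask][:, crops.index(s)].sum()
            if tot <= 0:
                raise CalibrationError(
                    f"land nest for sector {s} in {r} has positive output "
                    f"but zero land rent (zero-value nest)")

    # --- LES ---
    Y0 = hh0.sum(axis=0)
    eta = np.array([el.get_income(s) for s in sectors])
    beta = np.zeros((S, R))
    gamma = np.zeros((S, R))
    for r in range(R):
        shares = hh0[:, r] / Y0[r]
        b = eta * shares
        beta[:, r] = b / b.sum()
        gamma[:, r] = hh0[:, r] - beta[:, r] * el.supernumerary_share * Y0[r]

    return ModelParams(
        regions=regions, sectors=sectors, crops=crops,
        pasture_sector=config.pasture_sector,
        forest_sector=config.forest_sector, elasticities=el,
        y0=y0, io0=io0, m0=m0, hh0=hh0, lab0=lab0, cap0=cap0, L0=L0, K0=K0,
        beta=beta, gamma=gamma, cells=cells, cell_region=cell_region,
        area_f0=area_f0, area_o0=area_o0, area_p0=area_p0, area_c0=area_c0,
        val_f0=val_f0, val_p0=val_p0, val_c0=val_c0, val_o0=val_o0)


# ---------------------------------------------------------------------------
# the equation system
# ---------------------------------------------------------------------------


def _ces_index(prices, weights, sigma):
    """CES price index over the first axis; weights sum to 1 there."""
    if abs(sigma - 1.0) < 1e-12:
        return np.exp(np.sum(weights * np.log(prices), axis=0))
    return np.sum(weights * prices ** (1.0 - sigma), axis=0) ** \
        (1.0 / (1.0 - sigma))


def _cet_pair_index(rA, rB, vA, vB, sigma):
    """Composite CET rent index of a two-child nest (value weights)."""
    tot = vA + vB
    thA = np.where(tot > 0, vA / np.maximum(tot, 1e-300), 0.5)
    thB = 1.0 - thA
    if sigma == 0:
        return thA * rA + thB * rB
    e = 1.0 + sigma
    return (thA * rA ** e + thB * rB ** e) ** (1.0 / e)


def _cet_pair_split(parent, aA, aB, rA, rB, sigma):
    """Share-form CET split of a parent area between two covers (exact
    adding-up; equals renormalised revenue-maximising CET allocation)."""
    wA = np.where(aA > 0, aA * rA ** sigma, 0.0)
    wB = np.where(aB > 0, aB * rB ** sigma, 0.0)
    tot = np.maximum(wA + wB, 1e-300)
    xA = np.where(wA + wB > 0, parent * wA / tot, 0.0)
    return xA, parent - xA


class _System:
    """Vectorised residual function over the packed unknown vector."""

    def __init__(self, params: ModelParams, shocks: Shocks,
                 freeze_idx=None, freeze_target=None, numeraire_scale=1.0):
        pm = params
        self.pm = pm
        self.sh = shocks.filled(pm)
        self.freeze_idx = np.array(freeze_idx if freeze_idx is not None
                                   else [], dtype=int)
        self.freeze_target = np.array(freeze_target if freeze_target
                                      is not None else [], dtype=float)
        self.num_scale = numeraire_scale
        R, S, C, K = pm.nr, pm.ns, pm.nc, pm.nk
        el = pm.elasticities
        self.sig_d = np.array([el.get_armington(s) for s in pm.sectors])
        self.sig_m = self.sig_d * el.armington_src_scale
        self.sig_nat = np.array([el.get_sigma_nat(r) for r in pm.regions])
        # masks
        self.cap_mask = pm.K0 > 1e-12
        self.active = pm.y0 > 1e-12
        # land slots: (kind, cell) kind 0=forest 1=pasture 2..=crop k
        slots = []
        for c in range(C):
            if pm.val_f0[c] > 1e-12:
                slots.append((0, c))
            if pm.val_p0[c] > 1e-12:
                slots.append((1, c))
            for k in range(K):
                if pm.val_c0[c, k] > 1e-12:
                    slots.append((2 + k, c))
        self.slots = slots
        self.dom0 = np.array([[pm.m0[i, d, d] for d in range(R)]
                              for i in range(S)])          # [S,R]
        self.tot0 = pm.m0.sum(axis=1)                      # [S,R] all sources
        self.imp0 = self.tot0 - self.dom0
        self.va0 = pm.lab0 + pm.cap0 + self._landval_sector()  # [R,S]
        self.QA0 = pm.io0.sum(axis=2) + pm.hh0             # [S,R] composite
        # sanity: composite use equals sourcing total
        self.L_bar = pm.L0 * self.sh.endow_labor
        self.K_bar = pm.K0 * self.sh.endow_capital
        self.gamma = pm.gamma + self.sh.demand_shift
        # numeraire weights (region 0 primary factor price index)
        wl, wk = pm.L0[0], pm.K0[0]
        self.th_num = (wl / (wl + wk), wk / (wl + wk))
        self._build_index()
        self._land_struct()

    def _landval_sector(self):
        pm = self.pm
        R, S = pm.nr, pm.ns
        out = np.zeros((R, S))
        for c in range(pm.nc):
            r = pm.cell_region[c]
            out[r, pm.sectors.index(pm.forest_sector)] += pm.val_f0[c]
            out[r, pm.sectors.index(pm.pasture_sector)] += pm.val_p0[c]
            for k, crop in enumerate(pm.crops):
                out[r, pm.sectors.index(crop)] += pm.val_c0[c, k]
        return out

    def _land_struct(self):
        pm = self.pm
        # per-sector land slot lists for the CES land composite
        self.sector_cells = {}
        for si, s in enumerate(pm.sectors):
            entries = []
            for kind, c in self.slots:
                if (kind == 0 and s == pm.forest_sector) or \
                   (kind == 1 and s == pm.pasture_sector) or \
                   (kind >= 2 and pm.crops and s == pm.crops[kind - 2]):
                    entries.append((kind, c))
            if entries:
                self.sector_cells[si] = entries

    def _build_index(self):
        pm = self.pm
        R, S = pm.nr, pm.ns
        n = 0
        self.i_p = slice(n, n + R * S); n += R * S
        self.i_q = slice(n, n + R * S); n += R * S
        self.i_w = slice(n, n + R); n += R
        self.ncap = int(self.cap_mask.sum())
        self.i_k = slice(n, n + self.ncap); n += self.ncap
        self.i_Y = slice(n, n + R); n += R
        self.nslot = len(self.slots)
        self.i_r = slice(n, n + self.nslot); n += self.nslot
        self.nfreeze = len(self.freeze_idx)
        self.i_z = slice(n, n + self.nfreeze); n += self.nfreeze
        self.n = n

    def unpack(self, z):
        pm = self.pm
        R, S = pm.nr, pm.ns
        p = np.exp(z[self.i_p]).reshape(R, S)
        q = np.exp(z[self.i_q]).reshape(R, S) * np.maximum(pm.y0, 1e-300)
        w = np.exp(z[self.i_w])
        k = np.ones(R)
        k[self.cap_mask] = np.exp(z[self.i_k])
        Y = np.exp(z[self.i_Y]) * pm.hh0.sum(axis=0)
        rr_f = np.ones(pm.nc)
        rr_p = np.ones(pm.nc)
        rr_c = np.ones((pm.nc, pm.nk))
        rv = np.exp(z[self.i_r])
        for v, (kind, c) in zip(rv, self.slots):
            if kind == 0:
                rr_f[c] = v
            elif kind == 1:
                rr_p[c] = v
            else:
                rr_c[c, kind - 2] = v
        zeta = z[self.i_z]
        return p, q, w, k, Y, rr_f, rr_p, rr_c, zeta

    # -- land supply given rents ------------------------------------------
    def land_supply(self, rr_f, rr_p, rr_c, zeta, cpi=None):
        """Nested CET allocation of every cell given rent indices.

        ``cpi`` (per region) indexes the reservation rent of unmanaged
        natural cover, keeping it constant in real terms; omitting it
        (reporting calls) evaluates at benchmark prices.
        """
        pm = self.pm
        el = pm.elasticities
        C, K = pm.nc, pm.nk
        rf_eff = rr_f.copy()
        if self.nfreeze:
            rf_eff[self.freeze_idx] *= np.exp(zeta)
        cpi = np.ones(pm.nr) if cpi is None else cpi
        r_res = el.reservation_rent_othernat * cpi[pm.cell_region]
        # composite rent indices bottom-up
        if K:
            vK = pm.val_c0.sum(axis=1)
            e = 1.0 + el.sigma_crop
            with np.errstate(invalid="ignore"):
                th = pm.val_c0 / np.maximum(vK, 1e-300)[:, None]
            RK = np.where(vK > 0,
                          np.sum(th * rr_c ** e, axis=1) ** (1 / e), 1.0)
        else:
            vK = np.zeros(C)
            RK = np.ones(C)
        RA = _cet_pair_index(rr_p, RK, pm.val_p0, vK, el.sigma_agpast)
        RN = _cet_pair_index(rf_eff, r_res, pm.val_f0, pm.val_o0,
                             el.sigma_natsplit)
        total = pm.area_f0 + pm.area_o0 + pm.area_p0 + pm.area_c0.sum(axis=1)
        a_nat0 = pm.area_f0 + pm.area_o0
        a_ag0 = pm.area_p0 + pm.area_c0.sum(axis=1)
        sig_nat_c = self.sig_nat[pm.cell_region]
        # region-specific sigma_nat: split per cell
        x_nat = np.zeros(C)
        x_ag = np.zeros(C)
        for c in range(C):
            xn, xa = _cet_pair_split(total[c], a_nat0[c], a_ag0[c],
                                     RN[c], RA[c], sig_nat_c[c])
            x_nat[c], x_ag[c] = xn, xa
        x_f, x_o = _cet_pair_split(x_nat, pm.area_f0, pm.area_o0,
                                   rf_eff, r_res, el.sigma_natsplit)
        cK0 = pm.area_c0.sum(axis=1)
        x_p, x_k = _cet_pair_split(x_ag, pm.area_p0, cK0, rr_p, RK,
                                   el.sigma_agpast)
        if K:
            wgt = np.where(pm.area_c0 > 0,
                           pm.area_c0 * rr_c ** el.sigma_crop, 0.0)
            tot = np.maximum(wgt.sum(axis=1), 1e-300)
            x_c = wgt / tot[:, None] * x_k[:, None]
        else:
            x_c = np.zeros((C, 0))
        return x_f, x_o, x_p, x_c

    # -- price blocks ------------------------------------------------------
    def armington_prices(self, p):
        """Two-level Armington price indices PM (imports) and PA (composite)."""
        pm = self.pm
        R, S = pm.nr, pm.ns
        pT = p.T
        PM = np.ones((S, R))
        PA = np.ones((S, R))
        for i in range(S):
            for d in range(R):
                if self.tot0[i, d] <= 0:
                    continue
                if self.imp0[i, d] > 1e-12:
                    wsrc = pm.m0[i, :, d].copy()
                    wsrc[d] = 0.0
                    wsrc /= wsrc.sum()
                    PM[i, d] = _ces_index(pT[i], wsrc, self.sig_m[i])
                th_d = self.dom0[i, d] / self.tot0[i, d]
                pr = np.array([p[d, i], PM[i, d]])
                PA[i, d] = _ces_index(pr, np.array([th_d, 1 - th_d]),
                                      self.sig_d[i])
        return PM, PA

    def cpi(self, PA):
        """Consumption price index per region (benchmark budget weights)."""
        pm = self.pm
        Y0 = pm.hh0.sum(axis=0)
        return np.sum(pm.hh0 / np.maximum(Y0, 1e-300)[None, :] * PA, axis=0)

    # -- full residual -----------------------------------------------------
    def residual(self, z):
        pm, sh, el = self.pm, self.sh, self.pm.elasticities
        R, S, C, K = pm.nr, pm.ns, pm.nc, pm.nk
        p, q, w, k, Y, rr_f, rr_p, rr_c, zeta = self.unpack(z)
        PM, PA = self.armington_prices(p)
        cpi = self.cpi(PA)

        # land composite price per (region, land sector)
        Pland = np.ones((R, S))
        lam = np.ones((R, S))
        for si, entries in self.sector_cells.items():
            s = pm.sectors[si]
            vals = []
            rents = []
            cells_r = {}
            for kind, c in entries:
                v = (pm.val_f0[c] if kind == 0 else
                     pm.val_p0[c] if kind == 1 else pm.val_c0[c, kind - 2])
                rent = (rr_f[c] if kind == 0 else
                        rr_p[c] if kind == 1 else rr_c[c, kind - 2])
                cells_r.setdefault(pm.cell_region[c], []).append((v, rent))
            for r, pairs in cells_r.items():
                v = np.array([a for a, _ in pairs])
                rv = np.array([b for _, b in pairs])
                Pland[r, si] = _ces_index(rv, v / v.sum(), el.sigma_landmob)
            if s in pm.crops:
                # yield response to the real (CPI-deflated) crop price
                lam[:, si] = (p[:, si] / cpi) ** el.yield_elast

        # unit costs and zero profit
        va_sh = self.va0 / np.maximum(pm.y0, 1e-300)
        thL = pm.lab0 / np.maximum(self.va0, 1e-300)
        thK = pm.cap0 / np.maximum(self.va0, 1e-300)
        thT = np.clip(1.0 - thL - thK, 0.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            logPVA = (thL * np.log(w)[:, None] + thK * np.log(k)[:, None]
                      + thT * np.log(Pland / lam))
        PVA = np.exp(logPVA)
        interm_sh = pm.io0 / np.maximum(pm.y0, 1e-300)[None, :, :]  # [S,R,S]
        cost = (np.einsum("irs,ir->rs", interm_sh, PA) + va_sh * PVA) / sh.tfp
        # inactive (zero-benchmark) activities: pin their log-price and
        # log-quantity unknowns instead, keeping the Jacobian regular
        lnp_raw = z[self.i_p].reshape(pm.nr, pm.ns)
        lnq_raw = z[self.i_q].reshape(pm.nr, pm.ns)
        res_zp = np.where(self.active, np.log(p) -
                          np.log(np.maximum(cost, 1e-300)), lnp_raw)

        # demands
        scale_q = q / np.maximum(pm.y0, 1e-300) / sh.tfp  # input scaling
        io = pm.io0 * scale_q[None, :, :]                 # [S,R,S]
        E_comm = np.sum(PA * self.gamma, axis=0)          # [R]
        cons = self.gamma + pm.beta * (Y - E_comm)[None, :] / PA
        QA = io.sum(axis=2) + cons                        # [S,R]
        # split composite demand into domestic and import-by-source
        D = np.zeros((R, S))   # demand for output of (src, i)
        for i in range(S):
            for d in range(R):
                if self.tot0[i, d] <= 0:
                    continue
                sQA = QA[i, d] / self.QA0[i, d]
                dom_q = (self.dom0[i, d] * sQA *
                         (PA[i, d] / p[d, i]) ** self.sig_d[i])
                D[d, i] += dom_q
                if self.imp0[i, d] > 1e-12:
                    imp_q = (self.imp0[i, d] * sQA *
                             (PA[i, d] / PM[i, d]) ** self.sig_d[i])
                    for src in range(R):
                        if src == d or pm.m0[i, src, d] <= 0:
                            continue
                        D[src, i] += (pm.m0[i, src, d] / self.imp0[i, d] *
                                      imp_q *
                                      (PM[i, d] / p[src, i]) ** self.sig_m[i])
        res_goods = np.where(self.active,
                             np.log(np.maximum(D, 1e-300)) -
                             np.log(np.maximum(q, 1e-300)), lnq_raw)

        # factor demands
        VAval = va_sh * PVA * q / sh.tfp                  # [R,S] value
        lab_d = (thL * VAval).sum(axis=1) / w
        cap_d = (thK * VAval).sum(axis=1) / k
        res_lab = np.log(lab_d[1:] / self.L_bar[1:])
        res_cap = np.log(cap_d[self.cap_mask] / self.K_bar[self.cap_mask])

        # land market
        x_f, x_o, x_p, x_c = self.land_supply(rr_f, rr_p, rr_c, zeta, cpi)
        d_f = np.zeros(C)
        d_p = np.zeros(C)
        d_c = np.zeros((C, K))
        # per sector: composite scale, then CES cell demands
        for si, entries in self.sector_cells.items():
            by_region = {}
            for kind, c in entries:
                by_region.setdefault(pm.cell_region[c], []).append((kind, c))
            for r, ents in by_region.items():
                v0 = np.array([
                    pm.val_f0[c] if kind == 0 else
                    pm.val_p0[c] if kind == 1 else pm.val_c0[c, kind - 2]
                    for kind, c in ents])
                a0 = np.array([
                    pm.area_f0[c] if kind == 0 else
                    pm.area_p0[c] if kind == 1 else pm.area_c0[c, kind - 2]
                    for kind, c in ents])
                rents = np.array([
                    rr_f[c] if kind == 0 else
                    rr_p[c] if kind == 1 else rr_c[c, kind - 2]
                    for kind, c in ents])
                landval = thT[r, si] * VAval[r, si]
                QLidx = landval / (v0.sum() * Pland[r, si])
                dem = a0 * QLidx * (Pland[r, si] / rents) ** el.sigma_landmob
                for (kind, c), dv in zip(ents, dem):
                    if kind == 0:
                        d_f[c] = dv
                    elif kind == 1:
                        d_p[c] = dv
                    else:
                        d_c[c, kind - 2] = dv
        res_land = np.zeros(self.nslot)
        for j, (kind, c) in enumerate(self.slots):
            if kind == 0:
                dd, ss = d_f[c], x_f[c]
            elif kind == 1:
                dd, ss = d_p[c], x_p[c]
            else:
                dd, ss = d_c[c, kind - 2], x_c[c, kind - 2]
            res_land[j] = np.log(max(dd, 1e-300)) - np.log(max(ss, 1e-300))

        # income
        rho_f0 = np.where(pm.area_f0 > 0,
                          pm.val_f0 / np.maximum(pm.area_f0, 1e-300), 0.0)
        rho_p0 = np.where(pm.area_p0 > 0,
                          pm.val_p0 / np.maximum(pm.area_p0, 1e-300), 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho_c0 = np.where(pm.area_c0 > 0,
                              pm.val_c0 / np.maximum(pm.area_c0, 1e-300), 0.0)
        land_inc = np.zeros(R)
        for c in range(C):
            r = pm.cell_region[c]
            land_inc[r] += (rho_f0[c] * rr_f[c] * x_f[c] +
                            rho_p0[c] * rr_p[c] * x_p[c] +
                            float(np.sum(rho_c0[c] * rr_c[c] * x_c[c])))
        inc = w * self.L_bar + k * self.K_bar + land_inc
        res_inc = np.log(Y) - np.log(np.maximum(inc, 1e-300))

        res_num = np.array([self.th_num[0] * w[0] + self.th_num[1] * k[0]
                            - self.num_scale])
        if self.nfreeze:
            res_frz = (np.log(np.maximum(x_f[self.freeze_idx], 1e-300)) -
                       np.log(self.freeze_target))
        else:
            res_frz = np.zeros(0)

        return np.concatenate([
            res_zp.ravel(), res_goods.ravel(), res_lab, res_cap,
            res_inc, res_land, res_num, res_frz])

    def _labour_gap0(self, z):
        """Value gap of the dropped region-0 labour market (Walras check)."""
        pm, sh, el = self.pm, self.sh, self.pm.elasticities
        R, S = pm.nr, pm.ns
        p, q, w, k, Y, rr_f, rr_p, rr_c, zeta = self.unpack(z)
        _, PA = self.armington_prices(p)
        cpi = self.cpi(PA)
        thL = pm.lab0 / np.maximum(self.va0, 1e-300)
        thK = pm.cap0 / np.maximum(self.va0, 1e-300)
        thT = np.clip(1.0 - thL - thK, 0.0, 1.0)
        Pland = np.ones((R, S)); lam = np.ones((R, S))
        for si, entries in self.sector_cells.items():
            pairs = [(pm.val_f0[c] if kind == 0 else
                      pm.val_p0[c] if kind == 1 else pm.val_c0[c, kind - 2],
                      rr_f[c] if kind == 0 else
                      rr_p[c] if kind == 1 else rr_c[c, kind - 2])
                     for kind, c in entries if pm.cell_region[c] == 0]
            if pairs:
                v = np.array([a for a, _ in pairs])
                rv = np.array([b for _, b in pairs])
                Pland[0, si] = _ces_index(rv, v / v.sum(), el.sigma_landmob)
            if pm.sectors[si] in pm.crops:
                lam[0, si] = (p[0, si] / cpi[0]) ** el.yield_elast
        with np.errstate(divide="ignore", invalid="ignore"):
            PVA0 = np.exp(thL[0] * np.log(w[0]) + thK[0] * np.log(k[0]) +
                          thT[0] * np.log(Pland[0] / lam[0]))
        va_sh = self.va0 / np.maximum(pm.y0, 1e-300)
        VAval0 = va_sh[0] * PVA0 * q[0] / sh.tfp[0]
        lab_d0 = (thL[0] * VAval0).sum() / w[0]
        return (lab_d0 - self.L_bar[0]) * w[0]


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------


@dataclass
class Equilibrium:
    """A solved price-quantity-land state."""

    regions: list
    sectors: list
    crops: list
    p: np.ndarray
    q: np.ndarray
    w: np.ndarray
    k: np.ndarray
    Y: np.ndarray
    rr_f: np.ndarray
    rr_p: np.ndarray
    rr_c: np.ndarray
    areas: pd.DataFrame          # per-cell land allocation (kha)
    subsidy: pd.DataFrame        # per frozen cell: rent-index wedge
    walras: float
    iterations: int
    max_residual: float
    z: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ri, r in enumerate(self.regions):
            for si, s in enumerate(self.sectors):
                rows.append(("price", f"{r}|{s}", self.p[ri, si]))
                rows.append(("output", f"{r}|{s}", self.q[ri, si]))
            rows.append(("wage", r, self.w[ri]))
            rows.append(("capital_rent", r, self.k[ri]))
            rows.append(("income", r, self.Y[ri]))
        return pd.DataFrame(rows, columns=["variable", "key", "value"])


def _newton(system: _System, z0=None, tol=1e-10, max_iter=60, verbose=False):
    n = system.n
    z = np.zeros(n) if z0 is None else z0.copy()
    trace = []
    F = system.residual(z)
    fn = np.abs(F).max()
    for it in range(max_iter):
        trace.append(fn)
        if fn < tol:
            return z, it, fn, trace
        J = np.empty((n, n))
        h = 1e-7
        for j in range(n):
            zj = z.copy()
            zj[j] += h
            J[:, j] = (system.residual(zj) - F) / h
        try:
            step = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError as exc:
            raise SolverError(
                "singular Jacobian — check the closure (numeraire and "
                "dropped market)", trace) from exc
        # damped update with backtracking
        lam = 1.0
        for _ in range(25):
            z_new = z + lam * np.clip(step, -5, 5)
            F_new = system.residual(z_new)
            fn_new = np.abs(F_new).max()
            if np.isfinite(fn_new) and fn_new < fn * (1 - 1e-4 * lam) + 1e-14:
                break
            lam *= 0.5
        else:
            raise SolverError(
                f"line search failed at residual {fn:.3e}", trace)
        z, F, fn = z_new, F_new, fn_new
    if fn < 1e-8:
        return z, max_iter, fn, trace
    raise SolverError(f"no convergence after {max_iter} iterations "
                      f"(residual {fn:.3e})", trace)


def solve(params: ModelParams, shocks: Shocks | None = None,
          constraint=None, z0=None, tol=1e-10,
          numeraire_scale=1.0) -> Equilibrium:
    """Solve for the market-clearing equilibrium by damped Newton.

    ``constraint`` is the object returned by :func:`apply_zdsp`. On
    failure a :class:`SolverError` carrying the residual trace is raised;
    a silently unconverged state is never returned.
    """
    pm = params
    shocks = shocks if shocks is not None else Shocks.zero(pm)
    fidx, ftgt = (constraint.cell_indices, constraint.targets) \
        if constraint is not None else (None, None)
    system = _System(pm, shocks, fidx, ftgt, numeraire_scale=numeraire_scale)
    z, it, fn, trace = _newton(system, z0=z0, tol=tol)
    p, q, w, k, Y, rr_f, rr_p, rr_c, zeta = system.unpack(z)
    _, PA = system.armington_prices(p)
    x_f, x_o, x_p, x_c = system.land_supply(rr_f, rr_p, rr_c, zeta,
                                            system.cpi(PA))
    areas = pm.cells[["cell_id", "region", "biome", "compliant"]].copy()
    areas["forest_ha"] = x_f
    areas["other_natural_ha"] = x_o
    areas["pasture_ha"] = x_p
    for kk, crop in enumerate(pm.crops):
        areas[f"crop_{crop}_ha"] = x_c[:, kk]
    areas["cropland_ha"] = x_c.sum(axis=1)
    frozen = pm.cells["cell_id"].iloc[list(fidx)] if fidx is not None else []
    sub = pd.DataFrame({
        "cell_id": list(frozen),
        "subsidy_wedge": list(np.exp(zeta) - 1.0) if fidx is not None else [],
    })
    walras = system._labour_gap0(z) / max(system.L_bar[0] * w[0], 1e-300)
    return Equilibrium(regions=pm.regions, sectors=pm.sectors, crops=pm.crops,
                       p=p, q=q, w=w, k=k, Y=Y, rr_f=rr_f, rr_p=rr_p,
                       rr_c=rr_c, areas=areas, subsidy=sub, walras=walras,
                       iterations=it, max_residual=fn, z=z)


def replication_check(params: ModelParams, tol=1e-8) -> dict:
    """Benchmark replication: zero shocks evaluated at benchmark prices.

    Returns a report with the max relative residual and the worst
    equations; raises nothing (negative controls inspect the report).
    """
    system = _System(params, Shocks.zero(params))
    F = system.residual(np.zeros(system.n))
    worst = np.argsort(-np.abs(F))[:5]
    return {
        "max_residual": float(np.abs(F).max()),
        "passed": bool(np.abs(F).max() < tol),
        "worst_equations": [(int(i), float(F[i])) for i in worst],
    }


@dataclass
class ZDSPConstraint:
    """Conversion freeze: restricted cover held at benchmark area in the
    covered cells via an endogenous retention subsidy."""

    cell_indices: list
    targets: list
    cell_ids: list


def apply_zdsp(params: ModelParams, cells_under_policy) -> ZDSPConstraint:
    """Build the conversion-freeze constraint for covered cells.

    ``cells_under_policy`` is an iterable of cell_ids. Covered cells with
    no restricted cover are skipped; unknown cells raise.
    """
    ids = list(params.cells["cell_id"])
    idxs, targets, kept = [], [], []
    for cid in cells_under_policy:
        if cid not in ids:
            raise KeyError(f"covered cell {cid!r} absent from model")
        j = ids.index(cid)
        if params.area_f0[j] > 0 and params.val_f0[j] > 1e-12:
            idxs.append(j)
            targets.append(params.area_f0[j])
            kept.append(cid)
    return ZDSPConstraint(cell_indices=idxs, targets=targets, cell_ids=kept)


def run_baseline(params: ModelParams, drivers: Drivers,
                 config: WorldConfig, z0=None) -> Equilibrium:
    """2011->2016 run without land restrictions anywhere."""
    return solve(params, shocks_from_drivers(params, drivers, config), z0=z0)


def run_counterfactual(params: ModelParams, drivers: Drivers,
                       config: WorldConfig, footprint_cells,
                       z0=None) -> Equilibrium:
    """Same drivers as the baseline plus the conversion freeze in the
    scenario footprint."""
    constraint = apply_zdsp(params, footprint_cells)
    return solve(params, shocks_from_drivers(params, drivers, config),
                 constraint=constraint, z0=z0)


# ---------------------------------------------------------------------------
# differencing
# ---------------------------------------------------------------------------


@dataclass
class LandChangeTable:
    """Counterfactual-minus-baseline land deltas per cell (kha).

    Positive ``d_forest`` is avoided deforestation; negative is displaced
    clearing. ``d_forest`` sums satisfy global = ZDSP + NoZDSP exactly.
    """

    table: pd.DataFrame
    policy_region: str

    @property
    def delta_zdsp(self) -> float:
        t = self.table
        return float(t.loc[t["covered"], "d_forest"].sum())

    @property
    def delta_no_zdsp(self) -> float:
        t = self.table
        return float(t.loc[~t["covered"], "d_forest"].sum())

    @property
    def delta_global(self) -> float:
        return float(self.table["d_forest"].sum())


def diff_land(eq_base: Equilibrium, eq_cf: Equilibrium,
              covered_cells=None, policy_region=None) -> LandChangeTable:
    """Difference two paired runs into a land-change table.

    ``covered_cells`` defaults to the counterfactual's frozen cells.
    """
    a, b = eq_base.areas, eq_cf.areas
    if list(a["cell_id"]) != list(b["cell_id"]):
        raise ValueError("mismatched model dimensions between runs")
    covered = set(covered_cells) if covered_cells is not None else \
        set(eq_cf.subsidy["cell_id"])
    policy_region = policy_region or eq_base.regions[0]
    t = a[["cell_id", "region", "biome"]].copy()
    t["covered"] = t["cell_id"].isin(covered)
    for col, name in [("forest_ha", "d_forest"),
                      ("other_natural_ha", "d_other_natural"),
                      ("pasture_ha", "d_pasture"),
                      ("cropland_ha", "d_cropland")]:
        t[name] = b[col].to_numpy() - a[col].to_numpy()
    for crop in eq_base.crops:
        t[f"d_crop_{crop}"] = (b[f"crop_{crop}_ha"].to_numpy() -
                               a[f"crop_{crop}_ha"].to_numpy())
    return LandChangeTable(table=t, policy_region=policy_region)
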
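"""Deforestation leakage rates and their domestic / cross-border
decomposition.

The leakage rate is the increase in deforestation in regions *without*
restrictions induced by the policy, as a percentage of the absolute
avoided deforestation in covered regions:

    leakage_rate = dDeforestation_NoZDSP / |dDeforestation_ZDSP| * 100

with the accounting identity

    dDeforestation_Global = dDeforestation_ZDSP + dDeforestation_NoZDSP

holding exactly on every land-change table. The module also recomputes
every piece of printed-results arithmetic from the bundled fixture of
published headline numbers (gross/net avoided deforestation, leakage
rates, GHG shares) and reports machine-readable pass/fail.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import LandChangeTable

__all__ = ["LeakageReport", "leakage_rate", "build_report",
           "load_printed_fixture", "verify_printed_arithmetic"]

#: region codes treated as the neighbouring-frontier (BAP) block
BAP_REGIONS = {"BAP", "BOL", "ARG", "PRY"}


def leakage_rate(delta_no_zdsp: float, delta_zdsp: float) -> float:
    """Leakage rate in percent.

    ``delta_no_zdsp`` is the *increase in deforestation* outside covered
    regions (positive = displaced clearing); ``delta_zdsp`` the
    deforestation change inside covered regions (its absolute value is
    the gross avoided deforestation). A zero denominator yields NaN with
    a warning.
    """
    if delta_zdsp == 0:
        warnings.warn("leakage rate undefined: zero avoided deforestation",
                      stacklevel=2)
        return float("nan")
    return delta_no_zdsp / abs(delta_zdsp) * 100.0


@dataclass
class LeakageReport:
    """Gross/net avoided deforestation decomposition (kha, raw floats;
    rounding happens only at the presentation layer)."""

    scenario: str
    gross_avoided_kha: float
    displaced_domestic_kha: float
    displaced_bap_kha: float
    displaced_row_kha: float
    net_country_kha: float
    net_global_kha: float
    domestic_leakage_rate_pct: float
    crossborder_leakage_rate_pct: float

    @property
    def displaced_crossborder_kha(self) -> float:
        return self.displaced_bap_kha + self.displaced_row_kha

    def check(self, tol=1e-9):
        lhs = self.net_global_kha
        rhs = (self.gross_avoided_kha - self.displaced_domestic_kha
               - self.displaced_crossborder_kha)
        scale = max(abs(self.gross_avoided_kha), 1.0)
        if abs(lhs - rhs) > tol * scale:
            raise AssertionError("leakage report violates additivity")

    def to_dict(self):
        d = {k: getattr(self, k) for k in (
            "scenario", "gross_avoided_kha", "displaced_domestic_kha",
            "displaced_bap_kha", "displaced_row_kha", "net_country_kha",
            "net_global_kha", "domestic_leakage_rate_pct",
            "crossborder_leakage_rate_pct")}
        d["displaced_crossborder_kha"] = self.displaced_crossborder_kha
        return d


def build_report(table: LandChangeTable, scenario: str = "",
                 policy_region: str | None = None) -> LeakageReport:
    """Decompose a land-change table into a leakage report.

    Signs: the table's ``d_forest`` is counterfactual-minus-baseline
    forest area (positive = avoided deforestation). Displacement is the
    deforestation *increase* outside covered cells, i.e. minus the
    forest delta there.
    """
    t = table.table
    policy = policy_region or table.policy_region
    needed = {"covered", "region", "d_forest"}
    if not needed.issubset(t.columns):
        raise ValueError(f"land-change table missing {needed - set(t.columns)}")
    cov = t["covered"]
    dom = (~cov) & (t["region"] == policy)
    bap = (~cov) & t["region"].isin(BAP_REGIONS)
    row = (~cov) & (t["region"] != policy) & ~t["region"].isin(BAP_REGIONS)
    gross = float(t.loc[cov, "d_forest"].sum())
    disp_dom = -float(t.loc[dom, "d_forest"].sum())
    disp_bap = -float(t.loc[bap, "d_forest"].sum())
    disp_row = -float(t.loc[row, "d_forest"].sum())
    net_country = gross - disp_dom
    net_global = gross - disp_dom - disp_bap - disp_row
    if gross != 0:
        dom_rate = leakage_rate(disp_dom, gross)
        cb_rate = leakage_rate(disp_bap + disp_row, gross)
    else:
        dom_rate = cb_rate = 0.0 if disp_dom == disp_bap == disp_row == 0 \
            else float("nan")
    rep = LeakageReport(
        scenario=scenario, gross_avoided_kha=gross,
        displaced_domestic_kha=disp_dom, displaced_bap_kha=disp_bap,
        displaced_row_kha=disp_row, net_country_kha=net_country,
        net_global_kha=net_global, domestic_leakage_rate_pct=dom_rate,
        crossborder_leakage_rate_pct=cb_rate)
    rep.check()
    return rep


# ---------------------------------------------------------------------------
# printed-results arithmetic
# ---------------------------------------------------------------------------

_FIXTURE = Path(__file__).parent / "data" / "paper_printed_values.csv"


def load_printed_fixture(path=None) -> pd.DataFrame:
    """The bundled fixture of published headline numbers."""
    df = pd.read_csv(path or _FIXTURE)
    required = {"scenario", "quantity", "value", "unit", "flag", "note"}
    if not required.issubset(df.columns):
        raise ValueError("printed-values fixture schema mismatch")
    return df


def _get(fix, scenario, quantity) -> float:
    sel = fix[(fix["scenario"] == scenario) & (fix["quantity"] == quantity)]
    if len(sel) != 1:
        raise ValueError(f"fixture missing {scenario}/{quantity}")
    return float(sel["value"].iloc[0])


def verify_printed_arithmetic(fixture: pd.DataFrame | None = None
                              ) -> pd.DataFrame:
    """Recompute every printed derived quantity from the fixture inputs.

    Each row: check name, computed raw value, presentation-rounded value,
    the published value, and a pass flag. Integer-percent rounding is
    used except where the published number carries more decimals; two
    checks published from unrounded model output are verified to within
    one printed unit (noted in the table).
    """
    fix = load_printed_fixture() if fixture is None else fixture
    g = lambda s, q: _get(fix, s, q)
    yrs = g("ref", "horizon")
    checks = []

    def add(name, computed, printed, decimals=0, tol=0.0, note=""):
        rounded = round(computed, decimals) if decimals else float(
            np.floor(computed + 0.5))
        passed = abs(rounded - printed) <= tol * 10 ** -decimals + 1e-12
        checks.append({"check": name, "computed": computed,
                       "rounded": rounded, "printed": printed,
                       "passed": bool(passed), "note": note})

    asm_gross = g("ASM", "gross_avoided")
    asm_dom_disp = asm_gross - g("ASM", "net_brazil")
    asm_cb = g("ASM", "bap_displaced") + g("ASM", "row_displaced")
    add("asm_annualized_kha_per_yr", asm_gross / yrs, g("ASM", "annualized"))
    add("asm_domestic_leakage_rate_pct",
        leakage_rate(asm_dom_disp, -asm_gross), g("ASM", "domestic_rate"))
    add("asm_crossborder_leakage_rate_pct",
        leakage_rate(asm_cb, -asm_gross), g("ASM", "crossborder_rate"),
        note="published as a lower bound (just above 3%)")
    add("asm_net_global_kha", asm_gross - asm_dom_disp - asm_cb,
        g("ASM", "net_global"), tol=1.5,
        note="published value printed from unrounded components")

    gz_gross = asm_gross + g("GlobalZDC", "gross_added_vs_asm")
    add("gzdc_gross_avoided_kha", gz_gross, g("GlobalZDC", "gross_avoided"))
    gz_dom_disp = gz_gross - g("GlobalZDC", "net_brazil")
    gz_cb = g("GlobalZDC", "bap_displaced") + g("GlobalZDC", "row_displaced")
    add("gzdc_domestic_leakage_rate_pct",
        leakage_rate(gz_dom_disp, -gz_gross), g("GlobalZDC", "domestic_rate"))
    add("gzdc_crossborder_leakage_rate_pct",
        leakage_rate(gz_cb, -gz_gross), g("GlobalZDC", "crossborder_rate"))
    add("gzdc_net_global_kha", gz_gross - gz_dom_disp - gz_cb,
        g("GlobalZDC", "net_global"), tol=1.5,
        note="published value printed from unrounded components")
    add("gzdc_gross_increase_vs_asm_pct",
        g("GlobalZDC", "gross_added_vs_asm") / asm_gross * 100,
        g("GlobalZDC", "gross_increase_vs_asm"), tol=1.5,
        note="published value printed from unrounded components")

    add("eu_biome_share_pct",
        g("EU", "net_amazon_cerrado")
        / g("ref", "soy_deforestation_amazon_cerrado") * 100,
        g("EU", "biome_share"))
    add("eu_net_increase_vs_gzdc_pct",
        (g("EU", "net_brazil") / g("GlobalZDC", "net_brazil") - 1) * 100,
        g("EU", "net_increase_vs_gzdc"))
    add("eu_global_increase_vs_gzdc_pct",
        (g("EU", "net_global") / g("GlobalZDC", "net_global") - 1) * 100,
        g("EU", "global_increase_vs_gzdc"))
    add("eu_ghg_reduction_vs_gzdc_pct",
        (g("EU", "ghg_savings") / g("GlobalZDC", "ghg_savings") - 1) * 100,
        g("EU", "ghg_reduction_vs_gzdc"))
    add("eu_annual_net_global_kha_per_yr",
        g("EU", "net_global") / yrs, g("EU", "annual_net_global"))

    lucf_g = g("ref", "lucf_global") * 1e3    # Mt -> kt
    lucf_b = g("ref", "lucf_brazil") * 1e3
    for scen, dg, db in [("asm", 3, 2), ("gzdc", 3, 2), ("eu", 3, 2)]:
        name = {"asm": "ASM", "gzdc": "GlobalZDC", "eu": "EU"}[scen]
        ghg = g(name, "ghg_savings")
        add(f"{scen}_ghg_share_global_pct", ghg / lucf_g * 100,
            g("ref", f"ghg_share_global_{scen}"), decimals=dg)
        add(f"{scen}_ghg_share_brazil_pct", ghg / lucf_b * 100,
            g("ref", f"ghg_share_brazil_{scen}"), decimals=db)

    return pd.DataFrame(checks)
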
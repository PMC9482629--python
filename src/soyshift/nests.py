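"""CES / CET nest primitives in calibrated share form.

Conventions
-----------
All functions are calibrated at a benchmark point ``(x0, p0)``; prices are
usually price *indices* equal to 1 at the benchmark, but arbitrary
benchmark prices are supported. A CET (constant elasticity of
transformation) frontier governs how a land parcel is split between
competing covers as relative rents move; a CES aggregate governs demand
composites (Armington trade nests, land composites across cells).
"""
from __future__ import annotations

import numpy as np

__all__ = ["ces_price_index", "ces_demands", "cet_allocate", "cet_rent_index"]


def _shares(x0, p0):
    x0 = np.asarray(x0, dtype=float)
    p0 = np.ones_like(x0) if p0 is None else np.asarray(p0, dtype=float)
    v0 = x0 * p0
    tot = v0.sum()
    if tot <= 0:
        raise ValueError("benchmark value must be positive")
    return x0, p0, v0 / tot


def ces_price_index(prices, x0, p0=None, sigma=1.0):
    """Unit-cost index of a CES composite, = 1 at the benchmark prices."""
    x0, p0, theta = _shares(x0, p0)
    rel = np.asarray(prices, dtype=float) / p0
    if abs(sigma - 1.0) < 1e-12:
        return float(np.exp(np.sum(theta * np.log(rel))))
    return float(np.sum(theta * rel ** (1.0 - sigma)) ** (1.0 / (1.0 - sigma)))


def ces_demands(prices, x0, p0=None, sigma=1.0, scale=1.0):
    """Cost-minimising input quantities for a CES composite.

    ``scale`` is the composite quantity relative to benchmark (index).
    At ``prices == p0`` and ``scale == 1`` this returns ``x0`` exactly.
    """
    x0, p0, _ = _shares(x0, p0)
    P = ces_price_index(prices, x0, p0, sigma)
    rel = np.asarray(prices, dtype=float) / p0
    return x0 * scale * (P / rel) ** sigma


def cet_allocate(parent_area, x0, rents, r0=None, sigma=1.0,
                 preserve_total=False):
    """Revenue-maximising split of ``parent_area`` across competing covers.

    The CET frontier is calibrated so that at benchmark rents ``r0`` the
    allocation is ``x0`` (scaled to the parent). With
    ``preserve_total=False`` (default) the children satisfy the CET
    aggregate constraint at ``parent_area`` — the textbook CET, matching
    a brute-force revenue maximisation on the frontier. With
    ``preserve_total=True`` the same relative allocation is renormalised
    so children sum *exactly* to ``parent_area`` (physical-hectare
    accounting, used inside the equilibrium model).

    sigma = 0 returns benchmark proportions scaled to the parent.
    """
    x0 = np.asarray(x0, dtype=float)
    rents = np.asarray(rents, dtype=float)
    r0 = np.ones_like(x0) if r0 is None else np.asarray(r0, dtype=float)
    if parent_area < 0:
        raise ValueError("parent_area must be >= 0")
    if np.any(rents < 0):
        raise ValueError("negative rent")
    if np.any(x0 < 0):
        raise ValueError("negative benchmark area")
    if x0.sum() == 0:
        return np.zeros_like(x0)
    if sigma == 0:
        return parent_area * x0 / x0.sum()
    pos = x0 > 0
    raw = np.zeros_like(x0)
    raw[pos] = x0[pos] * (rents[pos] / r0[pos]) ** sigma
    if raw.sum() == 0:
        raise ValueError("all rents zero for covers with positive area")
    if preserve_total:
        return parent_area * raw / raw.sum()
    # scale so the CET aggregate (calibrated with G(x0) = sum(x0)) equals
    # parent_area; G is homogeneous of degree 1, so scale linearly.
    rho = (sigma + 1.0) / sigma
    # delta_i proportional to r0_i / x0_i^(rho-1), normalised via G(x0)=sum(x0)
    delta = np.zeros_like(x0)
    delta[pos] = r0[pos] / x0[pos] ** (rho - 1.0)
    g_unnorm = np.sum(delta[pos] * x0[pos] ** rho) ** (1.0 / rho)
    delta /= g_unnorm ** rho / x0.sum() ** rho  # now G(x0) == sum(x0)
    g_raw = np.sum(delta[pos] * raw[pos] ** rho) ** (1.0 / rho)
    return raw * (parent_area / g_raw)


def cet_rent_index(rents, x0, r0=None, sigma=1.0):
    """Composite (revenue-per-unit) rent index of a CET nest, 1 at benchmark.

    For sigma = 0 this is the benchmark-share-weighted average rent.
    """
    x0, r0, theta = _shares(x0, r0)
    rel = np.asarray(rents, dtype=float) / r0
    if sigma == 0:
        return float(np.sum(theta * rel))
    return float(np.sum(theta * rel ** (1.0 + sigma)) ** (1.0 / (1.0 + sigma)))
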
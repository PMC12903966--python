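"""SOC stocks, fumigation-difference microbial biomass, and fraction accounting.

The areal carbon stock of a soil layer is

    stock [kg C m^-2] = SOC fraction [kg C / kg soil] x BD [kg m^-3] x thickness [m]

which is linear in each factor and additive over sub-layers.  The interface
takes SOC as a *mass fraction*; percent inputs must be divided by 100 at the
boundary (a fraction above 1 is rejected as an un-converted percent, the
classic x100 error).

Microbial biomass C and N are the plain difference between fumigated and
non-fumigated extract concentrations, with no extraction-efficiency divisor;
small negative differences (measurement noise near the detection limit) are
clamped to zero and flagged rather than raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class StockResult:
    """Areal SOC stock of one depth interval, with inputs echoed."""

    soc_stock: float          # kg C m^-2
    depth_top: float          # m
    depth_bottom: float       # m
    soc_fraction: float
    bulk_density: float       # kg m^-3


@dataclass(frozen=True)
class BiomassComponent:
    """One fumigation-difference result (C or N channel)."""

    value: float
    fumigated: float
    non_fumigated: float
    below_detection: bool     # True when the raw difference was negative


@dataclass(frozen=True)
class ClosureResult:
    """Diagnostic check that POC + MAOC accounts for SOC."""

    passed: bool
    residual: float           # soc - (poc + maoc), same unit as inputs


def soc_stock(soc_fraction: float, bulk_density: float,
              depth_top: float, depth_bottom: float) -> StockResult:
    """Areal SOC stock (kg C m^-2) of the layer ``depth_top..depth_bottom``."""
    if not 0.0 <= soc_fraction <= 1.0:
        raise ValueError(
            f"soc_fraction must be a mass fraction in [0, 1], got {soc_fraction}; "
            "percent values must be divided by 100 before calling")
    if bulk_density <= 0:
        raise ValueError("bulk_density must be strictly positive")
    if depth_top < 0 or depth_bottom <= depth_top:
        raise ValueError("need depth_bottom > depth_top >= 0")
    stock = soc_fraction * bulk_density * (depth_bottom - depth_top)
    return StockResult(stock, depth_top, depth_bottom, soc_fraction, bulk_density)


def microbial_biomass(fumigated: float, non_fumigated: float) -> BiomassComponent:
    """Fumigation-extraction difference, clamped at zero below detection."""
    if fumigated < 0 or non_fumigated < 0:
        raise ValueError("extract concentrations must be >= 0")
    diff = fumigated - non_fumigated
    if diff < 0:
        return BiomassComponent(0.0, fumigated, non_fumigated, True)
    return BiomassComponent(diff, fumigated, non_fumigated, False)


def fraction_closure(poc: float, maoc: float, soc: float,
                     tolerance: float = 0.10) -> ClosureResult:
    """Check |SOC - (POC + MAOC)| <= tolerance x SOC (all in one unit)."""
    if min(poc, maoc, soc) < 0:
        raise ValueError("pool concentrations must be >= 0")
    residual = soc - (poc + maoc)
    return ClosureResult(abs(residual) <= tolerance * soc, residual)


def percent_change(baseline: float, treatment: float) -> float:
    """Percent change of ``treatment`` relative to ``baseline`` (full precision)."""
    if baseline <= 0:
        raise ValueError("baseline must be strictly positive")
    return 100.0 * (treatment - baseline) / baseline


def round_percent(p: float) -> int:
    """Round a percent to integer, half away from zero (reporting convention)."""
    return int(math.floor(abs(p) + 0.5)) * (1 if p >= 0 else -1)


# --------------------------------------------------------------------------
# Table-level helpers over the cohort CSV schema
# --------------------------------------------------------------------------

_DEPTH_INTERVALS_M = {"0-15": (0.0, 0.15), "15-30": (0.15, 0.30)}


def depth_interval_m(depth_cm: str) -> tuple[float, float]:
    """Map a depth label like ``'0-15'`` (cm) to (top, bottom) in metres."""
    try:
        return _DEPTH_INTERVALS_M[depth_cm]
    except KeyError:
        top, bottom = depth_cm.split("-")
        return float(top) / 100.0, float(bottom) / 100.0


def stock_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-row SOC stocks (plot_id, treatment, depth_cm, soc_stock_kg_m2).

    ``soc_pct`` is a percent in the cohort schema and is converted to a mass
    fraction here, at the interface boundary.
    """
    tops, bottoms = zip(*(depth_interval_m(d) for d in cohort["depth_cm"]))
    stocks = (cohort["soc_pct"].to_numpy() / 100.0
              * cohort["bd_kg_m3"].to_numpy()
              * (np.asarray(bottoms) - np.asarray(tops)))
    return pd.DataFrame({
        "plot_id": cohort["plot_id"],
        "treatment": cohort["treatment"],
        "depth_cm": cohort["depth_cm"],
        "soc_stock_kg_m2": stocks,
    })
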
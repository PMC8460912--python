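"""Whole-period electron-equivalent ledger with percent closure error.

Every flow is rate * duration * gamma(compound) in electron-mmol. Inflows:
electrons fed with the substrates (C_feed * D) and net H2 consumed from the
gas loop. Outflows: residual substrates and products leaving with the
withdrawn broth (feed + net production), CH4 formed, net H2 formed, and the
electron-accepting capacity of the O2 that leaked in (4 e- per mol O2).
The closure error is 100 * (out - in) / in — negative when part of the
monitored electron pool had unexplained consumption.

Inert species never enter the ledger: He, ethylene (inhibitor, consumption
never observed) and N2 (gamma would be -6 under the blanket ammonia-N
convention, but N2 is biologically untouched here). Biomass
(CH1.8O0.5N0.2, gamma 4.2) is excluded by default and includable via an
explicit rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from .compounds import (CompoundRegistry, DEFAULT_REGISTRY, MOLAR_VOLUME_ML,
                        degree_of_reduction)
from .errors import CoverageError, RegistryError
from .liquid_rates import RatePeriod

LEDGER_INERT = frozenset({"he", "ethylene", "n2"})


@dataclass(frozen=True)
class Flow:
    side: str        # "in" | "out"
    compound: str
    e_mmol: float    # magnitude, >= 0


@dataclass(frozen=True)
class ElectronLedger:
    period: RatePeriod
    flows: tuple[Flow, ...]
    error_pct: float

    def total(self, side: str) -> float:
        return sum(f.e_mmol for f in self.flows if f.side == side)


def build_ledger(rate_table: pd.DataFrame,
                 gas_rates: Mapping[str, float],
                 o2_rate_ml: float,
                 period: RatePeriod,
                 feed_mM: Mapping[str, float],
                 hrt: float,
                 liquid_volume: float = 1.0,
                 registry: Optional[CompoundRegistry] = None,
                 period_label: Optional[str] = None,
                 drop: frozenset[str] = frozenset(),
                 biomass_rate: float = 0.0) -> ElectronLedger:
    """Assemble the electron ledger for one period.

    ``rate_table`` is the tidy frame from :func:`fermbal.liquid_rates.rate_table`
    (liquid compounds); ``gas_rates`` maps gas species to net volumetric
    production rates in mmol L^-1 d^-1 (negative = consumed); ``o2_rate_ml``
    is the O2 contamination rate in mL O2 L^-1 d^-1. ``drop`` removes named
    compounds from the ledger (useful to demonstrate how a missing flow
    shows up as closure error). ``biomass_rate`` (mmol C-mol L^-1 d^-1)
    optionally adds a biomass outflow.
    """
    reg = registry or DEFAULT_REGISTRY
    label = period_label or period.label
    sub = rate_table[rate_table["period"] == label] if label else rate_table
    if sub.empty:
        raise CoverageError(f"rate table has no rows for period {label!r}")
    if sub["compound"].duplicated().any():
        raise CoverageError(f"duplicate compounds for period {label!r}")

    T = period.duration
    V = liquid_volume
    D = 1.0 / hrt
    flows: list[Flow] = []

    def add(side: str, compound: str, e: float) -> None:
        # A negative residual outflow means net drawdown of the liquid
        # inventory: book it on the opposite side to keep magnitudes >= 0.
        if e < 0:
            side = "in" if side == "out" else "out"
            e = -e
        if e > 0:
            flows.append(Flow(side, compound, e))

    for _, row in sub.iterrows():
        comp, rate = row["compound"], row["rate"]
        if comp in drop or comp in LEDGER_INERT:
            continue
        try:
            gamma = degree_of_reduction(reg.get(comp))
        except RegistryError:
            raise RegistryError(f"no registry entry (gamma) for {comp!r}")
        if gamma == 0:
            continue
        e_feed = dict(feed_mM).get(comp, 0.0) * D * T * V * gamma
        add("in", comp, e_feed)
        add("out", comp, e_feed + rate * T * V * gamma)

    for species, rate in gas_rates.items():
        if species in drop or species in LEDGER_INERT or species == "o2":
            continue
        gamma = degree_of_reduction(reg.get(species))
        if gamma == 0:
            continue
        e = rate * T * V * gamma
        if e >= 0:
            add("out", species, e)
        else:
            add("in", species, -e)

    if "o2" not in drop and o2_rate_ml:
        n_o2 = o2_rate_ml * T * V / MOLAR_VOLUME_ML       # mmol O2
        add("out", "o2", 4.0 * n_o2)                      # acceptor sink

    if biomass_rate:
        gamma_x = degree_of_reduction(reg.get("biomass"))
        add("out", "biomass", biomass_rate * T * V * gamma_x)

    total_in = sum(f.e_mmol for f in flows if f.side == "in")
    total_out = sum(f.e_mmol for f in flows if f.side == "out")
    if total_in <= 0:
        raise CoverageError("ledger has no electron inflows")
    error_pct = 100.0 * (total_out - total_in) / total_in
    return ElectronLedger(period, tuple(flows), error_pct)


def ledger_report(ledger: ElectronLedger) -> pd.DataFrame:
    """Ranked table of flows with per-side shares (percent, summing to 100
    per side); ordering is deterministic: share descending, then name."""
    totals = {"in": ledger.total("in"), "out": ledger.total("out")}
    rows = [{"side": f.side, "compound": f.compound, "e_mmol": f.e_mmol,
             "share_pct": 100.0 * f.e_mmol / totals[f.side]}
            for f in ledger.flows]
    df = pd.DataFrame(rows)
    df = df.sort_values(["side", "share_pct", "compound"],
                        ascending=[True, False, True], kind="mergesort")
    return df.reset_index(drop=True)
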
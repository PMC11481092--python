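"""Mass-flow accounting and green metrics (process mass intensity).

PMI is the total mass of material fed to the process divided by the mass of
product made; a value of 1 means everything fed ends up in the product.  On
a continuous rig both numbers are steady-state rates (g/h), so the ratio is
identical to the batch mass ratio.  Because dilute solutions dominate the
inventory, the headline comparison uses a best-case recycling scenario in
which only 20 % of the solvent mass is counted as consumed::

    PMI        = total mass rate / product mass rate
    PMI_20%    = (non-solvent mass + 0.2 x solvent mass) / product mass

The module converts rig steady states into per-material mass-flow
breakdowns, computes PMI and throughput, and assembles the four-row
single-step-vs-telescoped comparison table.  ``TABLE1`` holds the published
per-mode inputs (total mass rate, product mass rate, solvent percentage,
experiments to optimum) used by the reference comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .virtual_rig import MOLAR_MASS, RigPreset, StreamComposition

__all__ = [
    "MaterialFlow",
    "MassFlowBreakdown",
    "PMIReport",
    "UndefinedPMIError",
    "mass_flows",
    "pmi",
    "pmi_solvent_scenario",
    "throughput",
    "breakdown_from_totals",
    "comparison_report",
    "TABLE1",
    "MODE_ORDER",
]

#: Published reference row inputs, per mode: (total mass rate g/h, product
#: mass rate g/h, % of total mass from solvent, experiments to optimum).
TABLE1: dict[str, tuple[float, float, float, int]] = {
    "osat_step1": (26.9, 0.021, 96.0, 9),
    "osat_step2": (21.6, 0.072, 99.0, 11),
    "osat_combined": (39.9, 0.044, 97.0, 20),
    "telescoped": (44.8, 0.190, 95.0, 12),
}

MODE_ORDER = ("osat_step1", "osat_step2", "osat_combined", "telescoped")


class UndefinedPMIError(ZeroDivisionError):
    """PMI is undefined because the product mass rate is zero."""


@dataclass(frozen=True)
class MaterialFlow:
    name: str
    rate_g_h: float
    is_solvent: bool = False

    def __post_init__(self) -> None:
        if self.rate_g_h < 0:
            raise ValueError(f"negative mass rate for {self.name}")


@dataclass(frozen=True)
class MassFlowBreakdown:
    """Per-material input mass rates plus the product output rate (g/h)."""

    materials: tuple[MaterialFlow, ...]
    product_rate_g_h: float

    def __post_init__(self) -> None:
        if self.product_rate_g_h < 0:
            raise ValueError("negative product mass rate")

    @property
    def total(self) -> float:
        return sum(m.rate_g_h for m in self.materials)

    @property
    def solvent_mass(self) -> float:
        return sum(m.rate_g_h for m in self.materials if m.is_solvent)

    @property
    def solvent_fraction(self) -> float:
        return self.solvent_mass / self.total if self.total > 0 else 0.0

    @property
    def flagged(self) -> bool:
        """True when no product is made, so PMI is undefined."""
        return self.product_rate_g_h <= 0.0

    def scaled(self, c: float) -> "MassFlowBreakdown":
        return MassFlowBreakdown(
            tuple(MaterialFlow(m.name, m.rate_g_h * c, m.is_solvent)
                  for m in self.materials),
            self.product_rate_g_h * c)


@dataclass(frozen=True)
class PMIReport:
    """Green-metric summary for one campaign optimum."""

    pmi: float
    pmi_solvent20: float
    solvent_pct: float
    product_rate: float
    experiments_to_optimum: int | None = None


def _solution_stream(name_solutes: Sequence[tuple[str, float, float]],
                     flow_mL_min: float, preset: RigPreset
                     ) -> list[MaterialFlow]:
    """Feed-stream inventory: solutes plus solvent by difference.

    Solution density is approximated by the solvent density, so the solvent
    mass rate is the stream mass rate minus the dissolved-solute mass.
    """
    flows = []
    solute_mass = 0.0
    for name, conc, molar_mass in name_solutes:
        rate = conc * flow_mL_min / 1000.0 * molar_mass * 60.0
        solute_mass += rate
        if rate > 0:
            flows.append(MaterialFlow(name, rate))
    solvent = flow_mL_min * 60.0 * preset.solvent_density - solute_mass
    flows.append(MaterialFlow("2-MeTHF", max(solvent, 0.0), is_solvent=True))
    return flows


def mass_flows(conditions: Mapping[str, float], preset: RigPreset,
               outlet: StreamComposition, mode: str,
               feed: StreamComposition | None = None) -> MassFlowBreakdown:
    """Steady-state mass-flow breakdown at one set of conditions.

    ``mode`` selects the stream inventory:

    * ``step1`` — substrate solution + hydrogen; product is 4-aminophenol.
    * ``step2``/``step2_im`` — reservoir solution (with its anhydride
      charge) flowing at ``V_R2 / tau2``; product is acetaminophen.
    * ``telescoped`` — substrate solution, anhydride solution and hydrogen;
      product is acetaminophen in the combined outlet.
    """
    if mode == "step1":
        Q1 = float(conditions["Q1"])
        C1 = float(conditions.get("C1", preset.stock_conc_1))
        mats = _solution_stream(
            [("4-nitrophenol", C1, MOLAR_MASS["nitrophenol"])], Q1, preset)
        mats.append(MaterialFlow("hydrogen", preset.gas_mass_rate))
        product = (outlet.c_aminophenol * Q1 / 1000.0
                   * MOLAR_MASS["aminophenol"] * 60.0)
    elif mode in ("step2", "step2_im"):
        if feed is None:
            raise ValueError("step-2 mass flows require the reservoir feed")
        tau2 = float(conditions["tau2"])
        Q = preset.V_R2 / tau2
        equiv = float(conditions.get("equiv", 0.0))
        solutes = [
            ("4-aminophenol", feed.c_aminophenol, MOLAR_MASS["aminophenol"]),
            ("4-nitrophenol", feed.c_nitrophenol, MOLAR_MASS["nitrophenol"]),
            ("acetic anhydride", equiv * feed.c_aminophenol,
             MOLAR_MASS["anhydride"]),
        ]
        mats = _solution_stream(solutes, Q, preset)
        product = (outlet.c_acetaminophen * Q / 1000.0
                   * MOLAR_MASS["acetaminophen"] * 60.0)
    elif mode == "telescoped":
        Q1 = float(conditions["Q1"])
        Q3 = Q1 / float(conditions["ratio"])
        mats = _solution_stream(
            [("4-nitrophenol", preset.stock_conc_1,
              MOLAR_MASS["nitrophenol"])], Q1, preset)
        mats += _solution_stream(
            [("acetic anhydride", preset.stock_conc_3,
              MOLAR_MASS["anhydride"])], Q3, preset)
        mats.append(MaterialFlow("hydrogen", preset.gas_mass_rate))
        product = (outlet.c_acetaminophen * outlet.liquid_flow / 1000.0
                   * MOLAR_MASS["acetaminophen"] * 60.0)
    else:
        raise ValueError(f"unknown mass-flow mode {mode!r}")
    bd = MassFlowBreakdown(tuple(mats), max(product, 0.0))
    if bd.flagged:
        warnings.warn("zero product mass rate: PMI undefined for this "
                      "breakdown", stacklevel=2)
    return bd


def breakdown_from_totals(total: float, product: float, solvent_pct: float
                          ) -> MassFlowBreakdown:
    """Breakdown reconstructed from printed totals (reference-table rows)."""
    solvent = total * solvent_pct / 100.0
    other = max(total - solvent, 0.0)
    return MassFlowBreakdown(
        (MaterialFlow("solvent", solvent, is_solvent=True),
         MaterialFlow("non-solvent inputs", other)),
        product)


def pmi(bd: MassFlowBreakdown) -> float:
    """Process mass intensity: total input mass per mass of product."""
    if bd.flagged:
        raise UndefinedPMIError("PMI undefined: product mass rate is zero")
    return bd.total / bd.product_rate_g_h


def pmi_solvent_scenario(bd: MassFlowBreakdown,
                         retained_fraction: float = 0.2) -> float:
    """PMI when only ``retained_fraction`` of the solvent counts as consumed
    (the best-case solvent-recycling scenario)."""
    if not 0.0 <= retained_fraction <= 1.0:
        raise ValueError("retained_fraction must lie in [0, 1]")
    if bd.flagged:
        raise UndefinedPMIError("PMI undefined: product mass rate is zero")
    nonsolvent = bd.total - bd.solvent_mass
    return (nonsolvent + retained_fraction * bd.solvent_mass) / bd.product_rate_g_h


def throughput(bd: MassFlowBreakdown, hours: float) -> float:
    """Product mass (g) over an operating period."""
    if hours < 0:
        raise ValueError("hours must be nonnegative")
    return bd.product_rate_g_h * hours


def comparison_report(entries: Mapping[str, tuple[MassFlowBreakdown, int]]
                      ) -> pd.DataFrame:
    """Four-row comparison table (one row per optimization mode).

    ``entries`` maps mode names (see ``MODE_ORDER``) to a breakdown and the
    campaign's experiments-to-optimum count.  Missing modes are omitted
    with a warning.
    """
    rows = []
    for mode in MODE_ORDER:
        if mode not in entries:
            warnings.warn(f"comparison report: missing mode {mode!r}; "
                          f"row omitted", stacklevel=2)
            continue
        bd, n_expt = entries[mode]
        rows.append({
            "reaction step": mode,
            "total mass/g h-1": bd.total,
            "mass of product/g h-1": bd.product_rate_g_h,
            "PMI with 20% solvent mass": pmi_solvent_scenario(bd),
            "% of total mass from solvent": 100.0 * bd.solvent_fraction,
            "no. of expt. to reach optimum": n_expt,
        })
    return pd.DataFrame(rows)


def reference_report() -> pd.DataFrame:
    """The comparison table computed from the published row inputs."""
    entries = {
        mode: (breakdown_from_totals(total, product, pct), n)
        for mode, (total, product, pct, n) in TABLE1.items()
    }
    return comparison_report(entries)
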
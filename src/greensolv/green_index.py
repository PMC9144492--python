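"""Environmental-index (EI) aggregation and ranking.

The EI of a neat solvent is the plain sum of its eight raw component
scores (human ingestion/inhalation toxicity, terrestrial and aquatic
toxicity, global warming, ozone depletion, photochemical oxidation, acid
rain); lower is greener.  Water anchors the scale at EI = 0.02.  A variant
excluding the photochemical-oxidation (PCOP) term is carried alongside the
default: PCOP dominates the EI of low-volatility solvents such as DMSO
even though atmospheric photo-degradation is largely irrelevant for them.

Aqueous-binary mixtures are scored by mass-fraction-weighted averaging of
the neat organic EI with water's: converting the solute-free organic mole
fraction x to a mass fraction w = x·M_org/(x·M_org + (1−x)·M_water), then
EI_mix = w·EI_neat + (1−w)·EI_water.  Because water's component-level
breakdown is not published, mixing operates on EI totals, not per
component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from greensolv.catalog import EIComponents, SolventRecord

WATER_EI = 0.02
WATER_MOLAR_MASS = 18.02  # g/mol


def ei_total(components: EIComponents, include_pcop: bool = True) -> float:
    """Sum of the eight raw component scores; PCOP omitted on request."""
    total = sum(components.as_tuple())
    return total if include_pcop else total - components.pcop


def ei_aqueous_mixture(
    organic: SolventRecord,
    organic_fraction: float,
    water_molar_mass: float = WATER_MOLAR_MASS,
    water_ei: float = WATER_EI,
    include_pcop: bool = True,
) -> float:
    """EI of a water-organic binary at solute-free organic mole fraction
    ``organic_fraction``, by mass-fraction weighting of the EI totals."""
    if not 0.0 <= organic_fraction <= 1.0:
        raise ValueError("organic_fraction must lie in [0, 1]")
    if organic.ei is None:
        raise ValueError(f"solvent {organic.name!r} carries no EI components")
    x = organic_fraction
    m_org = x * organic.molar_mass
    m_wat = (1.0 - x) * water_molar_mass
    w = m_org / (m_org + m_wat) if (m_org + m_wat) > 0 else 0.0
    return w * ei_total(organic.ei, include_pcop) + (1.0 - w) * water_ei


@dataclass(frozen=True)
class EISystem:
    """One ranked system: a neat solvent, an aqueous mixture, or water."""

    label: str
    organic_fraction: Optional[float]  # None for water itself
    ei_default: float
    ei_no_pcop: float


@dataclass(frozen=True)
class RankedEntry:
    label: str
    organic_fraction: Optional[float]
    ei_default: float
    ei_no_pcop: float
    rank_default: int
    rank_no_pcop: int
    tied_default: bool = False
    tied_no_pcop: bool = False


def aqueous_grid_systems(
    organics: Iterable[SolventRecord],
    fractions: Sequence[float] = (0.2, 0.4, 0.6, 0.8, 1.0),
    include_water: bool = True,
    water_ei: float = WATER_EI,
) -> list[EISystem]:
    """Build the EI systems for each organic solvent across an aqueous
    composition grid (x = 1 is the neat solvent), optionally with water."""
    systems: list[EISystem] = []
    if include_water:
        systems.append(EISystem("water", None, water_ei, water_ei))
    for org in organics:
        for x in fractions:
            systems.append(
                EISystem(
                    label=org.name,
                    organic_fraction=x,
                    ei_default=ei_aqueous_mixture(org, x, water_ei=water_ei),
                    ei_no_pcop=ei_aqueous_mixture(
                        org, x, water_ei=water_ei, include_pcop=False
                    ),
                )
            )
    return systems


def _rank(values: Sequence[float], labels: Sequence[str]) -> tuple[list[int], list[bool]]:
    order = sorted(range(len(values)), key=lambda i: (values[i], labels[i]))
    ranks = [0] * len(values)
    for pos, i in enumerate(order):
        ranks[i] = pos + 1
    tied = [
        any(values[i] == values[j] for j in range(len(values)) if j != i)
        for i in range(len(values))
    ]
    return ranks, tied


def rank_systems(systems: Sequence[EISystem]) -> list[RankedEntry]:
    """Rank systems ascending by EI, independently for the default and the
    PCOP-excluded variant.  Ties broken lexicographically by label (then
    fraction) and flagged."""
    if not systems:
        raise ValueError("need at least one system to rank")
    keys = [f"{s.label}|{-1.0 if s.organic_fraction is None else s.organic_fraction}"
            for s in systems]
    r_def, t_def = _rank([s.ei_default for s in systems], keys)
    r_np, t_np = _rank([s.ei_no_pcop for s in systems], keys)
    return [
        RankedEntry(
            label=s.label,
            organic_fraction=s.organic_fraction,
            ei_default=s.ei_default,
            ei_no_pcop=s.ei_no_pcop,
            rank_default=r_def[i],
            rank_no_pcop=r_np[i],
            tied_default=t_def[i],
            tied_no_pcop=t_np[i],
        )
        for i, s in enumerate(systems)
    ]
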
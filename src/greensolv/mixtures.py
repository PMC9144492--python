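"""Binary-solvent solubility profiles and their classification.

A profile is solubility versus the solute-free organic mole fraction x2* in
a water-organic binary at fixed temperature.  Three behaviours are
distinguished:

* water-antisolvent — solubility falls monotonically as water is added
  (the common case for aprotic solubilizers of aromatic amides);
* synergistic (co-solvation) — an interior composition dissolves more than
  either neat endpoint, e.g. salicylamide in aqueous 4-formylmorpholine
  peaking at x2* = 0.6;
* irregular — neither, beyond replicate noise.

Also provides the "solubilizing power" ordering of neat solvents with an
explicit approximately-equal grouping (DMF > 4FM ≈ DMSO style).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from greensolv.catalog import MeasurementRecord


class ProfileClass(str, Enum):
    WATER_ANTISOLVENT = "water_antisolvent"
    SYNERGISTIC = "synergistic"
    IRREGULAR = "irregular"


@dataclass(frozen=True)
class SolubilityProfile:
    """Mean solubility vs. solute-free organic fraction at one temperature.

    Points are sorted by fraction on construction, so classification is
    independent of input order.  Fractions must be distinct; solubilities
    lie in (0, 1] (1.0 marks a miscible prediction).  ``gaps`` lists grid
    fractions at which a prediction failed to converge.
    """

    organic_fractions: tuple[float, ...]
    solubilities: tuple[float, ...]
    temperature: float
    sds: Optional[tuple[float, ...]] = None
    gaps: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        fr = tuple(float(f) for f in self.organic_fractions)
        sol = tuple(float(s) for s in self.solubilities)
        if len(fr) != len(sol):
            raise ValueError("fractions/solubilities length mismatch")
        if self.sds is not None and len(self.sds) != len(fr):
            raise ValueError("sds length mismatch")
        order = sorted(range(len(fr)), key=lambda i: fr[i])
        fr = tuple(fr[i] for i in order)
        sol = tuple(sol[i] for i in order)
        sds = None if self.sds is None else tuple(float(self.sds[i]) for i in order)
        if any(not 0.0 <= f <= 1.0 for f in fr):
            raise ValueError("organic fractions must lie in [0, 1]")
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise ValueError("organic fractions must be distinct")
        if any(not 0.0 < s <= 1.0 for s in sol):
            raise ValueError("solubilities must lie in (0, 1]")
        object.__setattr__(self, "organic_fractions", fr)
        object.__setattr__(self, "solubilities", sol)
        object.__setattr__(self, "sds", sds)

    def __len__(self) -> int:
        return len(self.organic_fractions)

    @classmethod
    def from_measurements(
        cls,
        records: Iterable[MeasurementRecord],
        solute: Optional[str] = None,
        organic: Optional[str] = None,
        temperature: Optional[float] = None,
    ) -> "SolubilityProfile":
        """Aggregate replicate measurements into a profile, optionally
        filtering by solute, organic solvent, and temperature."""
        rows = [
            r
            for r in records
            if (solute is None or r.solute == solute)
            and (organic is None or r.organic_solvent == organic)
            and (temperature is None or math.isclose(r.temperature, temperature))
        ]
        if not rows:
            raise ValueError("no measurements match the requested profile")
        temps = {r.temperature for r in rows}
        if len(temps) > 1:
            raise ValueError(f"measurements span several temperatures: {sorted(temps)}")
        return cls(
            organic_fractions=tuple(r.organic_fraction for r in rows),
            solubilities=tuple(r.mean() for r in rows),
            sds=tuple(r.sd() for r in rows),
            temperature=rows[0].temperature,
        )


@dataclass(frozen=True)
class SynergyReport:
    synergistic: bool
    argmax_fraction: float
    max_solubility: float
    endpoint_low: float  # mean at the lowest organic fraction
    endpoint_high: float  # mean at the highest organic fraction
    excess_over_best_endpoint: float  # relative, e.g. 0.12 = +12 %

    def __post_init__(self) -> None:
        if self.synergistic and self.excess_over_best_endpoint <= 0:
            raise ValueError("synergy implies positive excess over both endpoints")


def _require_interior(profile: SolubilityProfile) -> None:
    if len(profile) < 3:
        raise ValueError("need at least 3 grid points spanning an interior fraction")


def detect_synergy(profile: SolubilityProfile, rel_tol: float = 0.05) -> SynergyReport:
    """Co-solvation synergy: the maximum mean solubility sits at an interior
    fraction and exceeds both endpoint means by more than ``rel_tol``
    relative."""
    _require_interior(profile)
    sol = profile.solubilities
    i_max = max(range(len(sol)), key=sol.__getitem__)
    lo, hi = sol[0], sol[-1]
    best_endpoint = max(lo, hi)
    excess = sol[i_max] / best_endpoint - 1.0
    synergistic = 0 < i_max < len(sol) - 1 and excess > rel_tol
    return SynergyReport(
        synergistic=synergistic,
        argmax_fraction=profile.organic_fractions[i_max],
        max_solubility=sol[i_max],
        endpoint_low=lo,
        endpoint_high=hi,
        excess_over_best_endpoint=excess,
    )


def antisolvent_classification(
    profile: SolubilityProfile, rel_tol: float = 0.05
) -> ProfileClass:
    """Classify a profile.

    water-antisolvent: mean solubility non-decreasing in organic fraction,
    within one pooled replicate SD (one-sided); synergistic: per
    :func:`detect_synergy`; otherwise irregular.
    """
    _require_interior(profile)
    if profile.sds is not None and len(profile.sds) > 0:
        pooled_sd = math.sqrt(sum(s * s for s in profile.sds) / len(profile.sds))
    else:
        pooled_sd = 0.0
    sol = profile.solubilities
    if all(b >= a - pooled_sd for a, b in zip(sol, sol[1:])):
        return ProfileClass.WATER_ANTISOLVENT
    if detect_synergy(profile, rel_tol).synergistic:
        return ProfileClass.SYNERGISTIC
    return ProfileClass.IRREGULAR


def order_solvent_power(
    neat_values: Mapping[str, float | tuple[float, float]],
    tie_rel_tol: float = 0.05,
) -> list[list[str]]:
    """Order neat solvents by mean solubility, grouping near-ties.

    Values are either a mean or a (mean, sd) pair.  Adjacent solvents in the
    descending order are grouped as approximately equal when their means
    differ by less than ``tie_rel_tol`` relative to their average, or when
    both carry SDs and the ±1 SD intervals overlap.
    """
    if len(neat_values) < 2:
        raise ValueError("need at least two solvents to order")
    parsed: list[tuple[str, float, Optional[float]]] = []
    for name, v in neat_values.items():
        if isinstance(v, tuple):
            parsed.append((name, float(v[0]), float(v[1])))
        else:
            parsed.append((name, float(v), None))
    parsed.sort(key=lambda t: (-t[1], t[0]))

    groups: list[list[str]] = [[parsed[0][0]]]
    prev = parsed[0]
    for cur in parsed[1:]:
        _, m_prev, sd_prev = prev
        _, m_cur, sd_cur = cur
        denom = (abs(m_prev) + abs(m_cur)) / 2.0
        rel_close = denom > 0 and abs(m_prev - m_cur) / denom < tie_rel_tol
        sd_overlap = (
            sd_prev is not None
            and sd_cur is not None
            and (m_prev - sd_prev) <= (m_cur + sd_cur)
        )
        if rel_close or sd_overlap:
            groups[-1].append(cur[0])
        else:
            groups.append([cur[0]])
        prev = cur
    return groups


def format_ordering(groups: Sequence[Sequence[str]]) -> str:
    """Render grouped ordering as e.g. ``DMF > 4FM ≈ DMSO``."""
    return " > ".join(" ≈ ".join(g) for g in groups)
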
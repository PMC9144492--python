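"""Fusion thermodynamics: Gibbs energy of fusion and ideal solubility.

The Gibbs energy of fusion is the free-energy penalty for converting the
crystalline solute into a hypothetical supercooled liquid at temperature T.
With the heat-capacity change upon melting neglected (small for the rigid
aromatic amides this package targets),

    ΔfusG(T) = ΔHfus · (1 − T/Tm),

clamped at zero for T ≥ Tm: above the melting point the solute is already a
liquid and the penalty vanishes.  The ideal (γ = 1) saturation mole
fraction follows as  x_id = exp(−ΔfusG/(R·T)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from greensolv.catalog import SoluteRecord

#: gas constant, J mol^-1 K^-1
R = 8.31446


@dataclass(frozen=True)
class FusionState:
    """ΔfusG at a temperature, pre- and post-clamp, in kJ/mol."""

    gibbs_fusion: float
    raw_gibbs_fusion: float
    temperature: float

    def __post_init__(self) -> None:
        if self.gibbs_fusion != max(0.0, self.raw_gibbs_fusion):
            raise ValueError("gibbs_fusion must equal max(0, raw_gibbs_fusion)")


def gibbs_fusion(solute: SoluteRecord, temperature: float) -> FusionState:
    """ΔfusG(T) from melting temperature and enthalpy of fusion alone."""
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    dh_kj = solute.fusion_enthalpy_kj()
    raw = dh_kj * (1.0 - temperature / solute.melt_temp)
    return FusionState(
        gibbs_fusion=max(0.0, raw), raw_gibbs_fusion=raw, temperature=temperature
    )


def ideal_solubility(solute: SoluteRecord, temperature: float) -> float:
    """Saturation mole fraction in the ideal-solution (γ = 1) limit.

    exp(−ΔfusG/(R·T)); equals 1 at and above the melting point.
    """
    state = gibbs_fusion(solute, temperature)
    return math.exp(-state.gibbs_fusion * 1000.0 / (R * temperature))
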
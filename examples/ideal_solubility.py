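"""Ideal solubility of the three aromatic amides from fusion data.

Builds ΔfusG(T) = ΔHfus·(1 − T/Tm) for each bundled solute and prints the
ideal-solution (γ = 1) saturation mole fraction exp(−ΔfusG/RT) at the four
shake-flask temperatures.  The ideal value is the solubility every solvent
would give if it behaved ideally; real solvents move it up (favourable
interactions, γ < 1) or down (γ > 1).
"""

from greensolv import bundled_solutes, gibbs_fusion, ideal_solubility

temperatures = [298.15, 303.15, 308.15, 313.15]

print(f"{'solute':<14}{'Tm/K':>8}{'dHfus/kJ/mol':>14}", end="")
for T in temperatures:
    print(f"{'x_id(' + str(T) + ')':>16}", end="")
print()
for solute in bundled_solutes():
    print(
        f"{solute.name:<14}{solute.melt_temp:>8.1f}"
        f"{solute.fusion_enthalpy_kj():>14.1f}",
        end="",
    )
    for T in temperatures:
        print(f"{ideal_solubility(solute, T):>16.4f}", end="")
    print()

state = gibbs_fusion(bundled_solutes()[0], 298.15)
print(
    f"\nbenzamide at 298.15 K: dfusG = {state.gibbs_fusion:.3f} kJ/mol -> "
    f"ideal x = {ideal_solubility(bundled_solutes()[0], 298.15):.4f}"
)
print("Higher melting point and fusion enthalpy mean lower ideal solubility.")
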
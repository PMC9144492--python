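"""Saturation solubility in neat and mixed solvents via the fixed point.

Solves γ(x)·x = exp(−ΔfusG/RT) for benzamide under three activity models:
ideal (recovers the closed form), a binary Margules solvent with
unfavourable interactions (γ > 1 suppresses solubility), and a strongly
favourable solvent whose iterate runs to the miscibility cutoff — the
"infinite solubility" outcome that screening ranks first.
"""

from greensolv import (
    Composition,
    IdealModel,
    MargulesModel,
    NRTLModel,
    bundled_solutes,
    bundled_solvents,
    solubility_profile,
    solve_saturation,
)

benzamide = {s.name: s for s in bundled_solutes()}["benzamide"]
fourfm = {s.name: s for s in bundled_solvents()}["4FM"]
NEAT = Composition((1.0,))

for label, model in [
    ("ideal", IdealModel(2)),
    ("Margules A=+2 (unfavourable)", MargulesModel(2.0)),
    ("Margules A=-8 (very favourable)", MargulesModel(-8.0)),
]:
    res = solve_saturation(benzamide, NEAT, model, 298.15)
    x = "miscible" if res.miscible else f"{res.x_sat:.4f}"
    print(
        f"{label:<32} x_sat = {x:<10} gamma = {res.gamma_sat:6.3f} "
        f"iterations = {res.iterations}"
    )

# aqueous-binary profile: NRTL ternary (solute, water, organic) in which
# the organic is a far better partner for the solute than water
tau = [[0.0, 2.0, -1.0], [2.0, 0.0, 0.5], [-1.0, 0.5, 0.0]]
alpha = [[0.0, 0.3, 0.3], [0.3, 0.0, 0.3], [0.3, 0.3, 0.0]]
profile = solubility_profile(
    benzamide, fourfm, [0.0, 0.2, 0.4, 0.6, 0.8, 1.0], NRTLModel(tau, alpha), 298.15
)
print("\naqueous 4FM profile (x2*, x_sat):")
for f, x in zip(profile.organic_fractions, profile.solubilities):
    print(f"  {f:.1f}  {x:.4f}")
print("Monotone increase with organic fraction: water acts as antisolvent.")
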
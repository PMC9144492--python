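"""Co-solvation synergy and antisolvent classification of measured profiles.

Builds the salicylamide / aqueous-4FM room-temperature profile shape — an
interior maximum of 0.379 mole fraction at solute-free organic fraction
0.6, higher than either neat endpoint — and a typical monotone benzamide
profile, classifies both, and orders neat solvents by solubilizing power
with the approximately-equal grouping.
"""

from greensolv import (
    SolubilityProfile,
    antisolvent_classification,
    detect_synergy,
    format_ordering,
    order_solvent_power,
)

grid = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

salicylamide_4fm = SolubilityProfile(
    grid, (0.004, 0.05, 0.20, 0.379, 0.34, 0.31), temperature=298.15
)
rep = detect_synergy(salicylamide_4fm)
print(
    f"salicylamide/4FM: synergistic={rep.synergistic} at x2*="
    f"{rep.argmax_fraction} (x_max={rep.max_solubility:.3f}, "
    f"+{100 * rep.excess_over_best_endpoint:.0f}% over the best neat endpoint)"
)
print("classification:", antisolvent_classification(salicylamide_4fm).value)

benzamide_dmf = SolubilityProfile(
    grid, (0.002, 0.01, 0.04, 0.09, 0.14, 0.20), temperature=298.15
)
print(
    "benzamide/DMF:    classification:",
    antisolvent_classification(benzamide_dmf).value,
    "(adding water only ever lowers solubility)",
)

# neat solubilizing power, with near-ties grouped
print(
    "ethenzamide-like ordering: ",
    format_ordering(order_solvent_power({"DMF": 0.30, "4FM": 0.21, "DMSO": 0.20})),
)
print(
    "benzamide-like ordering:   ",
    format_ordering(order_solvent_power({"DMF": 0.30, "DMSO": 0.20, "4FM": 0.10})),
)
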
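"""Environmental-index ranking of the aqueous DMSO / DMF / 4FM systems.

Sums the bundled per-component environmental scores into neat EI totals,
combines each organic with water (EI 0.02) by mass-fraction weighting over
the composition grid x2* in {0.2, 0.4, 0.6, 0.8, 1.0}, and ranks all
sixteen systems ascending (lower EI = greener) twice: with the default
weighting and with the photochemical-oxidation (PCOP) term excluded —
the variant that rehabilitates low-volatility DMSO.
"""

from greensolv import aqueous_grid_systems, bundled_solvents, rank_systems

solvents = {s.name: s for s in bundled_solvents()}
organics = [solvents[n] for n in ("DMSO", "DMF", "4FM")]

ranked = rank_systems(aqueous_grid_systems(organics))
print(f"{'system':<12}{'x2*':>6}{'EI':>9}{'EI(-PCOP)':>11}{'rank':>6}{'rank(-PCOP)':>13}")
for e in ranked:
    x2 = "-" if e.organic_fraction is None else f"{e.organic_fraction:.1f}"
    print(
        f"{e.label:<12}{x2:>6}{e.ei_default:>9.2f}{e.ei_no_pcop:>11.2f}"
        f"{e.rank_default:>6}{e.rank_no_pcop:>13}"
    )

print(
    "\nWith all components, dilute aqueous 4FM (x2*=0.2) is the greenest "
    "solvent system after water; without PCOP, dilute aqueous DMSO takes "
    "that spot."
)
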
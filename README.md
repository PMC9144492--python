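# greensolv

A Python toolkit for screening efficient **and** environmentally friendly
solvents for crystalline organic solutes — built around the workflow used to
evaluate 4-formylmorpholine (4FM) as a green alternative to DMF and DMSO for
the aromatic amides benzamide, salicylamide and ethenzamide. It is aimed at
formulation and crystallization scientists who want to shortlist solvents
computationally before running shake-flask experiments.

## What it computes

**Solid–liquid equilibrium solubility.** At saturation the solute activity
balances the solid's chemical potential referenced to the supercooled liquid:

```
γ(x_sat) · x_sat = exp( −max(0, Δ_fus G) / (R·T) ),
Δ_fus G = Δ_fus H · (1 − T / T_m)
```

with the heat-capacity term neglected. `greensolv` solves this by a damped
fixed-point iteration in ln x, with the solvent components held at their
solute-free ratio. γ comes from a pluggable activity model (ideal, binary or
pairwise Margules, multicomponent NRTL); γ = 1 gives the ideal solubility
`exp(−Δ_fus G/RT)` in closed form. Iterates that run to the pure-liquid limit
are reported as *miscible* ("infinite solubility") and rank first in
screening.

**Environmental index (EI).** Each solvent carries eight impact scores
(HTPIng, HTPInh, TTP, ATP, GWP, ODP, PCOP, AR); their sum is the EI, lower is
greener, water anchors the scale at 0.02. Aqueous binaries are scored by
mass-fraction-weighted averaging of the neat EI with water's. A PCOP-excluded
variant is carried alongside the default, since photochemical smog formation
is largely irrelevant for low-volatility solvents such as DMSO.

**Screening cascade.** availability → EI < 2 (strict) → predicted
log₁₀ x_sat ranking → better-than-reference flag (default reference:
methanol).

**Mixture analysis.** Classifies solubility-vs-composition profiles in
water–organic binaries as *water-antisolvent* (monotone within replicate
noise), *synergistic* (interior maximum exceeding both neat endpoints by >5 %
relative — the co-solvation effect), or *irregular*; and orders neat solvents
by solubilizing power with an explicit `≈` grouping for near-ties.

**Synthetic data.** Seeded generators for PARIS-III-style solvent catalogs
(with planted known-good solvents for ground-truth tests) and triplicate
shake-flask measurements with multiplicative log-normal noise.

## Worked example

```python
from greensolv import (bundled_solutes, bundled_solvents, Composition,
                       MargulesModel, solve_saturation,
                       aqueous_grid_systems, rank_systems)

benzamide = {s.name: s for s in bundled_solutes()}["benzamide"]
res = solve_saturation(benzamide, Composition((1.0,)), MargulesModel(2.0), 298.15)
print(res.x_sat, res.gamma_sat)
```

prints `0.016631909860759582 6.917236237052512` — in a solvent with strongly
unfavourable interactions (Margules A = 2, γ ≈ 6.9 at saturation) benzamide's
solubility drops from the ideal 0.1150 to 0.0166 mole fraction. The product
γ·x equals the activity target 0.11505 to 1e-10.

```python
solvents = {s.name: s for s in bundled_solvents()}
ranked = rank_systems(aqueous_grid_systems([solvents[n] for n in ("DMSO", "DMF", "4FM")]))
for e in ranked[:3]:
    print(e.label, e.organic_fraction, round(e.ei_default, 2), e.rank_default)
```

```
water None 0.02 1
DMSO 0.2 6.07 12
DMSO 0.4 8.67 13
```

Ranking all sixteen systems puts dilute aqueous 4FM (x₂\* = 0.2, EI 0.32) at
rank 2 behind water under the default weighting, while the PCOP-excluded
variant puts dilute aqueous DMSO (EI 0.14) there instead — the two headline
orderings of the green-solvent analysis. The `examples/` directory has five
narrative scripts (ideal solubility, EI table, saturation solver, screening
cascade, mixture synergy), each printing and explaining its numbers.

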
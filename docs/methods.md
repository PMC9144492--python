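# Methods

## Solid–liquid equilibrium model

A solute dissolving from a crystal must first pay the free-energy cost of
melting into a hypothetical supercooled liquid. With the heat-capacity
change on melting neglected — a good approximation for rigid aromatic
amides near room temperature — that cost is

    Δ_fus G(T) = Δ_fus H · (1 − T / T_m),   clamped at max(0, ·),

so only the melting temperature T_m and the enthalpy of fusion Δ_fus H are
needed. The saturation condition equates solute activity with the solid's
reference activity:

    γ(x_sat) · x_sat = a_sat = exp(−Δ_fus G / (R·T)),   R = 8.31446 J·mol⁻¹·K⁻¹.

All internal energies are kJ/mol and temperatures kelvin; enthalpies tagged
kcal/mol are converted by the exact factor 4.184 at the record boundary.

The bundled solute constants (benzamide T_m = 401.0 K, Δ_fus H = 20.9;
salicylamide 412.3 K, 28.4; ethenzamide 405.0 K, 20.4) are declared kJ/mol.
The literature compilation they derive from prints the same magnitudes as
kcal/mol, but that reading would put benzamide's ideal solubility near
e⁻⁹ ≈ 1e−4, two orders below its measured solubility in methanol (0.092),
whereas the kJ/mol reading gives the plausible 0.115. Loaders preserve
whatever tag a file declares; the bundled fixtures' choice is logged once at
load so the ambiguity is visible, never silent.

## The fixed-point solver

The update iterates in log space with damping d (default 0.5):

    ln x_{k+1} = (1 − d)·ln x_k + d·[ln a_sat − ln γ_solute(x_k)],

starting from the ideal solubility x₀ = a_sat (one-step convergence when
γ ≈ 1), with the solvent components renormalised to their solute-free ratio
against the current solute fraction each step. Convergence is |Δ ln x| <
1e−10 (so the residual |γx − a| is below ~2e−10·a, comfortably inside the
1e−8 contract), capped at 500 iterations; non-convergence returns a result
flagged `converged=False` rather than raising. An iterate reaching the
miscibility cutoff 0.9999 is reported as miscible with x_sat = 1 — the
"infinite solubility" outcome that thermodynamic screening tools produce for
very favourable solvents. The cutoff is a declared convention, not a
physical threshold; screening treats miscible predictions as ranking above
every finite value. Correctness is checked against an independent bisection
oracle (Brent root-finding on ln γ(x) + ln x − ln a) over seeded random
Margules and NRTL binaries.

Margules parameters are kept below A = 2 in the randomized oracle tests:
at A ≥ 2 the activity x·exp(A(1−x)²) loses monotonicity (incipient phase
split) and the saturation root is no longer unique, which is a property of
the model, not of the solver.

Profile containers accept solubilities in (0, 1], the closed top allowing
miscible grid points to be carried; fractions are sorted on construction so
classification is independent of input order.

## Activity models

The solver is agnostic to where γ comes from; the package bundles

* **ideal** — ln γ ≡ 0;
* **binary Margules** — ln γ₁ = A·x₂², the one-parameter workhorse;
* **pairwise Margules** — G^E/RT = Σ_{i<j} A_ij·x_i·x_j for any n, giving
  ln γ_k = Σ_j A_kj x_j − G^E/RT;
* **NRTL** — the standard multicomponent expression with user-supplied τ
  and α tables; temperature dependence enters only through the tables.

Engines used in quantum-chemistry-based screening workflows (COSMO-RS and
kin) are deliberately *not* reimplemented: their parameterizations are
proprietary and not reproducible from published material. The contract
(`ActivityModel.ln_gamma`) is the seam where such an engine would plug in.
Because every bundled model derives from an explicit G^E, Gibbs–Duhem
consistency holds by construction and is verified numerically in tests.

The pairwise Margules model doubles as the synergy construction: a strongly
positive water–organic parameter makes the solute's γ dip at an interior
composition (the cross term A_sw + A_so − A_wo turns negative), which is the
thermodynamic signature of co-solvation.

## Environmental index

The EI of a neat solvent is the plain sum of its eight raw component scores;
the printed tables display HTPIng ×10 and ATP ×10⁵, and the CSV loader
de-scales columns whose headers declare `_x10`/`_x1e5`. The "default impact
factor" of the source tool is treated as already folded into the printed
scores. A PCOP-excluded variant is computed alongside, motivated by the
negligible atmospheric exposure of low-volatility solvents.

Aqueous mixtures are scored by mass-fraction weighting:
w = x·M_org/(x·M_org + (1−x)·M_water), EI_mix = w·EI_neat + (1−w)·0.02.
This rule was selected by validation against the full printed mixture table
(worst absolute deviation ≈ 0.03, at the high-EI DMSO rows, consistent with
2-decimal rounding); mole-fraction weighting misses the dilute DMSO row by
over 3 EI units and volume-fraction weighting requires densities the tables
do not print. Water's component-level breakdown is unpublished, so mixing
operates on EI totals, not per component — with the side effect that the
reproduced table carries small residuals where the source's unrounded
components differed from the printed ones (its neat-DMSO components sum to
11.66 against a printed total of 11.70).

Ranking sorts ascending EI, ranks 1..N, ties broken lexicographically and
flagged; the default and no-PCOP variants are ranked independently.

## Screening cascade

Stages: (1) keep `available=True`; (2) keep EI strictly below `ei_max`
(default 2.0 — a solvent at exactly the threshold is excluded); (3) solve
for each survivor's saturation solubility and rank descending, miscible
first. Each entry is flagged against a reference solvent (default methanol)
on *predicted* log₁₀ x — screening runs before any measurement exists, so
the comparison is made in computed-solubility space by design. Solvents
lacking EI components or an activity model are excluded with a logged
warning and separate counts, keeping the stage counts auditable.

## Mixture classification

* **Synergy**: the maximum mean solubility sits at an interior grid fraction
  and exceeds both endpoint means by more than 5 % relative (the tolerance
  is a parameter; the source analyses report only a qualitative
  "significant" effect, and 5 % is robust at the triplicate noise scale).
* **Water-antisolvent**: mean solubility non-decreasing in organic fraction,
  with a one-sided allowance of one pooled replicate SD so that noise-scale
  dips do not break monotonicity.
* **Irregular**: neither.

Neat-solvent power ordering groups adjacent solvents as `≈` when their means
differ by under 5 % relative or their ±1 SD intervals overlap — enough to
reproduce both the strict DMF > DMSO > 4FM and the grouped DMF > 4FM ≈ DMSO
patterns without inventing a significance test the underlying triplicate
data cannot support.

## Synthetic data

The catalog generator emulates an EPA/PARIS-III-style list: per-component
scores log-normal (heavy right tail, so EI spans orders of magnitude and a
minority clears EI < 2; ATP on its natural 1e−5 scale), availability
Bernoulli(0.7), molar masses uniform on 18–200 g/mol. "Planted" solvents
are forced to pass all three screening criteria: available, components
rescaled to an EI total uniform on (0.1, 1.9), and a binary Margules
A ~ U(−3, −1) so predicted solubility exceeds an ideal-solution reference;
non-planted solvents draw A ~ U(0.3, 3), keeping them strictly below it.
One integer seed drives everything.

The measurement generator emulates triplicate shake-flask assays over the
study's grid (organic fractions {0, 0.2, …, 1.0}; temperatures
298.15–313.15 K): replicate = true solubility × exp(ε), ε ~ N(0, cv), with
cv = 0.03 as the default noise scale (the source reports SD bars, n = 3,
without magnitudes; 3 % is typical of spectrophotometric assays).
Multiplicative noise keeps replicates positive and matches relative-error
behaviour. cv = 0 reproduces the model exactly, which the tests use as the
noise-free oracle.

What the generators do *not* emulate: real EI component correlations across
solvents, temperature-dependent activity parameters, solid-form changes
(solvates/polymorphs), or assay calibration drift. Passing the recovery
tests therefore shows the pipeline is correct and invertible under its own
stated noise model, not that any real catalog will behave as cleanly.

## Problem sizes and numerical choices

Tests run the solver oracle on 50 seeded random binaries, screening on a
200-solvent catalog with 40 planted passers (seed 42), and synergy recovery
on 200 seeded noisy repetitions of a 6-point profile; the whole suite
completes in seconds. Grid-search inversion of the Margules parameter scans
A ∈ [−4, 4] in steps of 0.01 on log-error of mean solubilities across the
four study temperatures. Degenerate inputs are defined, not special-cased:
empty catalogs yield empty reports with zero counts, empty grids yield empty
profiles, and profiles need at least three points spanning an interior
fraction before classification is attempted.

## Known limitations

* Predicted absolute solubilities are only as good as the supplied activity
  model; no bundled parameterization claims quantitative accuracy for real
  solvent–amide pairs.
* EI mixing on totals (not components) is an approximation forced by the
  unpublished water breakdown.
* The miscibility cutoff conflates "very high solubility" with true
  miscibility; downstream consumers see only the flag.
* Fusion constants are inputs; nothing is estimated from structure.
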
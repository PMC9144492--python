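"""Fixed-point solution of the saturation (solid-liquid equilibrium) equation.

At saturation the solute activity equals the activity of the pure solid
referenced to the supercooled liquid:

    γ(x_sat) · x_sat = a_sat = exp(−max(0, ΔfusG)/(R·T)).

The solver iterates the damped fixed point in ln x,

    ln x_{k+1} = (1 − d)·ln x_k + d·[ln a_sat − ln γ_solute(x_k)],

with the solvent components held at their solute-free ratio and
renormalised against the current solute fraction each step.  γ = 1
recovers the ideal closed form in one step; damping (default 0.5)
stabilises strongly non-ideal γ.  An iterate running up to the miscibility
cutoff (default 0.9999) is reported as "infinite solubility" (miscible,
x_sat = 1) rather than an error — such systems rank first in screening.

Component convention: the activity model covers the solute at index 0
followed by the solvent components in the order of the solute-free
composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from greensolv.activity import ActivityModel, Composition
from greensolv.catalog import SoluteRecord, SolventRecord
from greensolv.fusion import R, gibbs_fusion
from greensolv.mixtures import SolubilityProfile

#: sentinel for a miscible ("infinite solubility") prediction on the
#: log10 scale; sorts above every finite value.
MISCIBLE = math.inf


@dataclass(frozen=True)
class SolverOptions:
    tol: float = 1e-10  # on |Δ ln x|
    max_iter: int = 500
    damping: float = 0.5
    miscibility_cutoff: float = 0.9999

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not 0 < self.damping <= 1:
            raise ValueError("damping must lie in (0, 1]")
        if not 0 < self.miscibility_cutoff < 1:
            raise ValueError("miscibility cutoff must lie in (0, 1)")


@dataclass(frozen=True)
class SolubilityResult:
    x_sat: float
    gamma_sat: float
    activity_target: float
    iterations: int
    converged: bool
    miscible: bool

    def log10_x(self) -> float:
        return MISCIBLE if self.miscible else math.log10(self.x_sat)


def _full_composition(
    x_solute: float, solvent_ratio: Sequence[float]
) -> Composition:
    rest = 1.0 - x_solute
    return Composition((x_solute, *(rest * s for s in solvent_ratio)))


def solve_saturation(
    solute: SoluteRecord,
    solvent_composition: Composition,
    model: ActivityModel,
    temperature: float,
    options: SolverOptions = SolverOptions(),
) -> SolubilityResult:
    """Solve γ(x)·x = exp(−ΔfusG/RT) for the saturation mole fraction.

    ``solvent_composition`` is solute-free; the model must cover
    1 + len(solvent_composition) components with the solute first.
    Non-convergence within ``max_iter`` yields ``converged=False`` (no
    exception); reaching the miscibility cutoff yields ``miscible=True``
    and ``x_sat = 1.0``.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    n_expected = 1 + len(solvent_composition)
    if model.n_components != n_expected:
        raise ValueError(
            f"model covers {model.n_components} components; solute + solvent "
            f"composition needs {n_expected}"
        )
    ratio = solvent_composition.fractions
    dfus = gibbs_fusion(solute, temperature).gibbs_fusion  # kJ/mol, clamped
    a_target = math.exp(-dfus * 1000.0 / (R * temperature))
    ln_a = math.log(a_target)
    d = options.damping
    cutoff = options.miscibility_cutoff

    ln_x = math.log(min(a_target, cutoff))  # start at the ideal solubility
    ln_gam = 0.0
    converged = False
    miscible = False
    it = 0
    for it in range(1, options.max_iter + 1):
        x = math.exp(ln_x)
        if x >= cutoff:
            miscible = True
            converged = True
            break
        comp = _full_composition(x, ratio)
        ln_gam = float(model.ln_gamma(comp, temperature)[0])
        if not math.isfinite(ln_gam):
            raise ValueError(f"activity model returned non-finite ln gamma at x={x}")
        ln_x_new = (1.0 - d) * ln_x + d * (ln_a - ln_gam)
        step = abs(ln_x_new - ln_x)
        ln_x = ln_x_new
        if math.exp(ln_x) >= cutoff:
            miscible = True
            converged = True
            break
        if step < options.tol:
            converged = True
            break

    x_final = 1.0 if miscible else math.exp(ln_x)
    if not miscible:
        ln_gam = float(
            model.ln_gamma(_full_composition(x_final, ratio), temperature)[0]
        )
    return SolubilityResult(
        x_sat=x_final,
        gamma_sat=math.exp(ln_gam),
        activity_target=a_target,
        iterations=it,
        converged=converged,
        miscible=miscible,
    )


def solubility_profile(
    solute: SoluteRecord,
    organic: SolventRecord,
    grid: Sequence[float],
    model: ActivityModel,
    temperature: float,
    options: SolverOptions = SolverOptions(),
) -> SolubilityProfile:
    """Predicted solubility across a water-organic grid of solute-free
    organic fractions.

    The model must be ternary, components ordered (solute, water, organic).
    Grid points that fail to converge are recorded in ``profile.gaps``
    rather than aborting the profile.
    """
    fractions: list[float] = []
    sols: list[float] = []
    gaps: list[float] = []
    for f in grid:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"grid fraction {f} outside [0, 1]")
        res = solve_saturation(
            solute, Composition((1.0 - f, f)), model, temperature, options
        )
        if res.converged:
            fractions.append(f)
            sols.append(res.x_sat)
        else:
            gaps.append(f)
    return SolubilityProfile(
        organic_fractions=tuple(fractions),
        solubilities=tuple(sols),
        temperature=temperature,
        gaps=tuple(gaps),
    )


def predicted_log_solubility(
    solute: SoluteRecord,
    solvent: SolventRecord,
    model: ActivityModel,
    temperature: float,
    options: SolverOptions = SolverOptions(),
) -> float:
    """log10 saturation mole fraction in the neat solvent; ``math.inf``
    (the MISCIBLE sentinel, ranking above all finite values) when the
    prediction is miscible."""
    res = solve_saturation(
        solute, Composition((1.0,)), model, temperature, options
    )
    if not res.converged:
        raise RuntimeError(
            f"saturation solve did not converge for {solute.name} in {solvent.name}"
        )
    return res.log10_x()
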
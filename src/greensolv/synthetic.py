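"""Seeded synthetic data: solvent catalogs and noisy shake-flask profiles.

The catalog generator emulates the structure of an EPA/PARIS-III-style
solvent list: per-component environmental scores drawn log-normally (so EI
totals span orders of magnitude with a heavy right tail), a commercial-
availability flag, and molar masses on the common organic-solvent range.
A requested number of "planted" solvents is forced to satisfy all three
screening criteria by construction — available, EI total below 2, and a
favourable (negative) Margules parameter so the predicted solubility
exceeds an ideal-solution reference — giving screening tests a known
ground truth.

The measurement generator emulates triplicate shake-flask assays:
replicates are the model-true solubility times exp(ε) with ε ~ N(0, cv),
i.e. multiplicative log-normal noise, which keeps replicates positive and
matches the relative-error behaviour of spectrophotometric concentration
assays.  All randomness flows from one integer seed per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from greensolv.activity import ActivityModel, Composition, MargulesModel
from greensolv.catalog import (
    EI_FIELDS,
    EIComponents,
    MeasurementRecord,
    SoluteRecord,
    SolventRecord,
)
from greensolv.solver import SolverOptions, solve_saturation

#: log-space (mu, sigma) per EI component; ATP sits on its natural 1e-5
#: scale, the rest around a median of ~0.4 with a heavy tail so that a
#: realistic minority of solvents clears the EI < 2 screen.
DEFAULT_EI_LOGNORMAL: dict[str, tuple[float, float]] = {
    **{f: (-1.0, 1.5) for f in EI_FIELDS},
    "atp": (-9.0, 1.5),
}


@dataclass(frozen=True)
class CatalogSpec:
    n_solvents: int
    planted_good: int = 0
    availability_prob: float = 0.7
    ei_lognormal: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EI_LOGNORMAL)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_solvents < 0 or self.planted_good < 0:
            raise ValueError("counts must be nonnegative")
        if self.planted_good > self.n_solvents:
            raise ValueError("planted_good cannot exceed n_solvents")
        if not 0.0 <= self.availability_prob <= 1.0:
            raise ValueError("availability_prob must lie in [0, 1]")


@dataclass(frozen=True)
class CatalogTruth:
    """Ground truth behind a generated catalog: the planted solvent names
    and the per-solvent binary Margules parameter."""

    planted: frozenset[str]
    margules_a: dict[str, float]


@dataclass(frozen=True)
class NoiseSpec:
    replicates: int = 3
    cv: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")


def generate_solvent_catalog(
    spec: CatalogSpec, return_truth: bool = False
) -> list[SolventRecord] | tuple[list[SolventRecord], CatalogTruth]:
    """Generate a deterministic synthetic solvent catalog.

    Planted solvents are available, have their EI components rescaled to a
    total uniform on (0.1, 1.9), and carry a Margules A uniform on
    (−3, −1); the rest draw availability Bernoulli(availability_prob),
    unscaled log-normal components, and A uniform on (0.3, 3).  With
    ``return_truth=True`` the planted names and A table are returned too.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_solvents
    planted_idx = set(
        rng.choice(n, size=spec.planted_good, replace=False).tolist()
    ) if spec.planted_good else set()

    records: list[SolventRecord] = []
    margules_a: dict[str, float] = {}
    planted_names: list[str] = []
    for i in range(n):
        name = f"sol-{i:04d}"
        molar_mass = float(rng.uniform(18.0, 200.0))
        comps = {
            f: float(rng.lognormal(*spec.ei_lognormal[f])) for f in EI_FIELDS
        }
        is_planted = i in planted_idx
        if is_planted:
            target = float(rng.uniform(0.1, 1.9))
            total = sum(comps.values())
            comps = {f: v * target / total for f, v in comps.items()}
            available = True
            a_param = float(rng.uniform(-3.0, -1.0))
            planted_names.append(name)
        else:
            available = bool(rng.random() < spec.availability_prob)
            a_param = float(rng.uniform(0.3, 3.0))
        records.append(
            SolventRecord(
                name=name,
                cas=f"{i:06d}-00-0",
                molar_mass=molar_mass,
                available=available,
                ei=EIComponents(**comps),
            )
        )
        margules_a[name] = a_param

    if not return_truth:
        return records
    return records, CatalogTruth(
        planted=frozenset(planted_names), margules_a=margules_a
    )


def generate_measured_profiles(
    solute: SoluteRecord,
    organic: SolventRecord,
    grid: Sequence[float],
    true_model: ActivityModel,
    temperatures: Sequence[float],
    noise: NoiseSpec = NoiseSpec(),
    options: SolverOptions = SolverOptions(),
) -> list[MeasurementRecord]:
    """Simulate replicate shake-flask measurements over a composition grid.

    ``true_model`` is ternary (solute, water, organic) for a composition
    grid, or binary (solute, organic) when the grid is neat-only
    (all fractions 1).  Each replicate is the solver-true solubility times
    exp(ε), ε ~ N(0, cv); cv = 0 reproduces the model exactly.
    """
    binary = true_model.n_components == 2
    if binary and any(f != 1.0 for f in grid):
        raise ValueError("a binary model supports only the neat grid point x2*=1")
    rng = np.random.default_rng(noise.seed)
    records: list[MeasurementRecord] = []
    for T in temperatures:
        for f in grid:
            solvent = Composition((1.0,)) if binary else Composition((1.0 - f, f))
            res = solve_saturation(solute, solvent, true_model, T, options)
            if not res.converged:
                raise RuntimeError(
                    f"true-model solve failed at x2*={f}, T={T}"
                )
            x_true = res.x_sat
            if noise.cv == 0.0:
                reps = tuple([min(x_true, 1.0 - 1e-12)] * noise.replicates)
            else:
                eps = rng.normal(0.0, noise.cv, size=noise.replicates)
                reps = tuple(
                    min(float(x_true * math.exp(e)), 1.0 - 1e-12) for e in eps
                )
            records.append(
                MeasurementRecord(
                    solute=solute.name,
                    organic_solvent=organic.name,
                    organic_fraction=f,
                    temperature=T,
                    replicate_solubilities=reps,
                )
            )
    return records


def recover_margules_parameter(
    records: Sequence[MeasurementRecord],
    solute: SoluteRecord,
    a_grid: Optional[Sequence[float]] = None,
    options: SolverOptions = SolverOptions(),
) -> float:
    """Invert neat-solvent measurements for the binary Margules A by grid
    search, minimising the summed squared log-error of the mean replicate
    solubility against the model prediction.

    Only neat-solvent records (organic_fraction = 1) are used.
    """
    neat = [r for r in records if r.organic_fraction == 1.0]
    if not neat:
        raise ValueError("need neat-solvent (organic_fraction = 1) records")
    if a_grid is None:
        a_grid = np.arange(-4.0, 4.001, 0.01)

    def sse(a: float) -> float:
        model = MargulesModel(a)
        total = 0.0
        for r in neat:
            res = solve_saturation(
                solute, Composition((1.0,)), model, r.temperature, options
            )
            if res.miscible or not res.converged:
                return math.inf
            total += (math.log(r.mean()) - math.log(res.x_sat)) ** 2
        return total

    return float(min(a_grid, key=sse))
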
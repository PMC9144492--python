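"""The green-solvent screening cascade.

Stage 1 keeps commercially available solvents; stage 2 keeps those with
environmental index strictly below a threshold (default EI < 2, a tight
"greenness" criterion); stage 3 predicts the saturation solubility of the
target solute in each survivor and ranks descending, miscible ("infinite
solubility") predictions first.  Each survivor is finally flagged as
better or worse than a reference solvent (default methanol, the best
previously known solubilizer for benzamide) on predicted log10 solubility.

Solvents lacking EI components or an activity model are excluded with a
logged warning and counted separately, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from math import isinf
from typing import Callable, Iterable, Optional, Sequence

from greensolv.activity import ActivityModel
from greensolv.catalog import SoluteRecord, SolventRecord
from greensolv.green_index import ei_aqueous_mixture, ei_total
from greensolv.mixtures import SolubilityProfile
from greensolv.solver import SolverOptions, predicted_log_solubility, solubility_profile

logger = logging.getLogger(__name__)

#: returns a model for (solute + that solvent); None to skip the solvent
ModelProvider = Callable[[SolventRecord], Optional[ActivityModel]]


@dataclass(frozen=True)
class ScreeningConfig:
    ei_max: float = 2.0
    temperature: float = 298.15
    reference_solvent: str = "methanol"
    include_pcop: bool = True
    reference_log_solubility: Optional[float] = None
    solver_options: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self) -> None:
        if self.ei_max <= 0:
            raise ValueError("ei_max must be positive")


@dataclass(frozen=True)
class ShortlistEntry:
    solvent: str
    ei: float
    log10_x: float  # math.inf marks a miscible prediction
    miscible: bool
    better_than_reference: bool

    def display_solubility(self) -> str:
        return "miscible" if self.miscible else f"{self.log10_x:.3f}"


@dataclass(frozen=True)
class ScreeningReport:
    counts: dict[str, int]
    shortlist: tuple[ShortlistEntry, ...]
    reference_solvent: str
    reference_log_solubility: float

    def better_set(self) -> set[str]:
        return {e.solvent for e in self.shortlist if e.better_than_reference}


def _reference_log_x(
    catalog: Sequence[SolventRecord],
    solute: SoluteRecord,
    model_provider: ModelProvider,
    config: ScreeningConfig,
) -> float:
    if config.reference_log_solubility is not None:
        return config.reference_log_solubility
    ref = next((r for r in catalog if r.name == config.reference_solvent), None)
    if ref is None:
        raise ValueError(
            f"reference solvent {config.reference_solvent!r} not in catalog and no "
            "reference_log_solubility supplied"
        )
    model = model_provider(ref)
    if model is None:
        raise ValueError(f"no activity model for reference {ref.name!r}")
    return predicted_log_solubility(
        solute, ref, model, config.temperature, config.solver_options
    )


def screen_catalog(
    catalog: Sequence[SolventRecord],
    solute: SoluteRecord,
    model_provider: ModelProvider,
    config: ScreeningConfig = ScreeningConfig(),
) -> ScreeningReport:
    """Run the availability → EI → predicted-solubility cascade."""
    counts = {
        "input": len(catalog),
        "available": 0,
        "ei_pass": 0,
        "scored": 0,
        "skipped_no_ei": 0,
        "skipped_no_model": 0,
    }
    if not catalog:
        return ScreeningReport(counts, (), config.reference_solvent, float("nan"))

    available = [r for r in catalog if r.available]
    counts["available"] = len(available)

    ei_pass: list[tuple[SolventRecord, float]] = []
    for r in available:
        if r.ei is None:
            logger.warning("solvent %r lacks EI components; excluded", r.name)
            counts["skipped_no_ei"] += 1
            continue
        ei = ei_total(r.ei, config.include_pcop)
        if ei < config.ei_max:  # strictly below the threshold
            ei_pass.append((r, ei))
    counts["ei_pass"] = len(ei_pass)

    ref_log_x = _reference_log_x(catalog, solute, model_provider, config)

    entries: list[ShortlistEntry] = []
    for r, ei in ei_pass:
        model = model_provider(r)
        if model is None:
            logger.warning("solvent %r lacks an activity model; excluded", r.name)
            counts["skipped_no_model"] += 1
            continue
        log_x = predicted_log_solubility(
            solute, r, model, config.temperature, config.solver_options
        )
        entries.append(
            ShortlistEntry(
                solvent=r.name,
                ei=ei,
                log10_x=log_x,
                miscible=isinf(log_x),
                better_than_reference=log_x > ref_log_x,
            )
        )
    counts["scored"] = len(entries)
    entries.sort(key=lambda e: (-e.log10_x, e.solvent))
    return ScreeningReport(
        counts=counts,
        shortlist=tuple(entries),
        reference_solvent=config.reference_solvent,
        reference_log_solubility=ref_log_x,
    )


@dataclass(frozen=True)
class BinaryGridResult:
    """A predicted water-organic solubility profile coupled with the
    mixture EI at each converged grid fraction."""

    solvent: str
    profile: SolubilityProfile
    ei: tuple[float, ...]


def shortlist_binary_grids(
    shortlist: Sequence[SolventRecord],
    solute: SoluteRecord,
    grid: Sequence[float],
    model_provider: ModelProvider,
    config: ScreeningConfig = ScreeningConfig(),
) -> dict[str, BinaryGridResult]:
    """For each shortlisted solvent, predict the aqueous-binary solubility
    profile over ``grid`` and pair every point with the mixture EI at the
    same solute-free fraction.

    ``model_provider`` must here return a ternary model with components
    (solute, water, organic).  Per-solvent failures are logged; the other
    solvents proceed.
    """
    if not shortlist:
        raise ValueError("shortlist must be nonempty")
    out: dict[str, BinaryGridResult] = {}
    for rec in shortlist:
        model = model_provider(rec)
        if model is None:
            logger.warning("solvent %r lacks a ternary model; skipped", rec.name)
            continue
        try:
            profile = solubility_profile(
                solute, rec, grid, model, config.temperature, config.solver_options
            )
            ei = tuple(
                ei_aqueous_mixture(rec, f, include_pcop=config.include_pcop)
                for f in profile.organic_fractions
            )
        except Exception:
            logger.warning("binary grid failed for %r; skipped", rec.name, exc_info=True)
            continue
        out[rec.name] = BinaryGridResult(solvent=rec.name, profile=profile, ei=ei)
    return out
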
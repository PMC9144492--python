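"""Pluggable activity-coefficient models.

The saturation solver needs only ln γ for the solute at a trial
composition; any engine satisfying :class:`ActivityModel` plugs in.  The
reference state is the pure liquid, so ln γ_i → 0 as x_i → 1 for every
model.  Bundled engines:

* ideal — ln γ = 0 everywhere;
* two-suffix Margules, binary (single parameter A) and its pairwise
  multicomponent generalisation G^E/RT = Σ_{i<j} A_ij x_i x_j;
* multicomponent NRTL with user-supplied τ and α tables.

All engines derive from an explicit excess Gibbs energy, so Gibbs–Duhem
consistency holds by construction.
"""

from __future__ import annotations

import json
from abc import ABC, abstractmethod
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Composition",
    "ActivityModel",
    "IdealModel",
    "MargulesModel",
    "PairwiseMargulesModel",
    "NRTLModel",
    "ln_gamma_ideal",
    "ln_gamma_margules",
    "ln_gamma_nrtl",
    "model_from_dict",
    "model_from_json",
]

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class Composition:
    """Mole fractions of an n-component mixture; must sum to 1."""

    fractions: tuple[float, ...]
    names: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        x = np.asarray(self.fractions, dtype=float)
        if x.ndim != 1 or len(x) < 1:
            raise ValueError("composition needs at least one component")
        if np.any(x < -_SUM_TOL) or np.any(x > 1 + _SUM_TOL):
            raise ValueError("mole fractions must lie in [0, 1]")
        if abs(float(x.sum()) - 1.0) > 1e-9:
            raise ValueError(f"mole fractions must sum to 1 (got {x.sum()!r})")
        if self.names is not None and len(self.names) != len(x):
            raise ValueError("names/fractions length mismatch")
        object.__setattr__(self, "fractions", tuple(float(v) for v in x))

    def __len__(self) -> int:
        return len(self.fractions)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.fractions, dtype=float)


class ActivityModel(ABC):
    """Contract: finite ln γ at interior compositions, zero in the
    pure-component limit."""

    name: str = "activity-model"

    @property
    @abstractmethod
    def n_components(self) -> int: ...

    @abstractmethod
    def ln_gamma(self, composition: Composition, temperature: float) -> np.ndarray:
        """Per-component ln γ at the given composition and temperature (K)."""

    def _check(self, composition: Composition) -> np.ndarray:
        if len(composition) != self.n_components:
            raise ValueError(
                f"{self.name} expects {self.n_components} components, "
                f"got {len(composition)}"
            )
        return composition.as_array()


# ---------------------------------------------------------------------------
# functional forms


def ln_gamma_ideal(composition: Composition, temperature: float = 298.15) -> np.ndarray:
    """Ideal solution: all ln γ are zero."""
    return np.zeros(len(composition))


def ln_gamma_margules(
    A: float, composition: Composition, temperature: float = 298.15
) -> np.ndarray:
    """Binary two-suffix Margules: ln γ1 = A x2², ln γ2 = A x1²."""
    if len(composition) != 2:
        raise ValueError("Margules model is strictly binary")
    x1, x2 = composition.fractions
    return np.array([A * x2 * x2, A * x1 * x1])


def ln_gamma_pairwise_margules(
    A: np.ndarray, composition: Composition, temperature: float = 298.15
) -> np.ndarray:
    """Multicomponent two-suffix Margules from a symmetric pair matrix.

    ln γ_k = Σ_j A_kj x_j − Σ_{i<j} A_ij x_i x_j; reduces to the binary
    form for two components.
    """
    A = np.asarray(A, dtype=float)
    n = len(composition)
    if A.shape != (n, n):
        raise ValueError(f"A must be {n}x{n}")
    if not np.allclose(A, A.T) or np.any(np.diag(A) != 0):
        raise ValueError("A must be symmetric with zero diagonal")
    x = composition.as_array()
    ge = 0.5 * x @ A @ x  # Σ_{i<j} A_ij x_i x_j
    return A @ x - ge


def ln_gamma_nrtl(
    tau: np.ndarray,
    alpha: np.ndarray,
    composition: Composition,
    temperature: float = 298.15,
) -> np.ndarray:
    """Standard multicomponent NRTL ln γ.

    G_ji = exp(−α_ji τ_ji);  reduces to zeros when all τ vanish.
    """
    tau = np.asarray(tau, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    n = len(composition)
    if tau.shape != (n, n) or alpha.shape != (n, n):
        raise ValueError(f"tau and alpha must be {n}x{n}")
    if np.any(np.diag(tau) != 0):
        raise ValueError("tau must have zero diagonal")
    if not np.allclose(alpha, alpha.T):
        raise ValueError("alpha must be symmetric")
    x = composition.as_array()
    G = np.exp(-alpha * tau)
    # denom_j = Σ_k x_k G_kj
    denom = x @ G
    # S_j = Σ_m x_m τ_mj G_mj
    S = x @ (tau * G)
    term1 = S / denom
    # term2_i = Σ_j x_j G_ij / denom_j * (τ_ij − S_j/denom_j)
    term2 = ((x / denom) * (tau - S / denom) * G).sum(axis=1)
    return term1 + term2


# ---------------------------------------------------------------------------
# model classes


class IdealModel(ActivityModel):
    name = "ideal"

    def __init__(self, n_components: int = 2):
        if n_components < 1:
            raise ValueError("need at least one component")
        self._n = n_components

    @property
    def n_components(self) -> int:
        return self._n

    def ln_gamma(self, composition: Composition, temperature: float) -> np.ndarray:
        self._check(composition)
        return ln_gamma_ideal(composition, temperature)


class MargulesModel(ActivityModel):
    name = "margules"

    def __init__(self, A: float):
        self.A = float(A)

    @property
    def n_components(self) -> int:
        return 2

    def ln_gamma(self, composition: Composition, temperature: float) -> np.ndarray:
        self._check(composition)
        return ln_gamma_margules(self.A, composition, temperature)


class PairwiseMargulesModel(ActivityModel):
    name = "pairwise-margules"

    def __init__(self, A: Sequence[Sequence[float]]):
        self.A = np.asarray(A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("A must be a square matrix")
        if not np.allclose(self.A, self.A.T) or np.any(np.diag(self.A) != 0):
            raise ValueError("A must be symmetric with zero diagonal")

    @property
    def n_components(self) -> int:
        return self.A.shape[0]

    def ln_gamma(self, composition: Composition, temperature: float) -> np.ndarray:
        self._check(composition)
        return ln_gamma_pairwise_margules(self.A, composition, temperature)


class NRTLModel(ActivityModel):
    name = "nrtl"

    def __init__(self, tau: Sequence[Sequence[float]], alpha: Sequence[Sequence[float]]):
        self.tau = np.asarray(tau, dtype=float)
        self.alpha = np.asarray(alpha, dtype=float)
        n = self.tau.shape[0]
        if self.tau.shape != (n, n) or self.alpha.shape != (n, n):
            raise ValueError("tau and alpha must be square and equally sized")
        if np.any(np.diag(self.tau) != 0):
            raise ValueError("tau must have zero diagonal")
        if not np.allclose(self.alpha, self.alpha.T):
            raise ValueError("alpha must be symmetric")

    @property
    def n_components(self) -> int:
        return self.tau.shape[0]

    def ln_gamma(self, composition: Composition, temperature: float) -> np.ndarray:
        self._check(composition)
        return ln_gamma_nrtl(self.tau, self.alpha, composition, temperature)


# ---------------------------------------------------------------------------
# JSON parameter files


def model_from_dict(spec: dict) -> ActivityModel:
    """Build a model from {"model": ..., "components": [...], ...}."""
    kind = spec.get("model")
    if kind == "ideal":
        n = spec.get("n_components") or len(spec.get("components", [])) or 2
        return IdealModel(n)
    if kind == "margules":
        return MargulesModel(spec["A"])
    if kind == "pairwise_margules":
        return PairwiseMargulesModel(spec["A"])
    if kind == "nrtl":
        return NRTLModel(spec["tau"], spec["alpha"])
    raise ValueError(f"unknown activity model {kind!r}")


def model_from_json(path: str | Path) -> ActivityModel:
    return model_from_dict(json.loads(Path(path).read_text()))
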
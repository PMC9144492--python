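"""Domain records and catalog IO.

Solvent catalogs carry identity, molar mass, a commercial-availability flag
and the eight raw environmental-index component scores (PARIS-III style).
Solute records carry the fusion data (melting temperature, enthalpy of
fusion with an explicit unit tag) needed for the Gibbs energy of fusion.
Measurement records hold replicate shake-flask solubilities on a solute-free
binary-solvent composition basis.

CSV catalogs may declare scaled EI columns via ``_x10`` / ``_x1e5`` header
suffixes (the display convention of PARIS-III tables, where HTPIng is
printed x10 and ATP x10^5); such columns are de-scaled to raw scores at
load time, so records always hold raw scores.
"""

from __future__ import annotations

import json
import logging
import math
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

logger = logging.getLogger(__name__)

KCAL_TO_KJ = 4.184  # thermochemical calorie, exact

#: EI component field names, in the conventional printed order.
EI_FIELDS = ("htping", "htpinh", "ttp", "atp", "gwp", "odp", "pcop", "ar")

#: header-suffix -> multiplicative factor applied at *display* time;
#: loading divides by it, writing with ``scaled=True`` multiplies by it.
EI_SCALE_SUFFIXES = {"_x10": 10.0, "_x1e5": 1.0e5}


class CatalogSchemaError(ValueError):
    """A catalog file is missing a mandatory column."""


class CatalogRowError(ValueError):
    """A catalog row failed to parse or validate; carries the row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class EnthalpyUnit(str, Enum):
    KJ_PER_MOL = "kJ/mol"
    KCAL_PER_MOL = "kcal/mol"


class EIComponents(BaseModel):
    """The eight environmental scores on the raw (de-scaled) PARIS-III scale.

    Lower is greener.  HTPIng/HTPInh: human toxicity by ingestion/inhalation;
    TTP/ATP: terrestrial/aquatic toxicity; GWP: global warming; ODP: ozone
    depletion; PCOP: photochemical oxidation (smog); AR: acid rain.
    """

    model_config = ConfigDict(frozen=True)

    htping: float = Field(ge=0)
    htpinh: float = Field(ge=0)
    ttp: float = Field(ge=0)
    atp: float = Field(ge=0)
    gwp: float = Field(ge=0)
    odp: float = Field(ge=0)
    pcop: float = Field(ge=0)
    ar: float = Field(ge=0)

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, f) for f in EI_FIELDS)


class SoluteRecord(BaseModel):
    """A crystalline solute with the fusion data needed for ΔfusG.

    The enthalpy unit tag is always explicit and preserved as given; use
    :func:`convert_fusion_enthalpy` to obtain kJ/mol.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    cas: Optional[str] = None
    melt_temp: float = Field(gt=0, description="melting temperature, K")
    fusion_enthalpy: float = Field(gt=0, description="enthalpy of fusion")
    fusion_enthalpy_unit: EnthalpyUnit

    def fusion_enthalpy_kj(self) -> float:
        return convert_fusion_enthalpy(self.fusion_enthalpy, self.fusion_enthalpy_unit)


class SolventRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    cas: Optional[str] = None
    molar_mass: float = Field(gt=0, description="g/mol")
    available: bool = True
    ei: Optional[EIComponents] = None


class MeasurementRecord(BaseModel):
    """One shake-flask measurement: replicate saturation mole fractions of a
    solute in a water-organic binary at a solute-free organic fraction."""

    model_config = ConfigDict(frozen=True)

    solute: str
    organic_solvent: str
    organic_fraction: float = Field(ge=0, le=1, description="solute-free x2*")
    temperature: float = Field(gt=0, description="K")
    replicate_solubilities: tuple[float, ...]

    @field_validator("replicate_solubilities")
    @classmethod
    def _replicates_valid(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if len(v) < 1:
            raise ValueError("at least one replicate is required")
        if not all(0.0 < x < 1.0 for x in v):
            raise ValueError("replicate mole fractions must lie in (0, 1)")
        return v

    def mean(self) -> float:
        return sum(self.replicate_solubilities) / len(self.replicate_solubilities)

    def sd(self) -> float:
        """Sample standard deviation (ddof=1); 0.0 for a single replicate."""
        n = len(self.replicate_solubilities)
        if n == 1 or len(set(self.replicate_solubilities)) == 1:
            return 0.0
        m = self.mean()
        return math.sqrt(sum((x - m) ** 2 for x in self.replicate_solubilities) / (n - 1))


def convert_fusion_enthalpy(value: float, unit: EnthalpyUnit | str) -> float:
    """Convert an enthalpy of fusion to kJ/mol.

    kcal/mol is multiplied by 4.184 exactly; kJ/mol passes through.
    """
    if value <= 0:
        raise ValueError("fusion enthalpy must be positive")
    unit = EnthalpyUnit(unit)
    if unit is EnthalpyUnit.KJ_PER_MOL:
        return value
    return value * KCAL_TO_KJ


def solute_free_fraction(moles_organic: float, moles_water: float) -> float:
    """Mole fraction of the organic component in the binary solvent,
    excluding the solute from the basis (the x2* convention)."""
    if moles_organic < 0 or moles_water < 0:
        raise ValueError("mole amounts must be nonnegative")
    total = moles_organic + moles_water
    if total == 0:
        raise ValueError("at least one solvent amount must be positive")
    return moles_organic / total


# ---------------------------------------------------------------------------
# solvent catalog IO

_SOLVENT_MANDATORY = ("name", "cas", "molar_mass_g_mol", "available")


def _ei_column_map(columns: Sequence[str]) -> dict[str, tuple[str, float]]:
    """Map each present EI column name -> (field, de-scale divisor)."""
    out: dict[str, tuple[str, float]] = {}
    for col in columns:
        base, factor = col, 1.0
        for suffix, f in EI_SCALE_SUFFIXES.items():
            if col.endswith(suffix):
                base, factor = col[: -len(suffix)], f
                break
        if base in EI_FIELDS:
            out[col] = (base, factor)
    return out


def _row_to_solvent(row: dict, ei_cols: dict[str, tuple[str, float]], idx: int) -> SolventRecord:
    ei_vals: dict[str, float] = {}
    n_blank = 0
    for col, (field, factor) in ei_cols.items():
        raw = row.get(col)
        if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
            n_blank += 1
            continue
        try:
            ei_vals[field] = float(raw) / factor
        except (TypeError, ValueError) as exc:
            raise CatalogRowError(idx, f"non-numeric EI cell {col!r}: {raw!r}") from exc
    if n_blank and ei_vals:
        raise CatalogRowError(idx, "EI columns must be all present or all blank")
    ei = EIComponents(**ei_vals) if ei_vals else None

    avail = row["available"]
    if isinstance(avail, str):
        avail = avail.strip().lower() in ("true", "1", "yes")
    cas = row.get("cas")
    if cas is not None and (not isinstance(cas, str)) and math.isnan(cas):
        cas = None
    try:
        return SolventRecord(
            name=str(row["name"]),
            cas=None if cas is None else str(cas),
            molar_mass=float(row["molar_mass_g_mol"]),
            available=bool(avail),
            ei=ei,
        )
    except (ValueError, TypeError) as exc:
        raise CatalogRowError(idx, str(exc)) from exc


def load_solvent_catalog(
    path: str | Path, format: Literal["csv", "json"] = "csv"
) -> list[SolventRecord]:
    """Read a solvent catalog; EI columns with ``_x10``/``_x1e5`` header
    suffixes are de-scaled to raw scores."""
    path = Path(path)
    if format == "json":
        rows = json.loads(path.read_text())
        records = []
        for i, entry in enumerate(rows):
            try:
                records.append(SolventRecord.model_validate(entry))
            except Exception as exc:
                raise CatalogRowError(i, str(exc)) from exc
        return records

    df = pd.read_csv(path, dtype={"name": str, "cas": str})
    missing = [c for c in _SOLVENT_MANDATORY if c not in df.columns]
    if missing:
        raise CatalogSchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    ei_cols = _ei_column_map(df.columns)
    found_fields = {f for f, _ in ei_cols.values()}
    missing_ei = [f for f in EI_FIELDS if f not in found_fields]
    if missing_ei:
        raise CatalogSchemaError(f"missing mandatory column(s): {', '.join(missing_ei)}")
    return [_row_to_solvent(row, ei_cols, i) for i, row in enumerate(df.to_dict("records"))]


def write_solvent_catalog(
    records: Iterable[SolventRecord],
    path: str | Path,
    format: Literal["csv", "json"] = "csv",
    scaled: bool = False,
) -> None:
    """Write a solvent catalog.  ``scaled=True`` re-applies the printed
    display scaling (htping x10, atp x1e5) and declares it in the header."""
    path = Path(path)
    records = list(records)
    if format == "json":
        path.write_text(
            json.dumps([r.model_dump(mode="json") for r in records], indent=1) + "\n"
        )
        return

    ei_headers = {
        "htping": "htping_x10" if scaled else "htping",
        "atp": "atp_x1e5" if scaled else "atp",
    }
    rows = []
    for r in records:
        row: dict = {
            "name": r.name,
            "cas": r.cas,
            "molar_mass_g_mol": r.molar_mass,
            "available": r.available,
        }
        for f in EI_FIELDS:
            header = ei_headers.get(f, f)
            if r.ei is None:
                row[header] = None
            else:
                v = getattr(r.ei, f)
                if scaled and f == "htping":
                    v *= 10.0
                elif scaled and f == "atp":
                    v *= 1.0e5
                row[header] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# solute catalog IO

_SOLUTE_MANDATORY = ("name", "tm_K", "hfus", "hfus_unit")


def load_solute_catalog(path: str | Path) -> list[SoluteRecord]:
    df = pd.read_csv(path, dtype={"name": str, "cas": str, "hfus_unit": str})
    missing = [c for c in _SOLUTE_MANDATORY if c not in df.columns]
    if missing:
        raise CatalogSchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    records = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            records.append(
                SoluteRecord(
                    name=str(row["name"]),
                    cas=row.get("cas"),
                    melt_temp=float(row["tm_K"]),
                    fusion_enthalpy=float(row["hfus"]),
                    fusion_enthalpy_unit=EnthalpyUnit(str(row["hfus_unit"]).strip()),
                )
            )
        except (ValueError, TypeError) as exc:
            raise CatalogRowError(i, str(exc)) from exc
    return records


def write_solute_catalog(records: Iterable[SoluteRecord], path: str | Path) -> None:
    rows = [
        {
            "name": r.name,
            "cas": r.cas,
            "tm_K": r.melt_temp,
            "hfus": r.fusion_enthalpy,
            "hfus_unit": r.fusion_enthalpy_unit.value,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# measurement IO

_MEAS_MANDATORY = ("solute", "organic_solvent", "x2_star", "T_K")


def load_measurements(path: str | Path) -> list[MeasurementRecord]:
    """Read a measurements table with replicate columns ``x_rep1..x_repN``."""
    df = pd.read_csv(path, dtype={"solute": str, "organic_solvent": str})
    missing = [c for c in _MEAS_MANDATORY if c not in df.columns]
    if missing:
        raise CatalogSchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    rep_cols = sorted(
        (c for c in df.columns if c.startswith("x_rep")), key=lambda c: int(c[5:])
    )
    if not rep_cols:
        raise CatalogSchemaError("missing replicate column(s) x_rep1..")
    records = []
    for i, row in enumerate(df.to_dict("records")):
        reps = tuple(
            float(row[c])
            for c in rep_cols
            if not (isinstance(row[c], float) and math.isnan(row[c]))
        )
        try:
            records.append(
                MeasurementRecord(
                    solute=str(row["solute"]),
                    organic_solvent=str(row["organic_solvent"]),
                    organic_fraction=float(row["x2_star"]),
                    temperature=float(row["T_K"]),
                    replicate_solubilities=reps,
                )
            )
        except (ValueError, TypeError) as exc:
            raise CatalogRowError(i, str(exc)) from exc
    return records


def write_measurements(records: Iterable[MeasurementRecord], path: str | Path) -> None:
    records = list(records)
    n_rep = max((len(r.replicate_solubilities) for r in records), default=0)
    rows = []
    for r in records:
        row: dict = {
            "solute": r.solute,
            "organic_solvent": r.organic_solvent,
            "x2_star": r.organic_fraction,
            "T_K": r.temperature,
        }
        for k in range(n_rep):
            row[f"x_rep{k + 1}"] = (
                r.replicate_solubilities[k] if k < len(r.replicate_solubilities) else None
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# bundled fixtures: the four experimental solvents (plus the methanol
# reference) with their printed EI components, and the three aromatic amides

_warned_units = False


def _data_path(name: str):
    return resources.files("greensolv.data").joinpath(name)


def bundled_solvents() -> list[SolventRecord]:
    """Water, methanol, DMSO, DMF and 4-formylmorpholine with their printed
    EI component scores (water and methanol carry no component breakdown)."""
    with resources.as_file(_data_path("solvents.csv")) as p:
        return load_solvent_catalog(p, "csv")


def bundled_solutes() -> list[SoluteRecord]:
    """Benzamide, salicylamide and ethenzamide fusion data.

    The bundled enthalpies are declared kJ/mol.  The source compilation
    prints the same magnitudes tagged kcal/mol, but at those magnitudes only
    the kJ/mol reading yields ideal solubilities on the scale of the
    measured values; the discrepancy is logged once, not silently resolved.
    """
    global _warned_units
    if not _warned_units:
        logger.warning(
            "bundled solute fusion enthalpies are declared kJ/mol; the printed "
            "source tags the same magnitudes kcal/mol (unit tag is ambiguous)"
        )
        _warned_units = True
    with resources.as_file(_data_path("solutes.csv")) as p:
        return load_solute_catalog(p)
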
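"""Catalog records, unit conversion, and CSV/JSON round-trips."""

import math

import pytest
from pydantic import ValidationError

from greensolv.catalog import (
    CatalogRowError,
    CatalogSchemaError,
    EIComponents,
    EnthalpyUnit,
    MeasurementRecord,
    SoluteRecord,
    SolventRecord,
    convert_fusion_enthalpy,
    load_measurements,
    load_solvent_catalog,
    solute_free_fraction,
    write_measurements,
    write_solvent_catalog,
)

EI_KW = dict(htpinh=0.0, ttp=0.1, gwp=0.0, odp=0.0, pcop=0.0, ar=0.0)


@pytest.mark.parametrize(
    "value,unit,expected",
    [
        (20.9, "kJ/mol", 20.9),
        (1.0, "kcal/mol", 4.184),
        (20.9, "kcal/mol", 87.4456),
    ],
)
def test_fusion_enthalpy_conversion(value, unit, expected):
    assert convert_fusion_enthalpy(value, unit) == pytest.approx(expected, abs=1e-12)


def test_fusion_enthalpy_rejects_bad_input():
    with pytest.raises(ValueError):
        convert_fusion_enthalpy(-1.0, "kJ/mol")
    with pytest.raises(ValueError):
        convert_fusion_enthalpy(1.0, "cal/mol")


@pytest.mark.parametrize(
    "n_org,n_wat,expected", [(1, 4, 0.2), (1, 0, 1.0), (3, 2, 0.6), (0, 5, 0.0)]
)
def test_solute_free_fraction(n_org, n_wat, expected):
    assert solute_free_fraction(n_org, n_wat) == pytest.approx(expected)


def test_solute_free_fraction_rejects_empty_basis():
    with pytest.raises(ValueError):
        solute_free_fraction(0, 0)


def test_record_invariants_enforced():
    with pytest.raises(ValidationError):
        SolventRecord(name="bad", molar_mass=-1.0)
    with pytest.raises(ValidationError):
        SoluteRecord(
            name="bad", melt_temp=-5, fusion_enthalpy=10, fusion_enthalpy_unit="kJ/mol"
        )
    with pytest.raises(ValidationError):
        MeasurementRecord(
            solute="s",
            organic_solvent="o",
            organic_fraction=0.5,
            temperature=298.15,
            replicate_solubilities=(1.2,),
        )
    with pytest.raises(ValidationError):
        EIComponents(htping=-0.1, atp=0.0, **EI_KW)


def test_scaled_ei_headers_descale_on_load(tmp_path):
    # the printed DMSO row: HTPIng is displayed x10, ATP x1e5
    p = tmp_path / "cat.csv"
    p.write_text(
        "name,cas,molar_mass_g_mol,available,htping_x10,htpinh,ttp,atp_x1e5,gwp,odp,pcop,ar\n"
        "DMSO,67-68-5,78.13,True,1.30,0.00,0.13,6.20,0.0,0.0,11.40,0.0\n"
    )
    (rec,) = load_solvent_catalog(p)
    assert rec.ei.htping == pytest.approx(0.130)
    assert rec.ei.atp == pytest.approx(6.20e-5)


@pytest.mark.parametrize(
    "fmt,scaled", [("csv", False), ("csv", True), ("json", False)]
)
def test_catalog_round_trip(tmp_path, fmt, scaled, solvents):
    records = list(solvents.values())
    p = tmp_path / f"cat.{fmt}"
    if fmt == "csv":
        write_solvent_catalog(records, p, fmt, scaled=scaled)
    else:
        write_solvent_catalog(records, p, fmt)
    back = load_solvent_catalog(p, fmt)
    assert [r.name for r in back] == [r.name for r in records]
    for a, b in zip(records, back):
        assert (a.cas, a.available) == (b.cas, b.available)
        assert b.molar_mass == pytest.approx(a.molar_mass, rel=1e-12)
        assert (a.ei is None) == (b.ei is None)
        if a.ei is not None:
            for va, vb in zip(a.ei.as_tuple(), b.ei.as_tuple()):
                assert vb == pytest.approx(va, rel=1e-12)


def test_missing_column_is_schema_error(tmp_path):
    p = tmp_path / "cat.csv"
    p.write_text("name,cas,available\nfoo,1-1-1,True\n")
    with pytest.raises(CatalogSchemaError, match="molar_mass_g_mol"):
        load_solvent_catalog(p)


def test_non_numeric_ei_cell_names_row(tmp_path):
    p = tmp_path / "cat.csv"
    p.write_text(
        "name,cas,molar_mass_g_mol,available,htping,htpinh,ttp,atp,gwp,odp,pcop,ar\n"
        "ok,1-1-1,50.0,True,0.1,0,0,0,0,0,0,0\n"
        "bad,2-2-2,60.0,True,oops,0,0,0,0,0,0,0\n"
    )
    with pytest.raises(CatalogRowError, match="row 1"):
        load_solvent_catalog(p)


def test_measurements_round_trip(tmp_path):
    recs = [
        MeasurementRecord(
            solute="salicylamide",
            organic_solvent="4FM",
            organic_fraction=0.6,
            temperature=298.15,
            replicate_solubilities=(0.377, 0.379, 0.381),
        )
    ]
    p = tmp_path / "meas.csv"
    write_measurements(recs, p)
    (back,) = load_measurements(p)
    assert back.mean() == pytest.approx(0.379, rel=1e-12)
    assert back.organic_fraction == 0.6


def test_bundled_fixtures_cover_study_systems(solutes, solvents):
    assert set(solutes) == {"benzamide", "salicylamide", "ethenzamide"}
    assert solutes["benzamide"].melt_temp == 401.0
    assert {"water", "methanol", "DMSO", "DMF", "4FM"} <= set(solvents)
    assert solvents["water"].ei is None  # no published component breakdown
    assert solvents["4FM"].molar_mass == pytest.approx(115.13)
    assert math.isclose(solvents["DMSO"].ei.pcop, 11.40)
    for s in solutes.values():
        assert s.fusion_enthalpy_unit is EnthalpyUnit.KJ_PER_MOL
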
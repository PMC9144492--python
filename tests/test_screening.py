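"""The availability -> EI -> solubility screening cascade."""

import pytest

from greensolv.activity import IdealModel, MargulesModel
from greensolv.catalog import EIComponents, SolventRecord
from greensolv.green_index import ei_total
from greensolv.screening import (
    ScreeningConfig,
    screen_catalog,
    shortlist_binary_grids,
)
from greensolv.synthetic import CatalogSpec, generate_solvent_catalog


def flat_ei(total: float, pcop: float = 0.0) -> EIComponents:
    # exact float total: everything except pcop goes to one component
    return EIComponents(
        htping=total - pcop, htpinh=0, ttp=0, atp=0, gwp=0, odp=0,
        pcop=pcop, ar=0,
    )


@pytest.fixture()
def planted_problem(solutes):
    catalog, truth = generate_solvent_catalog(
        CatalogSpec(n_solvents=200, planted_good=40, seed=42), return_truth=True
    )
    reference = SolventRecord(name="methanol", molar_mass=32.04, available=False)

    def provider(rec):
        if rec.name == "methanol":
            return IdealModel(2)  # ideal-solution reference
        return MargulesModel(truth.margules_a[rec.name])

    return catalog + [reference], solutes["benzamide"], provider, truth


def test_cascade_recovers_planted_set(planted_problem):
    catalog, solute, provider, truth = planted_problem
    report = screen_catalog(catalog, solute, provider, ScreeningConfig())
    assert report.better_set() == set(truth.planted)
    c = report.counts
    assert c["input"] >= c["available"] >= c["ei_pass"] >= c["scored"]
    # shortlist sorted by predicted solubility descending
    finite = [e.log10_x for e in report.shortlist if not e.miscible]
    assert finite == sorted(finite, reverse=True)


def test_empty_catalog(solutes):
    report = screen_catalog([], solutes["benzamide"], lambda r: IdealModel(2))
    assert report.shortlist == ()
    assert all(v == 0 for v in report.counts.values())


def test_ei_threshold_is_strict(solutes):
    """EI exactly equal to ei_max is excluded."""
    catalog = [
        SolventRecord(name="at-threshold", molar_mass=50.0, available=True,
                      ei=flat_ei(2.0)),
        SolventRecord(name="just-below", molar_mass=50.0, available=True,
                      ei=flat_ei(2.0 - 1e-9)),
        SolventRecord(name="methanol", molar_mass=32.04, available=False),
    ]
    assert ei_total(catalog[0].ei) == pytest.approx(2.0, abs=1e-12)
    report = screen_catalog(
        catalog, solutes["benzamide"], lambda r: IdealModel(2), ScreeningConfig()
    )
    assert report.counts["ei_pass"] == 1
    assert [e.solvent for e in report.shortlist] == ["just-below"]


def test_all_ei_too_high_empty_shortlist(solutes):
    catalog = [
        SolventRecord(name=f"s{i}", molar_mass=50.0, available=True, ei=flat_ei(5.0))
        for i in range(3)
    ]
    report = screen_catalog(
        catalog, solutes["benzamide"], lambda r: IdealModel(2),
        ScreeningConfig(reference_log_solubility=-1.0),
    )
    assert report.counts["ei_pass"] == 0 and report.shortlist == ()


def test_solvent_without_ei_counted_separately(solutes, caplog):
    catalog = [
        SolventRecord(name="no-ei", molar_mass=50.0, available=True),
        SolventRecord(name="ok", molar_mass=50.0, available=True, ei=flat_ei(1.0)),
    ]
    with caplog.at_level("WARNING", logger="greensolv.screening"):
        report = screen_catalog(
            catalog, solutes["benzamide"], lambda r: IdealModel(2),
            ScreeningConfig(reference_log_solubility=-1.0),
        )
    assert report.counts["skipped_no_ei"] == 1
    assert "no-ei" in caplog.text


def test_missing_reference_raises(solutes):
    catalog = [
        SolventRecord(name="ok", molar_mass=50.0, available=True, ei=flat_ei(1.0))
    ]
    with pytest.raises(ValueError, match="reference"):
        screen_catalog(catalog, solutes["benzamide"], lambda r: IdealModel(2))


def test_miscible_predictions_rank_first(solutes):
    catalog = [
        SolventRecord(name="super", molar_mass=60.0, available=True, ei=flat_ei(1.0)),
        SolventRecord(name="plain", molar_mass=70.0, available=True, ei=flat_ei(1.2)),
        SolventRecord(name="methanol", molar_mass=32.04, available=False),
    ]
    models = {"super": MargulesModel(-8.0), "plain": MargulesModel(0.5),
              "methanol": IdealModel(2)}
    report = screen_catalog(
        catalog, solutes["benzamide"], lambda r: models[r.name], ScreeningConfig()
    )
    assert report.shortlist[0].solvent == "super"
    assert report.shortlist[0].miscible
    assert report.shortlist[0].display_solubility() == "miscible"
    assert report.shortlist[0].better_than_reference


def test_binary_grids_pair_solubility_with_mixture_ei(solutes, solvents):
    grid = [0.2, 0.4, 0.6, 0.8, 1.0]
    out = shortlist_binary_grids(
        [solvents["4FM"]], solutes["benzamide"], grid, lambda r: IdealModel(3)
    )
    res = out["4FM"]
    assert len(res.profile) == 5 and len(res.ei) == 5
    # the 4FM mixture EI column against the printed table
    assert res.ei == pytest.approx((0.32, 0.42, 0.46, 0.49, 0.51), abs=0.05)


def test_binary_grids_empty_grid_and_empty_shortlist(solutes, solvents):
    out = shortlist_binary_grids(
        [solvents["4FM"]], solutes["benzamide"], [], lambda r: IdealModel(3)
    )
    assert len(out["4FM"].profile) == 0
    with pytest.raises(ValueError):
        shortlist_binary_grids([], solutes["benzamide"], [0.5], lambda r: None)


def test_report_deterministic(planted_problem):
    catalog, solute, provider, _ = planted_problem
    r1 = screen_catalog(catalog, solute, provider, ScreeningConfig())
    r2 = screen_catalog(catalog, solute, provider, ScreeningConfig())
    assert r1 == r2
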
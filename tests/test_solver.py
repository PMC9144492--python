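"""Fixed-point saturation solver vs. independent root-finding oracles."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from greensolv.activity import Composition, IdealModel, MargulesModel, NRTLModel
from greensolv.fusion import ideal_solubility
from greensolv.solver import (
    MISCIBLE,
    SolverOptions,
    predicted_log_solubility,
    solubility_profile,
    solve_saturation,
)

NEAT = Composition((1.0,))


def bisection_x_sat(model, a_target, temperature=298.15, hi=0.999999):
    """Independent oracle: root of ln(gamma(x) x) - ln a on (0, hi)."""

    def f(x):
        c = Composition((x, 1.0 - x))
        return float(model.ln_gamma(c, temperature)[0]) + math.log(x) - math.log(a_target)

    return brentq(f, 1e-14, hi, xtol=1e-14, rtol=1e-15)


def test_ideal_model_recovers_closed_form(solutes):
    for s in solutes.values():
        for T in (298.15, 303.15, 313.15):
            res = solve_saturation(s, NEAT, IdealModel(2), T)
            assert res.converged and not res.miscible
            assert res.x_sat == pytest.approx(ideal_solubility(s, T), rel=1e-9)
            assert res.gamma_sat == 1.0


def test_above_melting_point_is_miscible(solutes):
    s = solutes["benzamide"]
    res = solve_saturation(s, NEAT, IdealModel(2), s.melt_temp + 1.0)
    assert res.miscible and res.x_sat == 1.0 and res.converged


def test_margules_matches_bisection_oracle(solutes):
    benz = solutes["benzamide"]
    res = solve_saturation(benz, NEAT, MargulesModel(2.0), 298.15)
    oracle = bisection_x_sat(MargulesModel(2.0), res.activity_target)
    assert res.x_sat == pytest.approx(0.0166, abs=2e-4)
    assert abs(res.x_sat - oracle) < 1e-8
    # converged result satisfies the saturation identity
    assert abs(res.gamma_sat * res.x_sat - res.activity_target) < 1e-8


def test_random_binaries_match_oracle(solutes):
    """Seeded random Margules/NRTL binaries agree with bisection to 1e-8."""
    rng = np.random.default_rng(2024)
    benz, sali = solutes["benzamide"], solutes["salicylamide"]
    for k in range(50):
        solute = benz if k % 2 == 0 else sali
        T = float(rng.uniform(283.15, 333.15))
        if rng.random() < 0.5:
            model = MargulesModel(float(rng.uniform(-2.0, 1.8)))
        else:
            t12, t21 = rng.uniform(-1.0, 1.0, size=2)
            al = float(rng.uniform(0.2, 0.47))
            model = NRTLModel(
                [[0.0, t12], [t21, 0.0]], [[0.0, al], [al, 0.0]]
            )
        res = solve_saturation(solute, NEAT, model, T)
        assert res.converged and not res.miscible
        oracle = bisection_x_sat(model, res.activity_target, T)
        assert abs(res.x_sat - oracle) < 1e-8, (k, model.name)


@pytest.mark.parametrize("damping", [0.25, 0.5, 1.0])
def test_damping_independence(solutes, damping):
    benz = solutes["benzamide"]
    ref = solve_saturation(benz, NEAT, MargulesModel(1.5), 298.15)
    res = solve_saturation(
        benz, NEAT, MargulesModel(1.5), 298.15, SolverOptions(damping=damping)
    )
    assert res.x_sat == pytest.approx(ref.x_sat, abs=1e-9)


def test_strong_negative_deviation_reports_miscible(solutes):
    """A sufficiently favourable solvent drives the iterate to the
    miscibility cutoff -> 'infinite solubility'."""
    res = solve_saturation(
        solutes["benzamide"], NEAT, MargulesModel(-8.0), 298.15
    )
    assert res.miscible and res.x_sat == 1.0


def test_profile_ideal_model_flat(solutes, solvents):
    prof = solubility_profile(
        solutes["benzamide"], solvents["4FM"], [0.0, 1.0], IdealModel(3), 298.15
    )
    xid = ideal_solubility(solutes["benzamide"], 298.15)
    assert prof.solubilities == pytest.approx((xid, xid), rel=1e-9)
    assert prof.gaps == ()


def test_profile_empty_grid(solutes, solvents):
    prof = solubility_profile(
        solutes["benzamide"], solvents["4FM"], [], IdealModel(3), 298.15
    )
    assert len(prof) == 0


def test_profile_monotone_with_organic_affinity(solutes, solvents):
    """NRTL with stronger organic affinity gives a monotone increasing
    aqueous-binary profile, each point agreeing with a direct solve."""
    # components: (solute, water, organic); organic much more favourable
    tau = [[0.0, 2.0, -1.0], [2.0, 0.0, 0.5], [-1.0, 0.5, 0.0]]
    alpha = np.full((3, 3), 0.3) - np.diag([0.3] * 3)
    model = NRTLModel(tau, alpha)
    grid = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
    prof = solubility_profile(
        solutes["benzamide"], solvents["4FM"], grid, model, 298.15
    )
    assert list(prof.solubilities) == sorted(prof.solubilities)
    for f, x in zip(prof.organic_fractions, prof.solubilities):
        direct = solve_saturation(
            solutes["benzamide"], Composition((1.0 - f, f)), model, 298.15
        )
        assert x == pytest.approx(direct.x_sat, rel=1e-12)


def test_predicted_log_solubility(solutes, solvents):
    benz = solutes["benzamide"]
    log_x = predicted_log_solubility(benz, solvents["4FM"], IdealModel(2), 298.15)
    assert log_x == pytest.approx(math.log10(ideal_solubility(benz, 298.15)))
    misc = predicted_log_solubility(
        benz, solvents["DMSO"], MargulesModel(-8.0), 298.15
    )
    assert misc == MISCIBLE and misc > log_x  # miscible sorts above any finite value
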
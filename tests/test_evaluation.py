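"""Normalization, weighted-average error, FVA error bounds, physiology."""

import numpy as np
import pandas as pd
import pytest

from exprflux import (
    MfaComparison,
    MfaEntry,
    error_bounds,
    normalization_factor,
    per_flux_errors,
    physiology_metrics,
    weighted_average_error,
)
from exprflux.evaluation import (
    combo_to_string,
    evaluate_combo,
    parse_combo,
    sweep_scaling_factor,
)
from exprflux.optimization import FluxSolution, FvaRanges


def sol_of(fluxes):
    return FluxSolution(fluxes=dict(fluxes), objective=0.0)


def mfa_of(entries, co2=("CO2", 10.0)):
    return MfaComparison(
        entries=[MfaEntry(f"m{i}", m, [(r, 1.0)]) for i, (r, m) in enumerate(entries)],
        measured_co2_uptake=co2[1],
        co2_combo=[(co2[0], 1.0)],
    )


# -- combos ------------------------------------------------------------------


def test_combo_parsing_and_round_trip():
    combo = parse_combo("1.0*RBC__leaf__day - 2*PRD__leaf__day + STS__leaf__day")
    assert combo == [("RBC__leaf__day", 1.0), ("PRD__leaf__day", -2.0), ("STS__leaf__day", 1.0)]
    assert parse_combo(combo_to_string(combo)) == combo
    fluxes = {"RBC__leaf__day": 4.0, "PRD__leaf__day": 1.0, "STS__leaf__day": 0.5}
    assert evaluate_combo(combo, fluxes) == pytest.approx(2.5)


# -- normalization -----------------------------------------------------------


def test_normalization_ratio():
    sol = sol_of({"CO2": 20.0})
    mfa = mfa_of([("CO2", 10.0)], co2=("CO2", 10.0))
    assert normalization_factor(sol, mfa) == pytest.approx(0.5)
    mfa2 = mfa_of([("CO2", 20.0)], co2=("CO2", 20.0))
    assert normalization_factor(sol, mfa2) == pytest.approx(1.0)


def test_zero_model_co2_is_undefined():
    with pytest.raises(ZeroDivisionError):
        normalization_factor(sol_of({"CO2": 0.0}), mfa_of([("CO2", 1.0)]))


def test_normalization_neutrality():
    """Scaling all model fluxes by k leaves the weighted error unchanged."""
    rng = np.random.default_rng(5)
    rids = [f"R{i}" for i in range(8)]
    fluxes = {r: float(rng.normal()) for r in rids}
    fluxes["CO2"] = 2.0
    measured = [(r, float(rng.normal())) for r in rids]
    mfa = mfa_of(measured, co2=("CO2", 3.0))
    base_sol = sol_of(fluxes)
    err0 = weighted_average_error(base_sol, mfa, normalization_factor(base_sol, mfa))
    for k in (0.1, 2.0, 100.0):
        scaled = sol_of({r: k * v for r, v in fluxes.items()})
        err = weighted_average_error(scaled, mfa, normalization_factor(scaled, mfa))
        assert err == pytest.approx(err0, rel=1e-9)


# -- weighted-average error --------------------------------------------------


def test_weighted_error_worked_example():
    sol = sol_of({"R1": 1.5, "R2": 1.5, "CO2": 1.0})
    mfa = mfa_of([("R1", 2.0), ("R2", 1.0)], co2=("CO2", 1.0))
    assert weighted_average_error(sol, mfa, A=1.0) == pytest.approx(100 * (0.5 + 0.5) / 3)


def test_exact_predictions_have_zero_error():
    sol = sol_of({"R1": 2.0, "R2": 1.0})
    mfa = mfa_of([("R1", 2.0), ("R2", 1.0)])
    assert weighted_average_error(sol, mfa, A=1.0) == pytest.approx(0.0)


def test_weighted_error_equals_brute_force_weighted_mean():
    """Eq identity: |v_m|-weighted mean of per-flux % errors collapses to
    sum|A v_p - v_m| / sum|v_m|."""
    rng = np.random.default_rng(17)
    for _ in range(50):
        n = 20
        rids = [f"R{i}" for i in range(n)]
        fluxes = {r: float(rng.normal(0, 5)) for r in rids}
        measured = [(r, float(rng.normal(0, 5))) for r in rids]
        measured = [(r, m if m != 0 else 1.0) for r, m in measured]
        mfa = mfa_of(measured, co2=("R0", 1.0))
        A = float(rng.uniform(0.5, 2.0))
        # oracle: explicit per-flux % errors then |v_m|-weighted averaging
        num = den = 0.0
        for r, m in measured:
            pct = 100.0 * abs(A * fluxes[r] - m) / abs(m)
            num += pct * abs(m)
            den += abs(m)
        assert weighted_average_error(sol_of(fluxes), mfa, A) == pytest.approx(num / den, abs=1e-12, rel=1e-12)


def test_all_zero_measured_is_undefined():
    with pytest.raises(ZeroDivisionError):
        weighted_average_error(sol_of({"R1": 1.0}), mfa_of([("R1", 0.0)]), A=1.0)


def test_per_flux_errors_flag_zero_measurements():
    sol = sol_of({"R1": 1.0, "R2": 0.5})
    mfa = mfa_of([("R1", 2.0), ("R2", 0.0)])
    table = per_flux_errors(sol, mfa, A=1.0)
    row1 = table[table.mfa_id == "m0"].iloc[0]
    assert row1.pct_error == pytest.approx(50.0)
    row2 = table[table.mfa_id == "m1"].iloc[0]
    assert bool(row2.zero_measured) and np.isnan(row2.pct_error)


# -- FVA error bounds --------------------------------------------------------


def fva_of(ranges):
    return FvaRanges(ranges=dict(ranges), objective=0.0, objective_tolerance=1e-6)


def test_point_face_gives_equal_bounds():
    sol = sol_of({"R1": 1.5})
    mfa = mfa_of([("R1", 2.0)])
    fva = fva_of({"R1": (1.5, 1.5)})
    point = weighted_average_error(sol, mfa, A=1.0)
    lo, hi = error_bounds(fva, mfa, A=1.0)
    assert lo == pytest.approx(point)
    assert hi == pytest.approx(point)


def test_interval_nearest_and_farthest_rule():
    mfa = mfa_of([("R1", 1.0)])
    lo, hi = error_bounds(fva_of({"R1": (0.5, 2.0)}), mfa, A=1.0)
    assert lo == pytest.approx(0.0)  # 1.0 lies inside [0.5, 2.0]
    assert hi == pytest.approx(100.0)  # farthest endpoint is 2.0


def test_signed_combo_interval_arithmetic():
    mfa = MfaComparison(
        entries=[MfaEntry("net", 1.0, [("F", 1.0), ("B", -1.0)])],
        measured_co2_uptake=1.0,
        co2_combo=[("F", 1.0)],
    )
    fva = fva_of({"F": (2.0, 3.0), "B": (0.0, 1.0)})
    lo, hi = error_bounds(fva, mfa, A=1.0)
    # net range is [1, 3]: nearest point to 1.0 is 1.0, farthest is 3.0
    assert lo == pytest.approx(0.0)
    assert hi == pytest.approx(200.0)


def test_missing_fva_range_raises():
    with pytest.raises(KeyError):
        error_bounds(fva_of({}), mfa_of([("R1", 1.0)]), A=1.0)


def test_bounds_bracket_point_error_on_fixture(bundle):
    from exprflux import build_weight_vector, minimize_weighted_flux, run_fva

    wv = build_weight_vector(bundle.model, bundle.expression, sf=0.0)
    sol = minimize_weighted_flux(bundle.model, wv)
    subset = sorted(
        {r for e in bundle.mfa.entries for r, _ in e.combo}
        | {r for r, _ in bundle.mfa.co2_combo}
    )
    fva = run_fva(bundle.model, wv, reactions=subset, incumbent=sol)
    A = normalization_factor(sol, bundle.mfa)
    point = weighted_average_error(sol, bundle.mfa, A)
    lo, hi = error_bounds(fva, bundle.mfa, A)
    assert lo <= point + 1e-6
    assert hi >= point - 1e-6


# -- physiology metrics ------------------------------------------------------


def test_physiology_hand_computed():
    sol = sol_of({"RBC": 2.0, "CUP": 1.0, "PRD": 0.5, "CEF": 0.2, "LEF": 1.0, "BIO": 0.4})
    sets = {
        "rubisco_carboxylase": ["RBC"],
        "co2_net": ["CUP"],
        "photorespiratory_decarboxylation": ["PRD"],
        "cef": ["CEF"],
        "lef": ["LEF"],
        "biomass_carbon": {"BIO": 2},
    }
    m = physiology_metrics(sol, sets)
    assert m.rubisco_ratio == pytest.approx(2.0)
    assert m.photorespiratory_loss_pct == pytest.approx(50.0)
    assert m.cef_lef_pct == pytest.approx(20.0)
    assert m.biomass_carbon_pct == pytest.approx(80.0)
    assert m.undefined == []


def test_no_cyclic_flow_gives_zero_ratio():
    sol = sol_of({"CEF": 0.0, "LEF": 1.0, "CUP": 1.0})
    m = physiology_metrics(sol, {"cef": ["CEF"], "lef": ["LEF"], "co2_net": ["CUP"]})
    assert m.cef_lef_pct == pytest.approx(0.0)


def test_zero_denominators_flagged_undefined():
    sol = sol_of({"CEF": 1.0, "LEF": 0.0, "CUP": 0.0, "RBC": 1.0})
    m = physiology_metrics(
        sol, {"cef": ["CEF"], "lef": ["LEF"], "co2_net": ["CUP"], "rubisco_carboxylase": ["RBC"]}
    )
    assert m.cef_lef_pct is None
    assert m.rubisco_ratio is None
    assert set(m.undefined) >= {"cef_lef_pct", "rubisco_ratio"}


def test_fixture_truth_physiology(bundle):
    m = physiology_metrics(bundle.true_fluxes, bundle.physiology_sets)
    assert m.rubisco_ratio == pytest.approx(1.0)  # no photorespiration planted
    assert m.cef_lef_pct == pytest.approx(0.0)
    # leaf daytime biomass / leaf daytime assimilation = 0.01 / 0.06
    assert m.biomass_carbon_pct == pytest.approx(100.0 / 6.0, rel=1e-9)


# -- sweep -------------------------------------------------------------------


def test_sweep_grid_arity_and_sf_zero_equivalence(bundle):
    grid = [0.0, 1.0]
    table = sweep_scaling_factor(
        bundle.model, bundle.expression, grid, ["unit", "tissue_median"], bundle.mfa,
        with_fva=False,
    )
    assert len(table) == 4
    sf0 = table[table.sf == 0.0]
    # SF = 0 is pFBA whatever the policy: identical objective and error
    assert sf0.objective.nunique() == 1
    assert sf0.point_pct.round(9).nunique() == 1
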
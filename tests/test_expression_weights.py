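"""Gene weights, GPR combination, scaling, policies, and control transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from exprflux import (
    ExpressionTable,
    ZeroPolicy,
    apply_scaling,
    build_weight_vector,
    combine_gpr_weights,
    gene_weight,
    make_toy_plant,
    parse_gpr,
    randomize_weights,
    swap_tissue_expression,
)
from exprflux.expression_weights import ConfigError
from exprflux.gpr import GprLeaf, GprOp


# -- gene weights ------------------------------------------------------------


def test_weight_is_peak_over_own_expression():
    row = {"leaf": 10.0, "stem": 5.0, "root": 2.5}
    assert gene_weight(row, "root") == pytest.approx(4.0)
    assert gene_weight(row, "stem") == pytest.approx(2.0)
    assert gene_weight(row, "leaf") == pytest.approx(1.0)


def test_zero_expression_capped_not_infinite():
    row = {"leaf": 10.0, "stem": 0.0, "root": 5.0}
    assert gene_weight(row, "stem", ZeroPolicy(w_max=1000.0)) == pytest.approx(1000.0)
    assert gene_weight(row, "stem", ZeroPolicy(w_max=50.0)) == pytest.approx(50.0)


def test_all_zero_gene_is_absent():
    assert gene_weight({"leaf": 0.0, "root": 0.0}, "leaf") is None


def test_scale_invariance_of_weights():
    """Multiplying a gene's whole row by k > 0 changes nothing (ratios only)."""
    row = {"leaf": 8.0, "stem": 2.0, "root": 1.0}
    for k in (0.001, 3.7, 1e4):
        scaled = {t: k * v for t, v in row.items()}
        for t in row:
            assert gene_weight(scaled, t) == pytest.approx(gene_weight(row, t))


# -- GPR combination ---------------------------------------------------------


def test_isozyme_mean_complex_max():
    tree = parse_gpr("(G1 or G2) and G3")
    w = combine_gpr_weights(tree, {"G1": 1.0, "G2": 3.0, "G3": 1.5})
    assert w == pytest.approx(2.0)  # max(mean(1, 3), 1.5)


def test_single_gene_identity():
    assert combine_gpr_weights(GprLeaf("G"), {"G": 7.0}) == pytest.approx(7.0)


def test_absent_genes_dropped_and_all_absent_signals_no_evidence():
    tree = parse_gpr("(G1 or G2) and G3")
    assert combine_gpr_weights(tree, {"G1": None, "G2": 4.0, "G3": 1.0}) == pytest.approx(4.0)
    assert combine_gpr_weights(tree, {"G1": None, "G2": None, "G3": None}) is None
    # missing from the mapping behaves like absent
    assert combine_gpr_weights(tree, {"G2": 4.0}) == pytest.approx(4.0)


def brute_force_combine(tree, weights):
    """Independent oracle: plain recursion, no numpy, explicit drop rules."""
    if isinstance(tree, GprLeaf):
        return weights.get(tree.gene)
    vals = []
    for child in tree.children:
        v = brute_force_combine(child, weights)
        if v is not None:
            vals.append(v)
    if not vals:
        return None
    if tree.op == "or":
        return sum(vals) / len(vals)
    return max(vals)


def random_tree(rng, depth):
    if depth == 0 or rng.random() < 0.3:
        return GprLeaf(f"G{rng.integers(10)}")
    op = "and" if rng.random() < 0.5 else "or"
    return GprOp(op, tuple(random_tree(rng, depth - 1) for _ in range(rng.integers(2, 4))))


def test_combination_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    for _ in range(300):
        tree = random_tree(rng, 4)
        weights = {
            f"G{i}": (None if rng.random() < 0.2 else float(1 + 9 * rng.random()))
            for i in range(10)
        }
        expected = brute_force_combine(tree, weights)
        got = combine_gpr_weights(tree, weights)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected, rel=1e-12)


# -- scaling -----------------------------------------------------------------


@pytest.mark.parametrize("w,sf,expected", [(2.0, 1.0, 2.0), (3.0, 0.5, 2.0), (5.0, 0.0, 1.0), (1.0, 7.0, 1.0)])
def test_scaling_examples(w, sf, expected):
    assert apply_scaling(w, sf) == pytest.approx(expected)


@settings(derandomize=True, max_examples=100)
@given(
    w=st.floats(min_value=1.0, max_value=1e3),
    sf=st.floats(min_value=0.0, max_value=10.0),
)
def test_scaled_weight_is_affine_with_intercept_one(w, sf):
    c = apply_scaling(w, sf)
    assert c >= 1.0 - 1e-12
    # affine in SF: c(sf) - 1 proportional to sf
    assert apply_scaling(w, 2 * sf) - 1 == pytest.approx(2 * (c - 1), rel=1e-9, abs=1e-9)


# -- full weight vectors -----------------------------------------------------


def hand_table():
    return ExpressionTable(
        pd.DataFrame(
            {"leaf": [10.0, 4.0, 2.0], "stem": [5.0, 4.0, 1.0], "root": [2.5, 1.0, 2.0]},
            index=["G1", "G2", "G3"],
        )
    )


def test_weight_vector_matches_hand_computation(bundle):
    expr = bundle.expression
    wv = build_weight_vector(bundle.model, expr, sf=1.0)
    # pick a replicated reaction with a known GPR and recompute by hand
    rid = "RBC__root__day"
    tree = parse_gpr(bundle.model.get_reaction(rid).gpr)
    weights = {
        g: gene_weight(expr.data.loc[g].to_dict(), "root")
        for g in ("RBC1", "RBC2")
    }
    expected = brute_force_combine(tree, weights)
    assert wv.base_weights[rid] == pytest.approx(expected, rel=1e-9)
    assert wv.coefficients[rid] == pytest.approx(apply_scaling(expected, 1.0), rel=1e-9)


def test_sf_zero_reduces_to_pfba_under_both_policies(bundle):
    for policy in ("unit", "tissue_median"):
        wv = build_weight_vector(bundle.model, bundle.expression, sf=0.0, gprless_policy=policy)
        assert all(c == pytest.approx(1.0) for c in wv.coefficients.values())


def test_reaction_peaking_in_own_tissue_gets_unit_weight(bundle):
    # every RBC gene peaks in leaf, so the leaf replica costs 1 at any SF
    for sf in (0.1, 1.0, 5.0):
        wv = build_weight_vector(bundle.model, bundle.expression, sf=sf)
        assert wv.coefficients["RBC__leaf__day"] == pytest.approx(1.0)
        assert wv.coefficients["RBC__leaf__night"] == pytest.approx(1.0)


def test_weights_at_least_one_and_shared_across_phases(bundle):
    wv = build_weight_vector(bundle.model, bundle.expression, sf=1.0)
    assert all(c >= 1.0 - 1e-12 for c in wv.coefficients.values())
    for rid, (cid, tissue, phase) in bundle.model.provenance.items():
        if phase == "day":
            other = rid.replace("__day", "__night")
            assert wv.coefficients[rid] == pytest.approx(wv.coefficients[other])


def test_tissue_median_policy_uses_home_tissue_median(bundle):
    wv = build_weight_vector(bundle.model, bundle.expression, sf=1.0, gprless_policy="tissue_median")
    # the leaf biomass drain has no GPR; its base weight must equal the
    # median base weight of the leaf's GPR-weighted reactions
    leaf_bases = [
        wv.base_weights[rid]
        for rid, flag in wv.flags.items()
        if flag == "gpr" and bundle.model.tissue_of(rid) == "leaf"
    ]
    assert wv.base_weights["BIO__leaf__day"] == pytest.approx(float(np.median(leaf_bases)))


def test_monotonicity_in_single_tissue_expression(bundle):
    """Lowering E_it for one gene never lowers weights that depend on it in t."""
    expr = bundle.expression
    rid = "RBC__root__day"
    base = build_weight_vector(bundle.model, expr, sf=1.0).coefficients[rid]
    df = expr.data.copy()
    df.loc[["RBC1", "RBC2"], "root"] = df.loc[["RBC1", "RBC2"], "root"] / 10.0
    lowered = build_weight_vector(bundle.model, ExpressionTable(df), sf=1.0).coefficients[rid]
    assert lowered >= base - 1e-12


def test_missing_model_tissue_is_config_error(bundle):
    df = bundle.expression.data.drop(columns=["root"])
    with pytest.raises(ConfigError, match="root"):
        build_weight_vector(bundle.model, ExpressionTable(df), sf=1.0)


def test_negative_abundance_rejected():
    with pytest.raises(ValueError, match="negative"):
        ExpressionTable(pd.DataFrame({"leaf": [-1.0]}, index=["G1"]))


# -- control transforms ------------------------------------------------------


def test_permutation_preserves_multiset_and_is_seeded(bundle):
    wv = build_weight_vector(bundle.model, bundle.expression, sf=1.0)
    p1 = randomize_weights(wv, seed=11)
    p2 = randomize_weights(wv, seed=11)
    p3 = randomize_weights(wv, seed=12)
    assert p1.coefficients == p2.coefficients
    assert p1.coefficients != p3.coefficients
    assert sorted(p1.coefficients.values()) == pytest.approx(sorted(wv.coefficients.values()))
    assert sum(p1.coefficients.values()) == pytest.approx(sum(wv.coefficients.values()))


def test_all_unit_vector_is_permutation_invariant(bundle):
    wv = build_weight_vector(bundle.model, bundle.expression, sf=0.0)
    assert randomize_weights(wv, seed=3).coefficients == wv.coefficients


def test_tissue_swap_is_an_involution():
    expr = hand_table()
    once = swap_tissue_expression(expr, "leaf", "root")
    twice = swap_tissue_expression(once, "leaf", "root")
    pd.testing.assert_frame_equal(twice.data, expr.data)
    pd.testing.assert_frame_equal(
        swap_tissue_expression(expr, "leaf", "leaf").data, expr.data
    )


def test_swap_moves_the_weight_one_tissue():
    expr = hand_table()
    assert gene_weight(expr.data.loc["G1"].to_dict(), "leaf") == pytest.approx(1.0)
    swapped = swap_tissue_expression(expr, "leaf", "root")
    assert gene_weight(swapped.data.loc["G1"].to_dict(), "root") == pytest.approx(1.0)
    assert gene_weight(swapped.data.loc["G1"].to_dict(), "leaf") == pytest.approx(4.0)


def test_swap_unknown_tissue_raises():
    with pytest.raises(KeyError):
        swap_tissue_expression(hand_table(), "leaf", "petal")
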
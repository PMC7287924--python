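"""Structural identifiability: correlation classification and sensitivities."""

import numpy as np
import pytest

from enoskit.identifiability import (classify, sensitivity_matrix,
                                     select_fit_parameters)
from enoskit.synthetic import generate_truth, DesignEntry


def test_product_degenerate_pair_is_flagged():
    """y(t) = a*b*exp(-t): the sensitivity columns of a and b are identical,
    |r| = 1, and both parameters are flagged at the 0.9 threshold."""
    t = np.linspace(0, 2, 5)
    col = np.exp(-t) * np.log(10)  # d y / d log10(a) = d y / d log10(b)
    S = np.column_stack([col, col])
    rep = classify(S, ("a", "b"), threshold=0.9)
    assert rep.unidentifiable_pairs
    a, b, r = rep.unidentifiable_pairs[0]
    assert {a, b} == {"a", "b"}
    assert abs(r) == pytest.approx(1.0)
    assert rep.identifiable == []


def test_orthogonal_columns_are_identifiable(rng):
    S = np.column_stack([np.sin(np.linspace(0, 6, 50)),
                         np.cos(np.linspace(0, 6, 50))])
    rep = classify(S, ("p", "q"))
    assert rep.identifiable == ["p", "q"]
    assert rep.unidentifiable_pairs == []
    assert np.allclose(np.diag(rep.correlation), 1.0)
    assert np.allclose(rep.correlation, rep.correlation.T)


def test_zero_variance_column_reported(model):
    S = np.column_stack([np.ones(10), np.arange(10.0)])
    rep = classify(S, ("dead", "alive"))
    assert rep.zero_variance == ["dead"]
    assert "dead" not in rep.identifiable


def test_report_invariant_to_output_rescaling():
    rng = np.random.default_rng(0)
    S = rng.normal(size=(30, 3))
    r1 = classify(S, ("a", "b", "c"))
    r2 = classify(S * 7.3, ("a", "b", "c"))
    np.testing.assert_allclose(r1.correlation, r2.correlation)


def test_parameter_without_path_gives_zero_column(model):
    """TSP1 binding constants cannot affect data measured at zero TSP1."""
    data = generate_truth(design=(DesignEntry("pR2", 50, (0, 5, 15)),),
                          model=model)
    S = sensitivity_matrix(model.network.params,
                           ("k_on_TSP1_CD47", "k_dephos_R2"),
                           tuple(data), model)
    rep = classify(S, ("k_on_TSP1_CD47", "k_dephos_R2"))
    assert rep.zero_variance == ["k_on_TSP1_CD47"]


def test_sensitivity_matrix_converges_under_step_halving(model):
    """Richardson check: halving the finite-difference step changes the
    sensitivities by well under 1%."""
    data = generate_truth(design=(DesignEntry("NO", 10, (0, 5, 15)),),
                          model=model)
    args = (model.network.params, ("k_clear_NO", "k_cat_eNOS_Hsp90"),
            tuple(data), model)
    S1 = sensitivity_matrix(*args, rel_step=0.02)
    S2 = sensitivity_matrix(*args, rel_step=0.01)
    scale = np.abs(S1).max()
    assert np.abs(S1 - S2).max() < 0.01 * scale


def test_fit_set_drops_one_member_per_correlated_pair():
    rep = classify(np.column_stack([np.arange(10.0), np.arange(10.0) * 2,
                                    np.sin(np.arange(10.0))]),
                   ("a", "b", "c"))
    assert {a for a, _, _ in rep.unidentifiable_pairs} == {"a"}
    chosen = select_fit_parameters(["a", "b", "c"], rep,
                                   st_values={"a": 0.5, "b": 0.3, "c": 0.2})
    assert chosen == ["a", "c"]  # b had the smaller index and is fixed
    # deterministic alphabetical tie-break without indices
    chosen2 = select_fit_parameters(["a", "b", "c"], rep)
    assert chosen2 == ["a", "c"]


def test_arginine_binding_constants_are_a_ratio_degeneracy(model):
    """k_on_Arg and k_off_Arg enter the kinetics only through their ratio
    (rapid-equilibrium K_Arg), so their sensitivity columns are exactly
    anti-collinear and both are flagged at the 0.9 threshold."""
    data = generate_truth(design=(DesignEntry("NO", 10, (0, 5, 15, 30)),),
                          model=model)
    S = sensitivity_matrix(model.network.params,
                           ("k_on_Arg", "k_off_Arg", "k_clear_NO"),
                           tuple(data), model)
    rep = classify(S, ("k_on_Arg", "k_off_Arg", "k_clear_NO"))
    flagged_pairs = {frozenset((a, b))
                     for a, b, _ in rep.unidentifiable_pairs}
    assert frozenset(("k_on_Arg", "k_off_Arg")) in flagged_pairs


def test_classify_needs_two_columns():
    with pytest.raises(ValueError):
        classify(np.ones((5, 1)), ("a",))
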
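"""eFAST sampling and index estimation on analytically known functions."""

import numpy as np
import pytest
from scipy import stats

from enoskit.efast import (EfastDesign, efast_sample, efast_indices,
                           select_influential, DUMMY)


@pytest.fixture(scope="module")
def toy_design():
    return EfastDesign(("p1", "p2", "p3"), np.array([0.1, 0.2, 0.5]),
                       np.array([10.0, 20.0, 50.0]), M=4, Ns=257, Nr=3)


def test_samples_stay_within_ranges(toy_design):
    s = efast_sample(toy_design, seed=0)
    flat = s.flat()
    for j in range(3):
        assert flat[:, j].min() >= toy_design.lower[j]
        assert flat[:, j].max() <= toy_design.upper[j]


def test_sampling_is_deterministic(toy_design):
    a = efast_sample(toy_design, seed=9).X
    b = efast_sample(toy_design, seed=9).X
    np.testing.assert_array_equal(a, b)
    c = efast_sample(toy_design, seed=10).X
    assert not np.array_equal(a, c)


def test_log_uniform_marginal_distribution():
    """KS distance of sampled log-values to uniform < 0.05 at >= 1e4 draws."""
    d = EfastDesign(("a", "b"), np.array([0.1, 0.1]), np.array([10.0, 10.0]),
                    M=4, Ns=257, Nr=40)
    s = efast_sample(d, seed=0)
    vals = np.log10(s.X[0][..., 0].ravel())
    assert len(vals) >= 1e4
    ks = stats.kstest(vals, "uniform", args=(-1.0, 2.0)).statistic
    assert ks < 0.05


def test_aliasing_guard():
    with pytest.raises(ValueError, match="aliasing"):
        EfastDesign(("a",), np.array([0.1]), np.array([1.0]), M=4, Ns=33)


def test_even_Ns_rejected():
    with pytest.raises(ValueError):
        EfastDesign(("a",), np.array([0.1]), np.array([1.0]), M=4, Ns=256)


def test_constant_output_gives_no_influential_parameters(toy_design):
    s = efast_sample(toy_design, seed=1)
    Y = np.ones((toy_design.n_params, toy_design.Nr, toy_design.Ns))
    rep = efast_indices(Y, s)
    assert np.all(rep.ST <= 1e-12)
    assert select_influential(rep, cutoff=0.0) == []  # nothing significant


def test_additive_linear_model_first_order_indices():
    """y = sum c_i x_i: S1_i proportional to c_i^2 Var(x_i)."""
    c = np.array([1.0, 2.0, 3.0])
    d = EfastDesign(("x1", "x2", "x3"), np.zeros(3), np.ones(3),
                    M=4, Ns=513, Nr=5, log_uniform=False)
    s = efast_sample(d, seed=3)
    Y = (s.X[..., :3] * c).sum(axis=-1)
    rep = efast_indices(Y, s)
    expected = c ** 2 / (c ** 2).sum()
    np.testing.assert_allclose(rep.S1[:3], expected, atol=0.03)
    # no interactions: totals equal first order
    np.testing.assert_allclose(rep.ST[:3], rep.S1[:3], atol=0.03)


def test_select_influential_cutoffs():
    d = EfastDesign(("x1", "x2", "x3"), np.zeros(3), np.ones(3),
                    M=4, Ns=257, Nr=3, log_uniform=False)
    s = efast_sample(d, seed=0)
    Y = (s.X[..., :3] * np.array([1.0, 2.0, 3.0])).sum(axis=-1)
    rep = efast_indices(Y, s)
    assert select_influential(rep, cutoff=1.1) == []
    assert select_influential(rep, cutoff=0.0,
                              require_significant=False) == \
        ["x1", "x2", "x3"]


def test_nonfinite_outputs_excluded_with_count(toy_design):
    s = efast_sample(toy_design, seed=2)
    Y = np.random.default_rng(0).normal(
        size=(toy_design.n_params, toy_design.Nr, toy_design.Ns))
    Y[0, 0, 5] = np.nan
    rep = efast_indices(Y, s)
    assert rep.n_excluded == 1


def test_dummy_parameter_is_bias_floor():
    """A zero-influence parameter is indistinguishable from the dummy."""
    d = EfastDesign(("active", "inert"), np.array([0.1, 0.1]),
                    np.array([10.0, 10.0]), M=4, Ns=513, Nr=5)
    s = efast_sample(d, seed=4)
    Y = np.log(s.X[..., 0])  # depends only on the first parameter
    rep = efast_indices(Y, s)
    names = list(d.all_names)
    i_inert, i_dummy = names.index("inert"), names.index(DUMMY)
    assert rep.ST[i_inert] < 0.02
    assert rep.p_vs_dummy[i_inert] > 0.05
    assert rep.p_vs_dummy[0] < 0.05
    assert select_influential(rep, cutoff=0.1) == ["active"]
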
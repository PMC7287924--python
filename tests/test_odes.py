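"""ODE right-hand side: fluxes, Jacobian, scaling laws, fixed point."""

import numpy as np
import pytest

from enoskit import Model, StimulusCondition, build_network, default_config
from enoskit.simulate import observable


def test_resting_state_is_fixed_point(model, rest_state):
    rhs = model.bind()
    dydt = rhs(0.0, rest_state)
    assert np.abs(dydt).max() < 1e-6  # nM/min


def test_serca_half_saturation_identity(model):
    """SERCA flux at Ca = K_M,SERCA equals I_SERCA/2 (Hill n=2)."""
    rhs = model.bind()
    params = model.network.params
    y = np.zeros(len(model.species))
    y[model.network.index["Ca_cyt"]] = params["K_M_SERCA"]
    v = rhs.fluxes(y)
    j = [r.name for r in model.network.reactions].index("serca_pump")
    assert v[j] == pytest.approx(params["I_SERCA"] / 2.0, rel=1e-12)


def test_cam_total_derivative_is_zero_along_any_state(model, rng):
    """d[CaM_total]/dt = 0: the stoichiometry-weighted flux sum over all
    CaM-containing states cancels exactly, for arbitrary states."""
    rhs = model.bind()
    w = model.compiled.conservation_vector("CaM")
    for _ in range(5):
        y = rng.uniform(0, 100, size=len(model.species))
        dydt = rhs(0.0, y)
        assert abs(w @ dydt) < 1e-9 * np.abs(dydt).max()


def test_volume_doubling_leaves_concentrations_invariant(model):
    """Doubling all compartment volumes (amounts scaled consistently, i.e.
    concentrations unchanged) must not change the trajectories."""
    cfg = default_config()
    for v in ("V_cyt", "V_ER", "V_ext"):
        cfg["geometry"][v] = cfg["geometry"][v] * 2.0
    m2 = Model(build_network(cfg))
    cond = StimulusCondition(vegf_nM=0.389, duration_min=10.0)
    r1 = model.simulate(cond)
    r2 = m2.simulate(cond)
    np.testing.assert_allclose(r1.concentrations, r2.concentrations,
                               rtol=1e-5, atol=1e-8)


def test_analytic_jacobian_matches_finite_differences(model, rng):
    rhs = model.bind()
    y = np.abs(model.pre_equilibrate()) + 1e-3
    y *= 1 + 1e-3 * rng.normal(size=len(y))
    J = rhs.jac(0.0, y)
    f0 = rhs(0.0, y)
    for j in rng.choice(len(y), size=12, replace=False):
        h = max(1e-6 * abs(y[j]), 1e-9)
        yp = y.copy()
        yp[j] += h
        ym = y.copy()
        ym[j] -= h
        col = (rhs(0.0, yp) - rhs(0.0, ym)) / (2 * h)
        np.testing.assert_allclose(J[:, j], col, rtol=5e-4,
                                   atol=1e-4 * max(np.abs(col).max(), 1.0))


def test_clamped_species_have_zero_derivative(model, rng):
    rhs = model.bind()
    y = rng.uniform(0, 1000, size=len(model.species))
    dydt = rhs(0.0, y)
    for name in ("PIP2", "Ca_ext", "GTP", "IP3R"):
        assert dydt[model.network.index[name]] == 0.0


def test_cycloheximide_zeroes_receptor_synthesis(model):
    params = model.network.params.with_values(k_syn_R2=0.0)
    rhs = model.bind(params)
    y = np.zeros(len(model.species))
    v = rhs.fluxes(y)
    j = [r.name for r in model.network.reactions].index("syn_r2")
    assert v[j] == 0.0
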
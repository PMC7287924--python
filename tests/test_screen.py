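"""Hill dose-to-fold mapping, AUC scoring, and screen consistency."""

import numpy as np
import pytest
from scipy.interpolate import CubicSpline
from scipy.integrate import quad

from enoskit import Model, StimulusCondition, observable
from enoskit.screen import (HillScaling, hill_factor, auc, run_screen,
                            combined_perturbation, PerturbationSpec,
                            TSP1_DOSES_NM, DIRECT_FOLDS)

try:
    from hypothesis import given, settings, strategies as st
    HAVE_HYPOTHESIS = True
except ImportError:  # pragma: no cover
    HAVE_HYPOTHESIS = False


def test_hill_factor_at_zero_dose_is_one():
    assert hill_factor(0.0) == 1.0


def test_hill_factor_half_max_identity():
    s = HillScaling(F_max=100.0, EC50_nM=0.022, n=1.0)
    assert s.f_positive(0.022) == pytest.approx(50.5)


def test_hill_factor_near_100_at_top_dose():
    assert hill_factor(2.2) == pytest.approx(100.0, rel=0.05)


def test_f_negative_is_reciprocal():
    s = HillScaling()
    for c in (0.0, 0.001, 0.022, 0.5, 2.2):
        assert s.f_negative(c) == pytest.approx(1.0 / s.f_positive(c))


if HAVE_HYPOTHESIS:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=100.0),
           st.floats(min_value=0.0, max_value=100.0))
    def test_hill_factor_is_monotone_in_dose(c1, c2):
        lo, hi = sorted((c1, c2))
        assert hill_factor(lo) <= hill_factor(hi) + 1e-12


def test_hill_scaling_validation():
    with pytest.raises(ValueError):
        HillScaling(F_max=0.5)
    with pytest.raises(ValueError):
        HillScaling(EC50_nM=-1.0)
    with pytest.raises(ValueError):
        hill_factor(-1.0)


def test_auc_of_constant_and_ramp(model):
    res = model.simulate(StimulusCondition(vegf_nM=0.0, duration_min=30.0))
    t = res.time_min
    const = res
    const.concentrations = np.ones_like(const.concentrations) * 2.0
    assert auc(const, "Ca_cyt", 30.0) == pytest.approx(60.0, rel=1e-9)
    ramp = res
    v = 4.0
    ramp.concentrations = np.tile((t / 30.0 * v)[:, None],
                                  (1, len(res.species)))
    assert auc(ramp, "Ca_cyt", 30.0) == pytest.approx(15.0 * v, rel=1e-9)


def test_auc_matches_adaptive_quadrature_on_cgmp(model):
    res = model.simulate(StimulusCondition(vegf_nM=0.389, duration_min=30.0))
    y = observable(res, "cGMP")
    spline = CubicSpline(res.time_min, y)
    ref, _ = quad(spline, 0.0, 30.0, limit=200)
    assert auc(res, "cGMP", 30.0) == pytest.approx(ref, rel=1e-3)


def test_auc_window_validation(model):
    res = model.simulate(StimulusCondition(vegf_nM=0.0, duration_min=10.0))
    with pytest.raises(ValueError):
        auc(res, "NO", 30.0)


def test_dose_grids_span_printed_ranges():
    assert TSP1_DOSES_NM[0] == pytest.approx(0.00022)
    assert TSP1_DOSES_NM[-1] == pytest.approx(2.2)
    assert len(TSP1_DOSES_NM) == 6
    assert DIRECT_FOLDS[0] == pytest.approx(2.0)
    assert DIRECT_FOLDS[-1] == pytest.approx(100.0)


def test_perturbation_direction_follows_tags(model):
    params = model.network.params
    assert PerturbationSpec.for_target("k_clear_NO", params).direction \
        == "positive"   # impedes signalling -> scaled up
    assert PerturbationSpec.for_target("k_cat_eNOS", params).direction \
        == "negative"   # promotes signalling -> scaled down
    assert PerturbationSpec.for_target("CaM", params).kind == "initial"
    with pytest.raises(ValueError):
        PerturbationSpec.for_target("n_CRAC", params)  # not perturbable
    with pytest.raises(ValueError):
        PerturbationSpec.for_target("unobtainium", params)


def test_unit_fold_gives_unit_fold_change(model):
    cond = StimulusCondition(vegf_nM=0.0003, duration_min=30.0)
    table = run_screen(["k_clear_NO"], cond, [model.network.params],
                       doses=(1.0,), mode="direct", model=model)
    assert np.allclose(table["mean_fold_change"], 1.0)
    assert not table["passes"].any()


def test_single_member_combined_matches_run_screen(model):
    cond = StimulusCondition(vegf_nM=0.0003, duration_min=30.0)
    fold = 10.0
    single = run_screen(["k_clear_NO"], cond, [model.network.params],
                        doses=(fold,), mode="direct", model=model)
    combo = combined_perturbation(("k_clear_NO",), fold, cond,
                                  [model.network.params], model=model)
    for out in ("Ca_cyt", "NO", "cGMP"):
        a = single[single["output"] == out]["mean_fold_change"].iloc[0]
        b = combo[combo["output"] == out]["mean_fold_change"].iloc[0]
        assert a == pytest.approx(b, rel=1e-9)


def test_empty_combined_set_is_baseline(model):
    cond = StimulusCondition(vegf_nM=0.0003, duration_min=30.0)
    table = combined_perturbation((), 10.0, cond, [model.network.params],
                                  model=model)
    assert np.allclose(table["mean_fold_change"], 1.0)


def test_unsorted_doses_rejected(model):
    cond = StimulusCondition(vegf_nM=0.0003, duration_min=30.0)
    with pytest.raises(ValueError):
        run_screen(["k_clear_NO"], cond, [model.network.params],
                   doses=(2.0, 1.0), mode="direct", model=model)
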
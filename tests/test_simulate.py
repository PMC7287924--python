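"""Stimulus-response behaviour of the calibrated default model."""

import numpy as np
import pytest

from enoskit import Model, StimulusCondition, observable, SEED_SPECIES
from enoskit.simulate import OBSERVABLES

PRINTED_DOSES = (0.0003, 0.008, 0.389, 1.1)


def test_unstimulated_trajectories_are_flat(model, rest_state):
    res = model.simulate(StimulusCondition(vegf_nM=0.0, tsp1_nM=0.0,
                                           duration_min=30.0))
    drift = np.abs(res.concentrations - res.concentrations[0])
    scale = np.maximum(np.abs(res.concentrations[0]), 1.0)
    assert (drift / scale).max() < 1e-4


def test_resting_calcium_is_50_nM(model, rest_state):
    ca = rest_state[model.network.index["Ca_cyt"]]
    assert ca == pytest.approx(50.0, rel=0.01)


def test_peak_pR2_fraction_monotone_in_vegf(model):
    peaks = []
    for dose in PRINTED_DOSES:
        res = model.simulate(StimulusCondition(vegf_nM=dose,
                                               duration_min=60.0))
        frac = observable(res, "pR2") / np.maximum(
            observable(res, "memR2"), 1e-12)
        peaks.append(frac.max())
    assert all(a < b for a, b in zip(peaks, peaks[1:]))


def test_tsp1_sequesters_vegf_bound_receptor(model):
    """At fixed VEGF, peak VEGF-bound R2 is non-increasing in TSP1 dose."""
    peaks = []
    for tsp1 in (0.0, 0.022, 2.2, 22.0):
        res = model.simulate(StimulusCondition(
            vegf_nM=0.389, tsp1_nM=tsp1, duration_min=30.0))
        peaks.append(observable(res, "boundR2").max())
    assert all(a >= b - 1e-12 for a, b in zip(peaks, peaks[1:]))
    assert peaks[-1] < 0.9 * peaks[0]


def test_totR2_monotone_decay_under_cycloheximide(model):
    res = model.simulate(StimulusCondition(
        vegf_nM=0.0, cycloheximide=True, duration_min=60.0))
    tot = observable(res, "totR2")
    assert np.all(np.diff(tot) <= 1e-9)
    assert tot[-1] < tot[0]


def test_observable_of_absent_states_is_zero(model):
    """peNOS before any stimulation stays identically zero."""
    res = model.simulate(StimulusCondition(vegf_nM=0.0, duration_min=10.0))
    np.testing.assert_allclose(observable(res, "peNOS"), 0.0, atol=1e-9)


def test_unknown_observable_raises(model):
    res = model.simulate(StimulusCondition(vegf_nM=0.0, duration_min=1.0))
    with pytest.raises(KeyError):
        observable(res, "not_an_observable")


def test_all_observables_resolve_to_existing_species(model):
    for name, species in OBSERVABLES.items():
        for sp in species:
            assert sp in model.network.index, (name, sp)


def test_concentrations_stay_nonnegative(model):
    for dose in PRINTED_DOSES:
        res = model.simulate(StimulusCondition(vegf_nM=dose,
                                               duration_min=60.0))
        assert res.concentrations.min() >= -1e-9


def test_condition_validation():
    with pytest.raises(ValueError):
        StimulusCondition(vegf_nM=-1.0)
    with pytest.raises(ValueError):
        StimulusCondition(duration_min=0.0)


def test_t_grid_outside_duration_rejected(model):
    with pytest.raises(ValueError):
        model.simulate(StimulusCondition(vegf_nM=0.1, duration_min=10.0),
                       t_grid=np.array([0.0, 20.0]))


def test_simulation_is_deterministic(model):
    cond = StimulusCondition(vegf_nM=0.389, duration_min=10.0)
    r1 = model.simulate(cond)
    r2 = model.simulate(cond)
    np.testing.assert_array_equal(r1.concentrations, r2.concentrations)
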
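"""Calibration objective, normalization matching, and small fits."""

import numpy as np
import pytest

from enoskit.calibration import (FitProblem, FitResult, FitEnsemble,
                                 objective, fit_multistart, validate)
from enoskit.synthetic import (generate_truth, simulate_design,
                               DEFAULT_VALIDATION_DESIGN, NORMALIZED,
                               ABSOLUTE)

FREE = ("k_int_VR2", "k_deg_IP3", "I_IP3R", "I_SERCA", "k_cat_sGC")


@pytest.fixture(scope="module")
def log_truth(model):
    """Truth parameters defined via the log10 round trip, so the optimizer's
    coordinate at truth reproduces the generating parameters bit-exactly."""
    shell = FitProblem(free_names=FREE, datasets=(),
                       base_params=model.network.params)
    return shell.params_from(shell.x0_log10)


@pytest.fixture(scope="module")
def problem(model, log_truth):
    data = generate_truth(log_truth, model=model)
    return FitProblem(free_names=FREE, datasets=tuple(data),
                      base_params=log_truth)


def test_objective_is_zero_at_truth(model, problem):
    assert objective(problem.x0_log10, problem, model) < 1e-10


def test_normalization_matches_data_scaling(model, problem):
    """For a normalized dataset the simulated curve is divided by its own
    maximum over the dataset's time points, so residuals are invariant to
    any overall rescaling of the observable."""
    sims = simulate_design(problem.base_params, problem.datasets, model)
    for ds in problem.datasets:
        if ds.value_kind == NORMALIZED and sims[ds.dataset_id].max() > 0:
            assert sims[ds.dataset_id].max() == pytest.approx(1.0)
        elif ds.value_kind == ABSOLUTE:
            assert sims[ds.dataset_id].max() > 1.0  # stays in nM


def test_objective_increases_away_from_truth(model, problem):
    """Pushing the sGC catalytic rate to its lower bound must worsen the
    cGMP fit."""
    x = problem.x0_log10.copy()
    i = problem.free_names.index("k_cat_sGC")
    x[i] = problem.bounds_log10[0][i]
    assert objective(x, problem, model) > \
        objective(problem.x0_log10, problem, model) + 1e-3


def test_single_start_from_truth_recovers_zero_objective(model, problem):
    ens = fit_multistart(problem, n_starts=1, seed=0, k=1, model=model,
                         include_baseline_start=True, max_nfev=5)
    assert ens.best.objective < 1e-10
    assert len(ens.top()) == 1


def test_fit_problem_validation(model):
    with pytest.raises(KeyError):
        FitProblem(free_names=("nope",), datasets=(),
                   base_params=model.network.params)
    with pytest.raises(ValueError):
        FitProblem(free_names=("k_p_Src", "k_p_Src"), datasets=(),
                   base_params=model.network.params)
    with pytest.raises(ValueError):
        FitProblem(free_names=("k_p_Src",), datasets=(),
                   base_params=model.network.params, bounds_decades=0.0)


def test_ensemble_must_be_sorted(model):
    prob = FitProblem(free_names=("k_p_Src",), datasets=(),
                      base_params=model.network.params)
    bad = [FitResult(np.array([0.0]), 2.0, 0, True),
           FitResult(np.array([0.0]), 1.0, 1, True)]
    with pytest.raises(ValueError):
        FitEnsemble(results=bad, problem=prob, k=1)


def test_validate_rejects_overlap_and_handles_empty(model, problem):
    ens = fit_multistart(problem, n_starts=1, seed=0, k=1, model=model,
                         include_baseline_start=True, max_nfev=3)
    with pytest.raises(ValueError):
        validate(ens, problem.datasets[:1], model)
    assert validate(ens, (), model) == {}


def test_validation_band_covers_truth_holdout(model, problem, log_truth):
    """An ensemble at truth predicts noise-free hold-out data exactly."""
    holdout = generate_truth(log_truth, design=DEFAULT_VALIDATION_DESIGN,
                             model=model, parameter_set_id="holdout",
                             id_prefix="val")
    ens = fit_multistart(problem, n_starts=1, seed=0, k=1, model=model,
                         include_baseline_start=True, max_nfev=3)
    report = validate(ens, tuple(holdout), model)
    assert len(report) == 4
    for entry in report.values():
        assert entry["rmse"] < 1e-6
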
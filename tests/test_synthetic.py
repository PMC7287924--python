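"""Synthetic time-course generation, noise model, and CSV round trip."""

import numpy as np
import pytest

from enoskit.synthetic import (
    DEFAULT_TRAINING_DESIGN, DEFAULT_VALIDATION_DESIGN, DesignEntry,
    NoiseModel, TimeCourseDataset, TimecourseParseError, corrupt,
    corrupt_all, generate_truth, read_timecourse_csv, total_points,
    write_timecourse_csv, NORMALIZED, ABSOLUTE)


def test_default_design_is_14_datasets_58_points(truth_datasets):
    assert len(truth_datasets) == 14
    assert total_points(truth_datasets) == 58


def test_validation_design_is_four_independent_datasets():
    assert len(DEFAULT_VALIDATION_DESIGN) == 4
    train = {(e.observable, e.vegf_ng_ml, e.cycloheximide)
             for e in DEFAULT_TRAINING_DESIGN}
    val = {(e.observable, e.vegf_ng_ml, e.cycloheximide)
           for e in DEFAULT_VALIDATION_DESIGN}
    assert not train & val


def test_normalized_truth_has_unit_maximum(truth_datasets):
    for ds in truth_datasets:
        if ds.value_kind == NORMALIZED:
            assert ds.values.max() == pytest.approx(1.0, abs=1e-12)


def test_absolute_species_keep_nanomolar_units(truth_datasets):
    kinds = {ds.observable: ds.value_kind for ds in truth_datasets}
    for obs in ("Ca_cyt", "IP3", "cGMP"):
        assert kinds[obs] == ABSOLUTE
    ca = next(ds for ds in truth_datasets if ds.observable == "Ca_cyt")
    assert ca.values[0] == pytest.approx(50.0, rel=0.02)


def test_pR2_without_vegf_is_identically_zero(model):
    entry = DesignEntry("pR2", 0.0, (0, 5, 15, 30))
    (ds,) = generate_truth(design=(entry,), model=model)
    np.testing.assert_allclose(ds.values, 0.0, atol=1e-12)


def test_corrupt_with_zero_sigma_is_identity(truth_datasets):
    ds = truth_datasets[0]
    out = corrupt(ds, NoiseModel(sigma=0.0, seed=5))
    np.testing.assert_array_equal(out.values, ds.values)


def test_corrupt_is_deterministic_under_seed(truth_datasets):
    ds = truth_datasets[2]
    a = corrupt(ds, NoiseModel(sigma=0.15, seed=7))
    b = corrupt(ds, NoiseModel(sigma=0.15, seed=7))
    np.testing.assert_array_equal(a.values, b.values)
    c = corrupt(ds, NoiseModel(sigma=0.15, seed=8))
    assert not np.array_equal(a.values, c.values)


def test_corrupt_renormalizes_normalized_datasets(truth_datasets):
    ds = next(d for d in truth_datasets if d.value_kind == NORMALIZED)
    out = corrupt(ds, NoiseModel(sigma=0.3, seed=1))
    assert out.values.max() == pytest.approx(1.0, abs=1e-12)


def test_lognormal_noise_scale_matches_sigma():
    """Monte-Carlo: sample sd of log noise within 10% of sigma = 0.15."""
    base = TimeCourseDataset(
        dataset_id="mc", observable="NO", time_min=np.array([1.0]),
        values=np.array([2.0]), value_kind=ABSOLUTE, vegf_nM=0.1)
    sigma = 0.15
    logs = [np.log(corrupt(base, NoiseModel(sigma, seed=s)).values[0] / 2.0)
            for s in range(1000)]
    assert np.std(logs) == pytest.approx(sigma, rel=0.10)


def test_csv_round_trip(tmp_path, truth_datasets):
    noisy = corrupt_all(truth_datasets, 0.15, master_seed=42)
    path = tmp_path / "tc.csv"
    write_timecourse_csv(noisy, path)
    back = read_timecourse_csv(path)
    assert len(back) == len(noisy)
    for a, b in zip(noisy, back):
        assert a == b


def test_negative_time_raises_parse_error(tmp_path, truth_datasets):
    path = tmp_path / "bad.csv"
    write_timecourse_csv(truth_datasets[:1], path)
    text = path.read_text().splitlines()
    text[1] = text[1].replace("0.0,", "-1.0,", 1)
    path.write_text("\n".join(text))
    with pytest.raises(TimecourseParseError, match="line"):
        read_timecourse_csv(path)


def test_missing_column_raises(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("dataset_id,observable\nx,NO\n")
    with pytest.raises(TimecourseParseError, match="missing"):
        read_timecourse_csv(path)


def test_dataset_invariants():
    with pytest.raises(ValueError):
        TimeCourseDataset("x", "NO", np.array([-1.0]), np.array([1.0]),
                          ABSOLUTE, 0.1)
    with pytest.raises(ValueError):
        TimeCourseDataset("x", "NO", np.array([0.0, 1.0]), np.array([1.0]),
                          ABSOLUTE, 0.1)
    with pytest.raises(ValueError):
        TimeCourseDataset("x", "NO", np.array([0.0]), np.array([1.0]),
                          "bad_kind", 0.1)
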
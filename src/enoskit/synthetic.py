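"""Synthetic normalized time-course data.

The original calibration data were densitometry/assay time courses digitized
from six published HUVEC studies (14 training sets, 58 points, plus four
validation sets) and are not deposited anywhere.  This module generates
datasets with the same structure from the model itself: simulate an
observable under each study's stimulus condition, sample it at
experiment-like time points, normalize to the within-dataset maximum where
the original units were arbitrary (Western blots), and corrupt with
multiplicative lognormal noise emulating densitometry error.

Ca2+, IP3 and cGMP are kept in absolute nM, as the original assays were
calibrated; everything else is normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .parameters import NG_PER_ML_TO_NM_VEGF, ParameterSet
from .simulate import Model, StimulusCondition, observable

NORMALIZED = "normalized_to_max"
ABSOLUTE = "absolute_nM"

DEFAULT_SIGMA = 0.15  # typical densitometry CV


@dataclass(frozen=True)
class DesignEntry:
    observable: str
    vegf_ng_ml: float
    times_min: tuple[float, ...]
    value_kind: str = NORMALIZED
    cycloheximide: bool = False

    @property
    def vegf_nM(self) -> float:
        return self.vegf_ng_ml * NG_PER_ML_TO_NM_VEGF


# Training design: 14 datasets, 58 points, mirroring receptor dynamics
# (+/- cycloheximide), the kinase cascade, and the Ca/NO/cGMP outputs.
DEFAULT_TRAINING_DESIGN: tuple[DesignEntry, ...] = (
    DesignEntry("totR2", 50, (0, 5, 15, 30, 60)),
    DesignEntry("memR2", 50, (0, 5, 15, 30, 60)),
    DesignEntry("pR2", 50, (0, 2, 5, 10, 30)),
    DesignEntry("totR2", 0, (0, 30, 60)),
    DesignEntry("totR2", 0, (0, 15, 30, 60), cycloheximide=True),
    DesignEntry("totR2", 50, (0, 15, 30, 60), cycloheximide=True),
    DesignEntry("pSrc", 2.5, (0, 2, 5, 10)),
    DesignEntry("pAkt", 50, (0, 2, 5, 15, 30)),
    DesignEntry("peNOS", 50, (0, 5, 15, 30)),
    DesignEntry("pPLCg", 80, (0, 2, 5, 10)),
    DesignEntry("NO", 10, (0, 5, 15, 30)),
    DesignEntry("IP3", 10, (0, 1, 3, 10), value_kind=ABSOLUTE),
    DesignEntry("Ca_cyt", 10, (0, 1, 3, 5), value_kind=ABSOLUTE),
    DesignEntry("cGMP", 30, (0, 10, 30), value_kind=ABSOLUTE),
)

# Hold-out design: four independent datasets used only for validation.
DEFAULT_VALIDATION_DESIGN: tuple[DesignEntry, ...] = (
    DesignEntry("pSrc", 50, (0, 2, 5, 10)),
    DesignEntry("pPLCg", 50, (0, 2, 5, 10)),
    DesignEntry("pR2", 25, (0, 2, 5, 10, 30)),
    DesignEntry("pAkt", 10, (0, 5, 15, 30)),
)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal noise: value -> value * exp(N(0, sigma^2))."""
    sigma: float = DEFAULT_SIGMA
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class TimeCourseDataset:
    dataset_id: str
    observable: str
    time_min: np.ndarray
    values: np.ndarray
    value_kind: str
    vegf_nM: float
    tsp1_nM: float = 0.0
    cycloheximide: bool = False
    noise_sigma: float = 0.0
    truth_parameter_set_id: str | None = None

    def __post_init__(self):
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_min.min() < 0:
            raise ValueError(f"{self.dataset_id}: negative time")
        if np.any(np.diff(self.time_min) < 0):
            raise ValueError(f"{self.dataset_id}: times must be sorted")
        if len(self.time_min) != len(self.values):
            raise ValueError(f"{self.dataset_id}: length mismatch")
        if self.value_kind not in (NORMALIZED, ABSOLUTE):
            raise ValueError(f"{self.dataset_id}: bad value_kind")

    @property
    def n_points(self) -> int:
        return len(self.values)

    @property
    def condition(self) -> StimulusCondition:
        duration = max(float(self.time_min.max()), 1.0)
        return StimulusCondition(vegf_nM=self.vegf_nM, tsp1_nM=self.tsp1_nM,
                                 cycloheximide=self.cycloheximide,
                                 duration_min=duration)

    def __eq__(self, other):
        if not isinstance(other, TimeCourseDataset):
            return NotImplemented
        return (self.dataset_id == other.dataset_id
                and self.observable == other.observable
                and self.value_kind == other.value_kind
                and self.cycloheximide == other.cycloheximide
                and np.allclose(self.vegf_nM, other.vegf_nM)
                and np.allclose(self.tsp1_nM, other.tsp1_nM)
                and np.array_equal(self.time_min, other.time_min)
                and np.allclose(self.values, other.values, rtol=1e-12))


# signals below this level (nM) are treated as identically zero when
# normalizing -- safely above the integrator's absolute tolerance and far
# below any real signal maximum
ZERO_SIGNAL_NM = 1e-6


def _normalize(values: np.ndarray) -> np.ndarray:
    m = values.max()
    return values / m if m > ZERO_SIGNAL_NM else np.zeros_like(values)


def _group_datasets(datasets):
    """Group by stimulus condition so each is simulated once per theta."""
    groups: dict[tuple, list[TimeCourseDataset]] = {}
    for ds in datasets:
        key = (ds.vegf_nM, ds.tsp1_nM, ds.cycloheximide)
        groups.setdefault(key, []).append(ds)
    return groups


def simulate_design(params: ParameterSet,
                    datasets: tuple,
                    model: Model) -> dict[str, np.ndarray]:
    """Normalization-matched model predictions at each dataset's times.

    This single prediction path is shared by the truth generator, the
    calibration objective and the identifiability sensitivities, so a fit
    at the true parameters reproduces noise-free synthetic data exactly.
    """
    out = {}
    for key, group in _group_datasets(datasets).items():
        vegf, tsp1, chx = key
        t_max = max(float(ds.time_min.max()) for ds in group)
        t_union = np.unique(np.concatenate(
            [ds.time_min for ds in group] + [np.array([0.0, t_max])]))
        if t_union[-1] == 0.0:
            t_union = np.array([0.0, 1.0])
        cond = StimulusCondition(vegf_nM=vegf, tsp1_nM=tsp1,
                                 cycloheximide=chx,
                                 duration_min=max(t_max, 1.0))
        res = model.simulate(cond, params, t_grid=t_union)
        for ds in group:
            y = observable(res, ds.observable)
            sim = np.interp(ds.time_min, res.time_min, y)
            if ds.value_kind == NORMALIZED:
                sim = _normalize(sim)
            out[ds.dataset_id] = sim
    return out


def generate_truth(params: ParameterSet | None = None,
                   design: tuple[DesignEntry, ...] = DEFAULT_TRAINING_DESIGN,
                   model: Model | None = None,
                   parameter_set_id: str = "truth",
                   id_prefix: str = "ds") -> list[TimeCourseDataset]:
    """Noise-free datasets simulated from the model at ``params``."""
    model = model or Model()
    params = params or model.network.params
    skeletons = [
        TimeCourseDataset(
            dataset_id=f"{id_prefix}{i + 1:02d}_{entry.observable}",
            observable=entry.observable,
            time_min=np.array(entry.times_min, dtype=float),
            values=np.zeros(len(entry.times_min)),
            value_kind=entry.value_kind,
            vegf_nM=entry.vegf_nM, cycloheximide=entry.cycloheximide,
            truth_parameter_set_id=parameter_set_id)
        for i, entry in enumerate(design)]
    sims = simulate_design(params, tuple(skeletons), model)
    return [replace(ds, values=sims[ds.dataset_id]) for ds in skeletons]


def corrupt(truth: TimeCourseDataset,
            noise: NoiseModel) -> TimeCourseDataset:
    """Apply multiplicative lognormal noise (deterministic under seed).

    Normalized datasets are re-normalized to their post-noise maximum,
    mirroring how arbitrary-unit data are scaled after measurement.
    """
    rng = np.random.default_rng(noise.seed)
    eps = rng.normal(0.0, noise.sigma, size=truth.n_points)
    values = truth.values * np.exp(eps)
    if truth.value_kind == NORMALIZED:
        values = _normalize(values)
    return replace(truth, values=values, noise_sigma=noise.sigma)


def corrupt_all(truth: list[TimeCourseDataset], sigma: float,
                master_seed: int) -> list[TimeCourseDataset]:
    """Corrupt every dataset with an independent stream off one master seed."""
    seeds = np.random.SeedSequence(master_seed).generate_state(len(truth))
    return [corrupt(ds, NoiseModel(sigma, int(s) % (2 ** 31)))
            for ds, s in zip(truth, seeds)]


# ---------------------------------------------------------------------------
# CSV round trip (tidy schema)
# ---------------------------------------------------------------------------

CSV_COLUMNS = ["dataset_id", "observable", "time_min", "value", "value_kind",
               "vegf_nM", "tsp1_nM", "chx", "noise_sigma"]


class TimecourseParseError(ValueError):
    pass


def write_timecourse_csv(datasets: list[TimeCourseDataset],
                         path) -> None:
    rows = []
    for ds in datasets:
        for t, v in zip(ds.time_min, ds.values):
            rows.append({
                "dataset_id": ds.dataset_id, "observable": ds.observable,
                "time_min": t, "value": v, "value_kind": ds.value_kind,
                "vegf_nM": ds.vegf_nM, "tsp1_nM": ds.tsp1_nM,
                "chx": ds.cycloheximide, "noise_sigma": ds.noise_sigma,
            })
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def read_timecourse_csv(path) -> list[TimeCourseDataset]:
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise TimecourseParseError(f"missing columns: {sorted(missing)}")
    datasets = []
    for ds_id, g in df.groupby("dataset_id", sort=False):
        g = g.reset_index()
        for col, check, msg in (
                ("time_min", lambda x: x < 0, "negative time"),
                ("value", lambda x: ~np.isfinite(x), "non-finite value")):
            bad = g[check(g[col].to_numpy())]
            if len(bad):
                line = int(bad["index"].iloc[0]) + 2  # header + 1-based
                raise TimecourseParseError(
                    f"{msg} in dataset {ds_id} (line {line})")
        first = g.iloc[0]
        try:
            datasets.append(TimeCourseDataset(
                dataset_id=str(ds_id), observable=str(first["observable"]),
                time_min=g["time_min"].to_numpy(),
                values=g["value"].to_numpy(),
                value_kind=str(first["value_kind"]),
                vegf_nM=float(first["vegf_nM"]),
                tsp1_nM=float(first["tsp1_nM"]),
                cycloheximide=bool(first["chx"]),
                noise_sigma=float(first["noise_sigma"])))
        except ValueError as e:
            raise TimecourseParseError(str(e)) from e
    return datasets


def total_points(datasets: list[TimeCourseDataset]) -> int:
    return sum(ds.n_points for ds in datasets)
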
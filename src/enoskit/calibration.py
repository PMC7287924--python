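"""Multi-start least-squares calibration against normalized time courses.

Parameters are estimated in log10 space within bounds of +/- one decade
around their baseline values.  The objective applies the same normalization
to the simulated curve as was applied to the data: for arbitrary-unit
(normalized) datasets the simulated observable is divided by its own maximum
over the dataset's time points, which makes the residuals invariant to any
overall scaling of that observable.  Residuals are weighted 1/n per dataset
so that densely sampled curves do not dominate.

The multi-start strategy draws Latin-hypercube start points in log space,
polishes each with bounded trust-region least squares, and keeps the top-k
fits ("best-fit ensemble") for downstream prediction bands and screens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .parameters import ParameterSet
from .simulate import Model
from .synthetic import TimeCourseDataset, simulate_design

PENALTY_RESIDUAL = 1e3
DEFAULT_TOP_K = 19


@dataclass(frozen=True)
class FitProblem:
    free_names: tuple[str, ...]
    datasets: tuple[TimeCourseDataset, ...]
    base_params: ParameterSet
    bounds_decades: float = 1.0  # log10 half-width around baseline

    def __post_init__(self):
        for name in self.free_names:
            if name not in self.base_params:
                raise KeyError(f"unknown parameter {name}")
            if self.base_params[name] <= 0:
                raise ValueError(f"{name}: baseline must be positive to fit "
                                 "in log space")
        if len(set(self.free_names)) != len(self.free_names):
            raise ValueError("duplicate free parameters")
        if self.bounds_decades <= 0:
            raise ValueError("bounds must have positive width")

    @property
    def x0_log10(self) -> np.ndarray:
        return np.log10([self.base_params[n] for n in self.free_names])

    @property
    def bounds_log10(self) -> tuple[np.ndarray, np.ndarray]:
        x0 = self.x0_log10
        return x0 - self.bounds_decades, x0 + self.bounds_decades

    def params_from(self, x_log10: np.ndarray) -> ParameterSet:
        values = {n: 10.0 ** v for n, v in zip(self.free_names, x_log10)}
        return self.base_params.with_values(**values)


@dataclass
class FitResult:
    x_log10: np.ndarray
    objective: float
    start_index: int
    converged: bool
    n_evaluations: int = 0

    def params(self, problem: FitProblem) -> ParameterSet:
        return problem.params_from(self.x_log10)

    def values(self, problem: FitProblem) -> dict[str, float]:
        return {n: 10.0 ** v
                for n, v in zip(problem.free_names, self.x_log10)}


@dataclass
class FitEnsemble:
    results: list[FitResult]          # sorted ascending by objective
    problem: FitProblem
    k: int

    def __post_init__(self):
        objs = [r.objective for r in self.results]
        if objs != sorted(objs):
            raise ValueError("ensemble must be sorted by objective")
        if self.k > len(self.results):
            raise ValueError("k exceeds number of fits")

    @property
    def best(self) -> FitResult:
        return self.results[0]

    def top(self) -> list[FitResult]:
        return self.results[:self.k]

    def parameter_sets(self) -> list[ParameterSet]:
        return [r.params(self.problem) for r in self.top()]

    def median_values(self) -> dict[str, float]:
        tops = np.array([r.x_log10 for r in self.top()])
        med = np.median(tops, axis=0)
        return {n: 10.0 ** v
                for n, v in zip(self.problem.free_names, med)}


def residuals(x_log10: np.ndarray, problem: FitProblem,
              model: Model) -> np.ndarray:
    """Stacked, 1/sqrt(n)-weighted residual vector (penalized on failure)."""
    n_total = sum(ds.n_points for ds in problem.datasets)
    try:
        params = problem.params_from(x_log10)
        sims = simulate_design(params, problem.datasets, model)
    except Exception:
        return np.full(n_total, PENALTY_RESIDUAL)
    parts = []
    for ds in problem.datasets:
        # per-dataset weight 1/n, with residuals made dimensionless by the
        # dataset's own maximum so absolute-unit series (nM) and normalized
        # series contribute comparably
        scale = max(float(np.abs(ds.values).max()), 1e-12)
        w = 1.0 / (np.sqrt(ds.n_points) * scale)
        parts.append(w * (sims[ds.dataset_id] - ds.values))
    return np.concatenate(parts)


def objective(x_log10: np.ndarray, problem: FitProblem,
              model: Model | None = None) -> float:
    """Per-dataset-weighted sum of squared residuals."""
    model = model or Model()
    r = residuals(np.asarray(x_log10, dtype=float), problem, model)
    return float(r @ r)


def fit_multistart(problem: FitProblem, n_starts: int = 20,
                   seed: int = 0, k: int = DEFAULT_TOP_K,
                   model: Model | None = None,
                   max_nfev: int = 80,
                   include_baseline_start: bool = False,
                   n_polish: int | None = None,
                   tol: float = 1e-8) -> FitEnsemble:
    """Latin-hypercube multi-start bounded least squares; top-k ensemble.

    When ``n_polish`` is given, the objective is first evaluated once at
    every start and only the ``n_polish`` most promising starts receive the
    full trust-region polish; the rest enter the ranking with their start
    objective.  This spends the simulation budget where it matters without
    changing which basin the best fit comes from.
    """
    if n_starts < 1:
        raise ValueError("need at least one start")
    model = model or Model()
    lo, hi = problem.bounds_log10
    sampler = qmc.LatinHypercube(d=len(problem.free_names), seed=seed)
    starts = qmc.scale(sampler.random(n_starts), lo, hi)
    if include_baseline_start:
        starts[0] = problem.x0_log10

    indexed = list(enumerate(starts))
    screened_out = []
    if n_polish is not None and n_polish < n_starts:
        scored = []
        for i, x0 in indexed:
            r = residuals(x0, problem, model)
            scored.append((float(r @ r), i, x0))
        scored.sort(key=lambda s: s[0])
        indexed = [(i, x0) for _, i, x0 in scored[:n_polish]]
        screened_out = [FitResult(x_log10=np.asarray(x0), objective=obj,
                                  start_index=i, converged=False,
                                  n_evaluations=1)
                        for obj, i, x0 in scored[n_polish:]]

    results = []
    for i, x0 in indexed:
        try:
            sol = least_squares(
                residuals, x0, bounds=(lo, hi), args=(problem, model),
                method="trf", xtol=tol, ftol=tol, gtol=tol,
                max_nfev=max_nfev, diff_step=1e-4)
            results.append(FitResult(
                x_log10=sol.x, objective=float(sol.cost * 2.0),
                start_index=i, converged=bool(sol.status > 0),
                n_evaluations=int(sol.nfev)))
        except Exception:
            continue
    if not results:
        raise RuntimeError("all optimization starts failed")
    results.extend(screened_out)
    results.sort(key=lambda r: r.objective)
    k_eff = min(k, len(results))
    return FitEnsemble(results=results, problem=problem, k=k_eff)


def validate(ensemble: FitEnsemble,
             holdout: tuple[TimeCourseDataset, ...],
             model: Model | None = None) -> dict:
    """Mean +/- SD prediction bands over the ensemble on hold-out data."""
    model = model or Model()
    train_ids = {ds.dataset_id for ds in ensemble.problem.datasets}
    overlap = train_ids & {ds.dataset_id for ds in holdout}
    if overlap:
        raise ValueError(f"holdout overlaps training: {sorted(overlap)}")
    report = {}
    if not holdout:
        return report
    member_sims = [simulate_design(r.params(ensemble.problem), tuple(holdout),
                                   model) for r in ensemble.top()]
    for ds in holdout:
        curves = np.array([sims[ds.dataset_id] for sims in member_sims])
        mean = curves.mean(axis=0)
        sd = curves.std(axis=0, ddof=1) if len(curves) > 1 \
            else np.zeros_like(mean)
        resid = mean - ds.values
        inside = np.abs(resid) <= np.maximum(sd, 1e-12)
        report[ds.dataset_id] = {
            "time_min": ds.time_min, "observed": ds.values,
            "mean": mean, "sd": sd,
            "rmse": float(np.sqrt(np.mean(resid ** 2))),
            "coverage_1sd": float(np.mean(inside)),
        }
    return report
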
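"""A-priori structural identifiability screen via sensitivity correlations.

Whether two parameters can be separated by a calibration design is judged
from the local sensitivity matrix: column j is the central finite-difference
derivative of the stacked, normalization-matched model outputs with respect
to log10 of parameter j.  If two columns are collinear (|Pearson r| >= 0.9
by default) the data constrain only a combination of the pair, and one
member must be fixed before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .parameters import ParameterSet
from .simulate import Model
from .synthetic import TimeCourseDataset, simulate_design

DEFAULT_THRESHOLD = 0.9


def _stack(sims: dict[str, np.ndarray],
           datasets: tuple[TimeCourseDataset, ...]) -> np.ndarray:
    return np.concatenate([sims[ds.dataset_id] for ds in datasets])


def sensitivity_matrix(params: ParameterSet,
                       free_names: tuple[str, ...],
                       datasets: tuple[TimeCourseDataset, ...],
                       model: Model | None = None,
                       rel_step: float = 0.01) -> np.ndarray:
    """Central-difference d(output)/d(log10 p) over the fitting design.

    A failed integration at a perturbed point degrades that column to a
    one-sided difference (with a warning).
    """
    model = model or Model()
    h = np.log10(1.0 + rel_step)  # ~1% relative step in log10 space
    y0 = None
    cols = []
    for name in free_names:
        p = params[name]
        up = params.with_values(**{name: 10 ** (np.log10(p) + h)})
        dn = params.with_values(**{name: 10 ** (np.log10(p) - h)})
        y_up = y_dn = None
        try:
            y_up = _stack(simulate_design(up, datasets, model), datasets)
        except Exception:
            warnings.warn(f"integration failed at +step for {name}; "
                          "using one-sided difference")
        try:
            y_dn = _stack(simulate_design(dn, datasets, model), datasets)
        except Exception:
            warnings.warn(f"integration failed at -step for {name}; "
                          "using one-sided difference")
        if y_up is not None and y_dn is not None:
            cols.append((y_up - y_dn) / (2 * h))
        else:
            if y0 is None:
                y0 = _stack(simulate_design(params, datasets, model),
                            datasets)
            if y_up is not None:
                cols.append((y_up - y0) / h)
            elif y_dn is not None:
                cols.append((y0 - y_dn) / h)
            else:
                raise RuntimeError(f"cannot differentiate w.r.t. {name}")
    return np.column_stack(cols)


@dataclass
class CorrelationReport:
    parameters: tuple[str, ...]
    correlation: np.ndarray
    threshold: float
    identifiable: list[str]
    unidentifiable_pairs: list[tuple[str, str, float]]
    zero_variance: list[str]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(self.correlation, index=self.parameters,
                            columns=self.parameters)


def classify(matrix: np.ndarray, names: tuple[str, ...],
             threshold: float = DEFAULT_THRESHOLD) -> CorrelationReport:
    """Pairwise Pearson correlations of sensitivity columns.

    A parameter is locally identifiable iff all its pairwise |r| stay below
    the threshold.  Columns with zero variance (no path to any observable)
    are reported separately as non-influential/unidentifiable.
    """
    if matrix.shape[1] != len(names):
        raise ValueError("column/name mismatch")
    if matrix.shape[1] < 2:
        raise ValueError("need at least two parameters")
    sd = matrix.std(axis=0)
    zero = [n for n, s in zip(names, sd) if s == 0]
    n = len(names)
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if sd[i] == 0 or sd[j] == 0:
                corr[i, j] = corr[j, i] = np.nan
            else:
                c = np.corrcoef(matrix[:, i], matrix[:, j])[0, 1]
                corr[i, j] = corr[j, i] = c
    pairs = []
    flagged = set(zero)
    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(corr[i, j]) and abs(corr[i, j]) >= threshold:
                pairs.append((names[i], names[j], float(corr[i, j])))
                flagged.add(names[i])
                flagged.add(names[j])
    identifiable = [nm for nm in names if nm not in flagged]
    return CorrelationReport(tuple(names), corr, threshold, identifiable,
                             pairs, zero)


def select_fit_parameters(influential: list[str],
                          report: CorrelationReport,
                          st_values: dict[str, float] | None = None
                          ) -> list[str]:
    """Fit set = influential minus one member of each correlated pair.

    From each unidentifiable pair the member with the smaller total-order
    sensitivity index is dropped (deterministic tie-break: alphabetical).
    """
    drop: set[str] = set(report.zero_variance)
    for a, b, _ in report.unidentifiable_pairs:
        if a not in influential or b not in influential:
            continue
        if a in drop or b in drop:
            continue
        if st_values is None:
            drop.add(max(a, b))
        else:
            drop.add(a if st_values.get(a, 0) <= st_values.get(b, 0) else b)
    return [n for n in influential if n not in drop]
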
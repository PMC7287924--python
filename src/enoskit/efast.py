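"""Extended Fourier Amplitude Sensitivity Test (eFAST).

Variance-based global sensitivity analysis after Saltelli, Tarantola &
Chan (1999).  Each parameter of interest is assigned a high drive frequency
and explored along periodic search curves through the unit hypercube while
the remaining parameters oscillate at low frequencies; the output variance
located at the drive frequency and its harmonics gives the first-order
index S_i, and the variance in the low-frequency band (everything NOT
driven by the parameter of interest) gives the total-order index
S_Ti = 1 - V_complement / V.

A "dummy" parameter with no influence on the model is always included; its
estimated total-order index is the bias floor of the estimator, and every
real parameter is tested against the dummy across resample curves (Welch
t-test, p < 0.05) before being called influential.

Parameter ranges default to a factor 0.1x-10x around the baseline values
(two orders of magnitude), mapped log-uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DUMMY = "_dummy"


@dataclass(frozen=True)
class EfastDesign:
    names: tuple[str, ...]            # parameters of interest (no dummy)
    lower: np.ndarray                 # absolute lower bounds
    upper: np.ndarray
    M: int = 4                        # interference factor (harmonics)
    Ns: int = 257                     # samples per search curve (odd)
    Nr: int = 5                       # resample curves (random phase shifts)
    log_uniform: bool = True

    def __post_init__(self):
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if len(lower) != len(self.names) or len(upper) != len(self.names):
            raise ValueError("bounds length mismatch")
        if np.any(lower >= upper):
            raise ValueError("need lower < upper")
        if self.log_uniform and np.any(lower <= 0):
            raise ValueError("log-uniform ranges need positive bounds")
        if self.Ns % 2 == 0:
            raise ValueError("Ns must be odd")
        if self.omega_max < 2 * self.M:
            raise ValueError(
                "aliasing: Ns too small for the requested M "
                f"(need Ns >= {4 * self.M * self.M + 1})")

    @classmethod
    def around_baseline(cls, baseline: dict[str, float], factor: float = 10.0,
                        **kwargs) -> "EfastDesign":
        names = tuple(baseline)
        vals = np.array([baseline[n] for n in names])
        return cls(names, vals / factor, vals * factor, **kwargs)

    @property
    def n_params(self) -> int:
        return len(self.names) + 1  # + dummy

    @property
    def all_names(self) -> tuple[str, ...]:
        return self.names + (DUMMY,)

    @property
    def omega_max(self) -> int:
        """Drive frequency of the parameter of interest."""
        return (self.Ns - 1) // (2 * self.M)

    def complementary_frequencies(self) -> np.ndarray:
        """Low frequencies for the non-driven parameters.

        Small odd primes are preferred: harmonically unrelated frequencies
        only collide at high, low-amplitude harmonics, which keeps the
        cross-spectral interference between undriven parameters small.
        """
        max_c = max(self.omega_max // (2 * self.M), 1)
        primes = [p for p in (3, 5, 7, 11, 13, 17, 19, 23, 29, 31)
                  if p <= max_c]
        pool = primes if primes else list(range(1, max_c + 1))
        n_other = self.n_params - 1
        return np.array([pool[i % len(pool)] for i in range(n_other)])


@dataclass
class EfastSample:
    design: EfastDesign
    X: np.ndarray          # (n_params, Nr, Ns, n_params) parameter values
    s: np.ndarray          # (Ns,) curve coordinate

    def flat(self) -> np.ndarray:
        """All evaluation points stacked: (n_params*Nr*Ns, n_params)."""
        d = self.design
        return self.X.reshape(d.n_params * d.Nr * d.Ns, d.n_params)


def efast_sample(design: EfastDesign, seed: int = 0) -> EfastSample:
    """Search-curve sample matrix; deterministic under ``seed``.

    For each parameter of interest i (including the dummy) and each of the
    Nr resamples, builds a curve of Ns points where parameter i runs at the
    drive frequency and all others at distinct low frequencies, with random
    phases per resample.
    """
    rng = np.random.default_rng(seed)
    d = design
    n = d.n_params
    s = -np.pi + 2.0 * np.pi * (np.arange(d.Ns) + 0.5) / d.Ns
    comp = design.complementary_frequencies()

    # bounds including the dummy (unit range; it is never used by models)
    lo = np.concatenate([d.lower, [0.0]])
    hi = np.concatenate([d.upper, [1.0]])
    log_mask = np.concatenate(
        [np.full(n - 1, d.log_uniform), [False]])

    X = np.empty((n, d.Nr, d.Ns, n))
    for i in range(n):
        others = [j for j in range(n) if j != i]
        for r in range(d.Nr):
            # random phases AND a random assignment of the (low)
            # complementary frequencies per resample decorrelate the
            # undriven parameters; keeping the frequencies at the bottom of
            # the band leaves their higher harmonics inside the complement
            freqs = np.empty(n, dtype=int)
            freqs[i] = d.omega_max
            freqs[others] = rng.permutation(comp)
            phase = rng.uniform(0.0, 2.0 * np.pi, size=n)
            # x in (0, 1) along the search curve
            angles = np.outer(freqs, s) + phase[:, None]
            x01 = 0.5 + np.arcsin(np.sin(angles)) / np.pi
            for j in range(n):
                if log_mask[j]:
                    X[i, r, :, j] = lo[j] * (hi[j] / lo[j]) ** x01[j]
                else:
                    X[i, r, :, j] = lo[j] + (hi[j] - lo[j]) * x01[j]
    return EfastSample(design=d, X=X, s=s)


@dataclass
class SensitivityReport:
    design: EfastDesign
    S1: np.ndarray                 # (n_params,) first-order, mean over Nr
    ST: np.ndarray                 # total-order, mean over Nr
    S1_resamples: np.ndarray       # (n_params, Nr)
    ST_resamples: np.ndarray
    p_vs_dummy: np.ndarray         # Welch t-test of ST against the dummy's
    n_excluded: int = 0

    def table(self) -> pd.DataFrame:
        d = self.design
        st_sum = self.ST[:-1].sum()
        return pd.DataFrame({
            "parameter": d.all_names,
            "S1": self.S1, "ST": self.ST,
            "ST_normalized": np.where(
                np.arange(d.n_params) < d.n_params - 1,
                self.ST / st_sum if st_sum > 0 else np.nan, np.nan),
            "p_vs_dummy": self.p_vs_dummy,
        })


def _curve_variances(y: np.ndarray, omega: int,
                     M: int) -> tuple[float, float, float]:
    """(V_i, V_complement, V_total) from one search curve's outputs."""
    Ns = len(y)
    k = np.arange(Ns)
    # real DFT at integer frequencies 1 .. (Ns-1)//2
    jmax = (Ns - 1) // 2
    j = np.arange(1, jmax + 1)
    angles = 2.0 * np.pi * np.outer(j, (k + 0.5)) / Ns
    yc = y - y.mean()
    A = np.cos(angles) @ yc * (2.0 / Ns)
    B = np.sin(angles) @ yc * (2.0 / Ns)
    spec = (A ** 2 + B ** 2) / 2.0
    harmonics = omega * np.arange(1, M + 1)
    harmonics = harmonics[harmonics <= jmax]
    Vi = spec[harmonics - 1].sum()
    Vci = spec[:omega // 2].sum()
    return float(Vi), float(Vci), float(spec.sum())


def efast_indices(Y: np.ndarray, sample: EfastSample) -> SensitivityReport:
    """Sensitivity indices from model outputs on the sample matrix.

    ``Y`` has shape (n_params, Nr, Ns) matching ``sample.X`` (or the
    flattened equivalent).  Curves containing non-finite outputs are
    excluded and counted.
    """
    d = sample.design
    n = d.n_params
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y.reshape(n, d.Nr, d.Ns)
    if Y.shape != (n, d.Nr, d.Ns):
        raise ValueError(f"Y shape {Y.shape} does not match design")

    S1 = np.full((n, d.Nr), np.nan)
    ST = np.full((n, d.Nr), np.nan)
    S1_pool = np.zeros(n)
    ST_pool = np.zeros(n)
    n_excluded = 0
    for i in range(n):
        Vi_sum = Vc_sum = V_sum = 0.0
        for r in range(d.Nr):
            y = Y[i, r]
            if not np.all(np.isfinite(y)):
                n_excluded += 1
                continue
            Vi, Vc, V = _curve_variances(y, d.omega_max, d.M)
            Vi_sum += Vi
            Vc_sum += Vc
            V_sum += V
            if V > 0:
                S1[i, r], ST[i, r] = Vi / V, 1.0 - Vc / V
            else:
                S1[i, r], ST[i, r] = 0.0, 0.0
        if V_sum > 0:
            # pooling variances over the phase resamples before taking the
            # ratio suppresses the finite-curve cross-spectral bias
            S1_pool[i] = Vi_sum / V_sum
            ST_pool[i] = 1.0 - Vc_sum / V_sum
    S1_mean, ST_mean = S1_pool, ST_pool

    p = np.ones(n)
    dummy_st = ST[-1][np.isfinite(ST[-1])]
    for i in range(n - 1):
        sti = ST[i][np.isfinite(ST[i])]
        if len(sti) > 1 and len(dummy_st) > 1:
            if np.allclose(sti, sti[0]) and np.allclose(dummy_st,
                                                        dummy_st[0]):
                p[i] = 0.0 if sti[0] > dummy_st[0] else 1.0
            else:
                res = stats.ttest_ind(sti, dummy_st, equal_var=False,
                                      alternative="greater")
                p[i] = float(res.pvalue)
    return SensitivityReport(design=d, S1=S1_mean, ST=ST_mean,
                             S1_resamples=S1, ST_resamples=ST,
                             p_vs_dummy=p, n_excluded=n_excluded)


def select_influential(report: SensitivityReport, cutoff: float = 0.2,
                       require_significant: bool = True) -> list[str]:
    """Parameters with (significant) total-order index >= cutoff.

    The fitting workflow uses cutoff 0.2; the perturbation-target workflow
    uses 0.1.
    """
    names = report.design.names
    out = []
    for i, name in enumerate(names):
        if report.ST[i] >= cutoff:
            if not require_significant or report.p_vs_dummy[i] < 0.05:
                out.append(name)
    return out


def efast_run(func, design: EfastDesign, seed: int = 0) -> SensitivityReport:
    """Convenience: sample, evaluate ``func(row) -> scalar``, and analyse."""
    sample = efast_sample(design, seed)
    d = design
    Y = np.empty((d.n_params, d.Nr, d.Ns))
    for i in range(d.n_params):
        for r in range(d.Nr):
            for k in range(d.Ns):
                Y[i, r, k] = func(sample.X[i, r, k])
    return efast_indices(Y, sample)
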
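"""End-to-end workflow orchestration at desk scale.

Scenarios mirror the study's main computational experiments:

``dose_response``
    time courses of nine pathway readouts at the four printed VEGF doses
    (healthy 0.0003, low-tumor 0.008, high-tumor 0.389, exogenous 1.1 nM);
``tsp1_screen_basal`` / ``tsp1_screen_tumor``
    TSP1-mediated perturbation screens (Hill dose-to-fold mapping) at basal
    and tumor VEGF;
``highvegf_screen``
    direct 2-100-fold parameter scaling at tumor VEGF without TSP1;
``full_workflow``
    synthetic data -> eFAST -> identifiability -> multi-start fit ->
    basal screen, chained with one master seed.

Every scenario writes CSV tables plus a JSON manifest (seed, config hash,
package version) into the output directory, so a report bundle can be
regenerated exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import FitProblem, fit_multistart
from .efast import EfastDesign, efast_sample, efast_indices, \
    select_influential
from .identifiability import sensitivity_matrix, classify, \
    select_fit_parameters
from .network import PERTURBABLE_INITIALS
from .screen import (run_screen, BASAL_VEGF_NM, TUMOR_VEGF_NM, auc,
                     SCREEN_OUTPUTS)
from .simulate import Model, StimulusCondition, observable
from .synthetic import (generate_truth, corrupt_all, write_timecourse_csv,
                        DEFAULT_SIGMA)

SCENARIOS = ("dose_response", "tsp1_screen_basal", "tsp1_screen_tumor", "highvegf_screen",
             "full_workflow")

DOSE_RESPONSE_VEGF_NM = (0.0003, 0.008, 0.389, 1.1)
DOSE_RESPONSE_OBSERVABLES = ("totR2", "boundR2", "pR2", "pSrc", "pAkt", "peNOS",
                    "Ca_cyt", "NO", "cGMP")

# Representative perturbation targets spanning the network modules; used
# when a screen scenario runs with targets='default' (the 'auto' mode runs
# eFAST target selection first, which is the full-study path).
DEFAULT_SCREEN_TARGETS = (
    "k_clear_NO", "k_off_Ca2C", "k_off_CaMeNOS", "k_cat_eNOS",
    "k_cat_sGC", "k_a_PDE", "I_IP3R", "I_CRAC", "I_SERCA", "K_M_PMCA",
    "CaM", "eNOS", "sGC",
)


@dataclass
class RunConfig:
    scenario: str
    out_dir: str = "results"
    seed: int = 0
    sigma: float = DEFAULT_SIGMA
    n_starts: int = 40
    top_k: int = 19
    efast_Ns: int = 129
    efast_Nr: int = 3
    targets: str | tuple[str, ...] = "default"
    ensemble_size: int = 3
    fit_max_nfev: int = 30
    fit_n_polish: int = 8
    fit_free_names: tuple[str, ...] = (
        "k_int_VR2", "k_deg_IP3", "I_IP3R", "I_SERCA", "k_cat_sGC")

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; valid: {SCENARIOS}")

    def hash(self) -> str:
        payload = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _write_manifest(config: RunConfig, out: Path, artifacts: list[str]):
    manifest = {
        "scenario": config.scenario,
        "seed": config.seed,
        "config_hash": config.hash(),
        "enoskit_version": __version__,
        "artifacts": sorted(artifacts),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))


def _dose_response(config: RunConfig, model: Model, out: Path) -> dict:
    rows = []
    results = {}
    for dose in DOSE_RESPONSE_VEGF_NM:
        res = model.simulate(StimulusCondition(vegf_nM=dose,
                                               duration_min=60.0))
        results[dose] = res
    # normalize each observable to its maximum across the four doses,
    # except Ca and cGMP which stay absolute
    for obs in DOSE_RESPONSE_OBSERVABLES:
        overall_max = max(observable(results[d], obs).max()
                          for d in DOSE_RESPONSE_VEGF_NM)
        for dose in DOSE_RESPONSE_VEGF_NM:
            y = observable(results[dose], obs)
            if obs not in ("Ca_cyt", "cGMP") and overall_max > 0:
                y = y / overall_max
            t = results[dose].time_min
            keep = slice(None, None, 5)  # 0.5-min output grid
            for ti, yi in zip(t[keep], y[keep]):
                rows.append({"observable": obs, "vegf_nM": dose,
                             "time_min": ti, "value": yi})
    df = pd.DataFrame(rows)
    df.to_csv(out / "dose_response_trajectories.csv", index=False)

    summary = []
    for dose in DOSE_RESPONSE_VEGF_NM:
        res = results[dose]
        totR2 = observable(res, "totR2")
        pk = (observable(res, "pR2") / np.maximum(totR2, 1e-12)).max()
        summary.append({
            "vegf_nM": dose, "peak_pR2_over_R2": pk,
            **{f"auc30_{o}": auc(res, o) for o in SCREEN_OUTPUTS}})
    pd.DataFrame(summary).to_csv(out / "dose_response_summary.csv", index=False)
    return {"trajectories": df, "summary": pd.DataFrame(summary)}


def _screen_scenario(config: RunConfig, model: Model, out: Path) -> dict:
    if config.scenario == "tsp1_screen_basal":
        cond = StimulusCondition(vegf_nM=BASAL_VEGF_NM, duration_min=30.0)
        mode, threshold = "tsp1", 0.2
    elif config.scenario == "tsp1_screen_tumor":
        cond = StimulusCondition(vegf_nM=TUMOR_VEGF_NM, duration_min=30.0)
        mode, threshold = "tsp1", 0.2
    else:  # highvegf_screen
        cond = StimulusCondition(vegf_nM=TUMOR_VEGF_NM, duration_min=30.0)
        mode, threshold = "direct", 0.1

    if config.targets == "default":
        targets = list(DEFAULT_SCREEN_TARGETS)
    elif config.targets == "auto":
        targets = _auto_targets(config, model, cond)
    else:
        targets = list(config.targets)

    ensemble = [model.network.params]
    table = run_screen(targets, cond, ensemble, mode=mode,
                       reduction_threshold=threshold, model=model)
    table.to_csv(out / f"{config.scenario}_screen.csv", index=False)
    return {"screen": table}


def _auto_targets(config: RunConfig, model: Model,
                  cond: StimulusCondition) -> list[str]:
    """eFAST-based target selection (S_Ti >= 0.1 for any output)."""
    params = model.network.params
    names = tuple(params.perturbable())
    baseline = {n: params[n] for n in names}
    design = EfastDesign.around_baseline(
        baseline, M=4, Ns=config.efast_Ns, Nr=config.efast_Nr)
    sample = efast_sample(design, seed=config.seed)
    d = design
    Y = {o: np.empty((d.n_params, d.Nr, d.Ns)) for o in SCREEN_OUTPUTS}
    for i in range(d.n_params):
        for r in range(d.Nr):
            for s_idx in range(d.Ns):
                row = sample.X[i, r, s_idx]
                p = params.with_values(
                    **{n: row[j] for j, n in enumerate(names)})
                try:
                    res = model.simulate(cond, p)
                    for o in SCREEN_OUTPUTS:
                        Y[o][i, r, s_idx] = auc(res, o)
                except Exception:
                    for o in SCREEN_OUTPUTS:
                        Y[o][i, r, s_idx] = np.nan
    hits: set[str] = set()
    for o in SCREEN_OUTPUTS:
        rep = efast_indices(Y[o], sample)
        hits.update(select_influential(rep, cutoff=0.1))
    return sorted(hits)


def _full_workflow(config: RunConfig, model: Model, out: Path) -> dict:
    rng_seed = config.seed
    params = model.network.params

    truth = generate_truth(params, model=model)
    noisy = corrupt_all(truth, config.sigma, rng_seed)
    write_timecourse_csv(noisy, out / "training_data.csv")

    free = config.fit_free_names
    problem = FitProblem(free_names=free, datasets=tuple(noisy),
                         base_params=params)

    # identifiability screen of the candidate fit set
    S = sensitivity_matrix(params, free, tuple(noisy), model)
    report = classify(S, free)
    st_proxy = {n: float(np.std(S[:, i])) for i, n in enumerate(free)}
    fit_set = select_fit_parameters(list(free), report, st_proxy)
    pd.DataFrame(report.correlation, index=free, columns=free).to_csv(
        out / "identifiability_correlations.csv")

    problem = FitProblem(free_names=tuple(fit_set), datasets=tuple(noisy),
                         base_params=params)
    ensemble = fit_multistart(problem, n_starts=config.n_starts,
                              seed=rng_seed, k=min(config.top_k,
                                                   config.n_starts),
                              model=model, max_nfev=config.fit_max_nfev,
                              n_polish=min(config.fit_n_polish,
                                           config.n_starts))
    fits = pd.DataFrame([
        {"rank": i, "objective": r.objective, "start": r.start_index,
         **r.values(problem)}
        for i, r in enumerate(ensemble.top())])
    fits.to_csv(out / "fit_ensemble.csv", index=False)

    cond = StimulusCondition(vegf_nM=BASAL_VEGF_NM, duration_min=30.0)
    members = ensemble.parameter_sets()[:config.ensemble_size]
    table = run_screen(list(DEFAULT_SCREEN_TARGETS[:4]), cond, members,
                       mode="tsp1", reduction_threshold=0.2, model=model)
    table.to_csv(out / "basal_screen.csv", index=False)
    return {"ensemble": fits, "screen": table}


def run_scenario(config: RunConfig, model: Model | None = None) -> dict:
    """Execute one scenario; returns its tables and writes the bundle."""
    model = model or Model()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.scenario == "dose_response":
        result = _dose_response(config, model, out)
    elif config.scenario in ("tsp1_screen_basal", "tsp1_screen_tumor", "highvegf_screen"):
        result = _screen_scenario(config, model, out)
    else:
        result = _full_workflow(config, model, out)
    artifacts = [p.name for p in out.iterdir() if p.suffix == ".csv"]
    _write_manifest(config, out, artifacts)
    return result
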
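"""Time-course simulation of the eNOS signalling model.

A stimulus condition is applied to the pre-equilibrated (resting) model:
the system is first relaxed to its fixed point with zero VEGF and zero TSP1,
then the ligand doses are added at t = 0 and the stiff ODE system is
integrated over the requested duration.  Cycloheximide zeroes receptor
synthesis for the stimulus phase only (the cells are assumed to be at
steady state when the drug is added).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from .network import ReactionNetwork, build_network
from .odes import CompiledModel, BoundModel
from .parameters import ParameterSet

RTOL = 1e-6
ATOL = 1e-9
EQUILIBRATION_MIN = 1000.0
OUTPUT_DT_MIN = 0.1
# hard cap on internal LSODA steps per output interval: pathological
# parameter draws fail fast instead of stalling a calibration run
MAX_STEPS = 20000


def _integrate(rhs, y0, t_grid, rtol, atol):
    import warnings
    from scipy.integrate import ODEintWarning

    t = np.asarray(t_grid, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ODEintWarning)
        y, info = odeint(rhs, y0, t, Dfun=rhs.jac, tfirst=True,
                         rtol=rtol, atol=atol, mxstep=MAX_STEPS,
                         full_output=True, printmessg=False)
    success = info["message"] == "Integration successful."
    return y, info, success

# observable name -> summed species states
OBSERVABLES: dict[str, tuple[str, ...]] = {
    "totR2": ("R2", "VEGF_R2", "pR2", "CD47_R2", "CD47_VEGF_R2", "CD47_pR2",
              "R2_int"),
    "memR2": ("R2", "VEGF_R2", "pR2", "CD47_R2", "CD47_VEGF_R2", "CD47_pR2"),
    "boundR2": ("VEGF_R2", "pR2", "CD47_VEGF_R2", "CD47_pR2"),
    "pR2": ("pR2", "CD47_pR2"),
    "pSrc": ("pSrc",),
    "pAkt": ("pAkt",),
    "peNOS": ("eNOS_p", "eNOS_CaM_p", "eNOS_Hsp90_p", "eNOS_CaM_Hsp90_p"),
    "pPLCg": ("pPLCg",),
    "IP3": ("IP3",),
    "Ca_cyt": ("Ca_cyt",),
    "NO": ("NO",),
    "cGMP": ("cGMP",),
    "eNOS_activity": ("NO",),  # NO level is the readout of catalytic activity
}


class SimulationError(RuntimeError):
    def __init__(self, message: str, parameter_set_id: str | None = None):
        super().__init__(message)
        self.parameter_set_id = parameter_set_id


@dataclass(frozen=True)
class StimulusCondition:
    vegf_nM: float = 0.0
    tsp1_nM: float = 0.0
    cycloheximide: bool = False
    duration_min: float = 60.0
    pre_equilibrate: bool = True

    def __post_init__(self):
        if self.vegf_nM < 0 or self.tsp1_nM < 0:
            raise ValueError("doses must be >= 0")
        if self.duration_min <= 0:
            raise ValueError("duration must be > 0")


@dataclass
class SimulationResult:
    time_min: np.ndarray
    concentrations: np.ndarray          # (n_times, n_species), nM
    species: list[str]
    condition: StimulusCondition
    parameter_set_id: str = "default"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.concentrations.min() < -1e-9:
            raise ValueError("negative concentration beyond tolerance")

    def series(self, species_name: str) -> np.ndarray:
        return self.concentrations[:, self.species.index(species_name)]

    def to_frame(self, condition_id: str = "") -> pd.DataFrame:
        """Tidy long-format table (time_min, species, concentration_nM)."""
        n_t = len(self.time_min)
        return pd.DataFrame({
            "time_min": np.repeat(self.time_min, len(self.species)),
            "species": self.species * n_t,
            "concentration_nM": self.concentrations.ravel(),
            "condition_id": condition_id or self.parameter_set_id,
        })


class Model:
    """A compiled network plus caching of pre-equilibrated resting states."""

    def __init__(self, network: ReactionNetwork | None = None):
        self.network = network if network is not None else build_network()
        self.compiled = CompiledModel(self.network)
        self._rest_cache: dict[bytes, np.ndarray] = {}

    @property
    def species(self) -> list[str]:
        return self.network.species_names()

    def initial_state(self, params: ParameterSet) -> np.ndarray:
        y0 = np.array([s.initial for s in self.network.species])
        return y0

    def bind(self, params: ParameterSet | None = None) -> BoundModel:
        return self.compiled.bind(params or self.network.params)

    # -- resting state ----------------------------------------------------
    def pre_equilibrate(self, params: ParameterSet | None = None,
                        t_max: float = EQUILIBRATION_MIN) -> np.ndarray:
        """Resting state with zero VEGF/TSP1 (cached per parameter vector)."""
        params = params or self.network.params
        key = params.key()
        if key in self._rest_cache:
            return self._rest_cache[key].copy()
        rhs = self.bind(params)
        y0 = self.initial_state(params)
        for name in ("VEGF", "TSP1"):
            y0[self.network.index[name]] = 0.0
        y, info, success = _integrate(rhs, y0, [0.0, t_max],
                                      rtol=1e-8, atol=1e-10)
        if not success:
            raise SimulationError(
                f"pre-equilibration failed: {info['message']}")
        rest = np.maximum(y[-1], 0.0)
        self._rest_cache[key] = rest
        return rest.copy()

    # -- stimulus ----------------------------------------------------------
    def simulate(self, condition: StimulusCondition,
                 params: ParameterSet | None = None,
                 t_grid: np.ndarray | None = None,
                 parameter_set_id: str = "default") -> SimulationResult:
        params = params or self.network.params
        if condition.pre_equilibrate:
            y0 = self.pre_equilibrate(params)
        else:
            y0 = self.initial_state(params)
        y0 = y0.copy()
        y0[self.network.index["VEGF"]] = condition.vegf_nM
        y0[self.network.index["TSP1"]] = condition.tsp1_nM

        sim_params = params
        if condition.cycloheximide:
            sim_params = params.with_values(k_syn_R2=0.0)
        rhs = self.compiled.bind(sim_params)

        if t_grid is None:
            t_grid = np.arange(
                0.0, condition.duration_min + OUTPUT_DT_MIN / 2,
                OUTPUT_DT_MIN)
        t_grid = np.asarray(t_grid, dtype=float)
        if t_grid[0] < 0 or t_grid[-1] > condition.duration_min + 1e-9:
            raise ValueError("t_grid must lie within [0, duration]")

        t_solver = t_grid if t_grid[0] == 0.0 \
            else np.concatenate([[0.0], t_grid])
        y, info, success = _integrate(rhs, y0, t_solver, RTOL, ATOL)
        if not success:
            raise SimulationError(
                f"integration failed: {info['message']}",
                parameter_set_id=parameter_set_id)
        if t_grid[0] != 0.0:
            y = y[1:]
        conc = np.maximum(y, 0.0)
        return SimulationResult(
            time_min=t_grid, concentrations=conc, species=self.species,
            condition=condition, parameter_set_id=parameter_set_id,
            diagnostics={"nfev": int(info["nfe"][-1]),
                         "njev": int(info["nje"][-1])})


def observable(result: SimulationResult, name: str) -> np.ndarray:
    """Summed concentration time course of a named observable."""
    if name not in OBSERVABLES:
        raise KeyError(f"unknown observable {name!r}; "
                       f"choose from {sorted(OBSERVABLES)}")
    cols = [result.species.index(s) for s in OBSERVABLES[name]
            if s in result.species]
    if not cols:
        return np.zeros_like(result.time_min)
    return result.concentrations[:, cols].sum(axis=1)


_DEFAULT_MODEL: Model | None = None


def default_model() -> Model:
    """Process-wide default model (compiled once)."""
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = Model()
    return _DEFAULT_MODEL


def simulate(condition: StimulusCondition,
             params: ParameterSet | None = None,
             t_grid: np.ndarray | None = None,
             model: Model | None = None,
             parameter_set_id: str = "default") -> SimulationResult:
    """Convenience wrapper around :meth:`Model.simulate`."""
    model = model or default_model()
    return model.simulate(condition, params, t_grid, parameter_set_id)
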
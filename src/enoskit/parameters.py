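"""Kinetic, transport and geometric parameters of the eNOS signalling model.

Units are nM and minutes throughout.  Bimolecular constants are /nM/min,
first-order constants /min, transport capacities nM/min (referenced to
cytosolic volume).  Each parameter carries

* ``group`` -- the sub-module it belongs to (``receptor``,
  ``src_akt_hsp90``, ``calcium``, ``enos_act``, ``enos_cat``, ``sgc``,
  ``geometry``), used to organise sensitivity analyses;
* ``perturbable`` -- whether the in-silico perturbation screens may scale it;
* ``direction`` -- ``promotes`` or ``impedes`` (overall eNOS signalling),
  which decides whether a simulated inhibitor multiplies the parameter by
  ``f_negative`` (promoters are scaled down) or ``f_positive`` (impeders are
  scaled up).

The resting calcium sub-system is balanced analytically: with the defaults
below the fluxes through SERCA, PMCA, the ER leak and the store-operated
(CRAC) channel cancel exactly at 50 nM free cytosolic Ca2+ and 0.4 mM ER
Ca2+, so the unstimulated model sits at its homeostatic set point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

PROMOTES = "promotes"
IMPEDES = "impedes"

# Dose conversion fixed by 30 ng/mL == 1.1 nM VEGF.
NG_PER_ML_TO_NM_VEGF = 1.1 / 30.0


@dataclass(frozen=True)
class Parameter:
    name: str
    value: float
    units: str
    group: str
    perturbable: bool = True
    direction: str = PROMOTES
    description: str = ""


# SERCA carries 1000 nM/min at 50 nM Ca (I*50^2/(200^2+50^2)); the leak must
# return exactly that across the resting ER gradient of 99950 nM.
_K_LEAK_REST = 1000.0 / 99950.0

_PARAMS: list[Parameter] = [
    # --- receptor module -------------------------------------------------
    Parameter("k_on_VEGF_R2", 0.6, "1/nM/min", "receptor", True, PROMOTES,
              "VEGF binding to VEGFR2"),
    Parameter("k_off_VEGF_R2", 0.6, "1/min", "receptor", True, IMPEDES,
              "VEGF-VEGFR2 dissociation"),
    Parameter("k_phos_R2", 6.0, "1/min", "receptor", True, PROMOTES,
              "autophosphorylation of ligated R2"),
    Parameter("k_dephos_R2", 0.6, "1/min", "receptor", True, IMPEDES,
              "pR2 dephosphorylation"),
    Parameter("k_int_R2", 0.02, "1/min", "receptor", True, IMPEDES,
              "internalisation of unligated surface R2"),
    Parameter("k_int_VR2", 0.2, "1/min", "receptor", True, IMPEDES,
              "internalisation of ligated/phosphorylated R2"),
    Parameter("k_deg_R2int", 0.05, "1/min", "receptor", True, IMPEDES,
              "degradation of internalised R2"),
    Parameter("k_syn_R2", 0.005, "nM/min", "receptor", True, PROMOTES,
              "constitutive R2 synthesis (zeroed by cycloheximide)"),
    Parameter("k_couple_CD47_R2", 1.0, "1/nM/min", "receptor", True, PROMOTES,
              "CD47-R2 coupling"),
    Parameter("k_uncouple_CD47_R2", 1.0, "1/min", "receptor", True, IMPEDES,
              "CD47-R2 uncoupling"),
    Parameter("phos_eff_uncoupled", 1.0, "-", "receptor", False, PROMOTES,
              "phosphorylation-efficiency factor for CD47-uncoupled R2"),
    Parameter("k_on_TSP1_CD47", 1.0, "1/nM/min", "receptor", True, IMPEDES,
              "TSP1 ligation of CD47 (disrupts CD47-R2 coupling)"),
    Parameter("k_off_TSP1_CD47", 0.1, "1/min", "receptor", True, PROMOTES),
    Parameter("k_on_TSP1_VEGF", 0.1, "1/nM/min", "receptor", True, IMPEDES,
              "extracellular sequestration of VEGF by TSP1"),
    Parameter("k_off_TSP1_VEGF", 0.1, "1/min", "receptor", True, PROMOTES),
    # --- Src / Akt / Hsp90 module ---------------------------------------
    Parameter("k_p_Src", 5.0, "1/nM/min", "src_akt_hsp90", True, PROMOTES,
              "pR2-catalysed Src phosphorylation"),
    Parameter("k_dp_Src", 0.5, "1/min", "src_akt_hsp90", True, IMPEDES),
    Parameter("k_p_Akt", 0.01, "1/nM/min", "src_akt_hsp90", True, PROMOTES,
              "pSrc-catalysed Akt phosphorylation"),
    Parameter("k_dp_Akt", 0.3, "1/min", "src_akt_hsp90", True, IMPEDES),
    Parameter("k_a_Hsp90", 0.01, "1/nM/min", "src_akt_hsp90", True, PROMOTES,
              "pSrc-driven Hsp90 activation"),
    Parameter("k_d_Hsp90", 0.3, "1/min", "src_akt_hsp90", True, IMPEDES),
    Parameter("k_on_Hsp90_CaMeNOS", 0.01, "1/nM/min", "src_akt_hsp90", True,
              PROMOTES, "active Hsp90 association with eNOS species"),
    Parameter("k_off_Hsp90_CaMeNOS", 0.5, "1/min", "src_akt_hsp90", True,
              IMPEDES),
    Parameter("k_p_eNOS", 0.01, "1/nM/min", "src_akt_hsp90", True, PROMOTES,
              "pAkt-catalysed eNOS phosphorylation within Hsp90 complexes"),
    Parameter("k_dp_eNOS", 0.05, "1/min", "src_akt_hsp90", True, IMPEDES),
    # --- calcium module --------------------------------------------------
    Parameter("k_p_PLCg", 5.0, "1/nM/min", "calcium", True, PROMOTES,
              "pR2-catalysed PLCgamma phosphorylation"),
    Parameter("k_dp_PLCg", 0.5, "1/min", "calcium", True, IMPEDES),
    Parameter("k_cat_PLCg", 20.0, "1/min", "calcium", True, PROMOTES,
              "PIP2 -> IP3 turnover by active PLCgamma"),
    Parameter("K_M_PLCg", 4000.0, "nM", "calcium", True, IMPEDES),
    Parameter("k_deg_IP3", 2.5, "1/min", "calcium", True, IMPEDES),
    Parameter("I_IP3R", 0.3, "1/min", "calcium", True, PROMOTES,
              "IP3R channel conductance (per nM channel, per nM ER gradient)"),
    Parameter("K_M_IP3R", 120.0, "nM", "calcium", True, IMPEDES),
    Parameter("I_CRAC", 1700.0, "nM/min", "calcium", True, PROMOTES,
              "maximal store-operated Ca entry"),
    Parameter("k_in_Ca_bg", 6.0e-4, "1/min", "calcium", False, PROMOTES,
              "constitutive background plasma-membrane Ca influx "
              "(first order in extracellular Ca)"),
    Parameter("K_CRAC", 5.0e4, "nM", "calcium", True, PROMOTES,
              "ER Ca level at half-maximal CRAC gating"),
    Parameter("n_CRAC", 4.0, "-", "calcium", False, PROMOTES,
              "CRAC store-depletion Hill exponent"),
    Parameter("I_SERCA", 17000.0, "nM/min", "calcium", True, IMPEDES),
    Parameter("K_M_SERCA", 200.0, "nM", "calcium", True, PROMOTES),
    Parameter("I_PMCA", 3000.0, "nM/min", "calcium", True, IMPEDES),
    Parameter("K_M_PMCA", 100.0, "nM", "calcium", True, PROMOTES),
    Parameter("k_leak", _K_LEAK_REST, "1/min", "calcium", True, PROMOTES,
              "passive ER leak"),
    Parameter("f_buf", 0.05, "-", "calcium", False, IMPEDES,
              "free fraction of cytosolic Ca (instantaneous buffering)"),
    # --- eNOS module: activation -----------------------------------------
    Parameter("k_on_Ca2N", 4.0e-4, "1/nM^2/min", "enos_act", True, PROMOTES,
              "2 Ca binding to the CaM N-lobe"),
    Parameter("k_off_Ca2N", 100.0, "1/min", "enos_act", True, IMPEDES),
    Parameter("k_on_Ca2C", 4.0e-2, "1/nM^2/min", "enos_act", True, PROMOTES,
              "2 Ca binding to the CaM C-lobe"),
    Parameter("k_off_Ca2C", 200.0, "1/min", "enos_act", True, IMPEDES),
    Parameter("k_on_CaMeNOS", 4.0, "1/nM/min", "enos_act", True, PROMOTES,
              "4-Ca CaM binding to eNOS"),
    Parameter("k_off_CaMeNOS", 4.0, "1/min", "enos_act", True, IMPEDES),
    Parameter("gamma_Hsp90CaM", 150.0, "-", "enos_act", True, PROMOTES,
              "fold reduction of k_off_CaMeNOS when Hsp90 is bound"),
    # --- eNOS module: catalysis ------------------------------------------
    Parameter("k_on_Arg", 0.02, "1/nM/min", "enos_cat", True, PROMOTES),
    Parameter("k_off_Arg", 60.0, "1/min", "enos_cat", True, IMPEDES),
    Parameter("k_cat_eNOS", 0.2, "1/min", "enos_cat", True, PROMOTES,
              "catalytic rate of basal (non-Hsp90) eNOS forms"),
    Parameter("k_cat_eNOS_Hsp90", 0.5, "1/min", "enos_cat", True, PROMOTES,
              "catalytic rate of Hsp90-bound eNOS forms"),
    Parameter("alpha_phos", 12.0, "-", "enos_cat", True, PROMOTES,
              "catalytic enhancement by Ser-phosphorylation"),
    Parameter("f_basal_eNOS", 0.001, "-", "enos_cat", False, PROMOTES,
              "Ca/CaM-independent basal activity fraction"),
    Parameter("k_clear_NO", 20.0, "1/min", "enos_cat", True, IMPEDES,
              "first-order NO clearance"),
    Parameter("k_recycle_Cit", 0.05, "1/min", "enos_cat", False, PROMOTES,
              "citrulline -> arginine recycling"),
    # --- sGC / cGMP / PDE module -----------------------------------------
    Parameter("k_on_NO_sGC", 6.0, "1/nM/min", "sgc", True, PROMOTES,
              "NO binding to the distal (activating) heme of sGC"),
    Parameter("k_off_NO_sGC", 30.0, "1/min", "sgc", True, IMPEDES),
    Parameter("k_a_sGC", 30.0, "1/min", "sgc", True, PROMOTES,
              "activation of 1-NO sGC"),
    Parameter("k_f_NOGC_NO", 0.1, "1/nM/min", "sgc", True, IMPEDES,
              "NO binding to the proximal heme (desensitisation)"),
    Parameter("k_r_NOGC_NO", 1.0, "1/min", "sgc", True, PROMOTES),
    Parameter("k_off_NO_NOGC", 0.5, "1/min", "sgc", True, PROMOTES,
              "NO loss from the desensitised 2-NO state"),
    Parameter("k_cat_sGC", 10.0, "1/min", "sgc", True, PROMOTES,
              "GTP -> cGMP turnover by active sGC"),
    Parameter("K_M_sGC", 1.0e5, "nM", "sgc", True, IMPEDES),
    Parameter("k_on_cGMP_PDE", 0.005, "1/nM/min", "sgc", True, IMPEDES,
              "cGMP binding to the PDE regulatory site"),
    Parameter("k_off_cGMP_PDE", 2.0, "1/min", "sgc", True, PROMOTES),
    Parameter("k_a_PDE", 1.0, "1/min", "sgc", True, IMPEDES),
    Parameter("k_a2_PDE", 0.5, "1/min", "sgc", True, IMPEDES),
    Parameter("k_d_PDE", 1.0, "1/min", "sgc", True, PROMOTES),
    Parameter("k_d2_PDE", 1.0, "1/min", "sgc", True, PROMOTES),
    Parameter("k_cat_PDE", 20.0, "1/min", "sgc", True, IMPEDES),
    Parameter("K_M_PDE", 2000.0, "nM", "sgc", True, PROMOTES),
    # --- geometry ---------------------------------------------------------
    Parameter("V_cyt", 1.0e-12, "L", "geometry", False, PROMOTES,
              "cytosolic volume"),
    Parameter("V_ER", 1.0e-13, "L", "geometry", False, PROMOTES,
              "ER volume"),
    Parameter("V_ext", 1.0e-11, "L", "geometry", False, PROMOTES,
              "extracellular volume per cell"),
]


class ParameterSet:
    """Ordered, named collection of model constants.

    Behaves like a read-mostly mapping; :meth:`with_values` returns a modified
    copy, :meth:`vector`/:meth:`from_vector` convert to and from a plain
    float array in the canonical order (used by the ODE compiler, the
    optimiser and eFAST).
    """

    def __init__(self, params: list[Parameter] | None = None):
        self._params: dict[str, Parameter] = {
            p.name: p for p in (params if params is not None else _PARAMS)
        }
        self._index = {name: i for i, name in enumerate(self._params)}
        self._validate()

    def _validate(self) -> None:
        for p in self._params.values():
            if not np.isfinite(p.value) or p.value < 0:
                raise ValueError(f"parameter {p.name} must be finite and >= 0")
            if p.direction not in (PROMOTES, IMPEDES):
                raise ValueError(f"bad direction tag on {p.name}")
        if self["V_ER"] >= self["V_cyt"]:
            raise ValueError("ER volume must be smaller than cytosolic volume")
        for name in ("V_cyt", "V_ER", "V_ext"):
            if self[name] <= 0:
                raise ValueError("compartment volumes must be positive")

    # -- mapping-ish interface -------------------------------------------
    def __getitem__(self, name: str) -> float:
        return self._params[name].value

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def __iter__(self) -> Iterator[str]:
        return iter(self._params)

    def __len__(self) -> int:
        return len(self._params)

    def names(self) -> list[str]:
        return list(self._params)

    def meta(self, name: str) -> Parameter:
        return self._params[name]

    def index(self, name: str) -> int:
        return self._index[name]

    def group(self, group: str) -> list[str]:
        return [p.name for p in self._params.values() if p.group == group]

    def perturbable(self) -> list[str]:
        return [p.name for p in self._params.values() if p.perturbable]

    # -- conversions ------------------------------------------------------
    def vector(self) -> np.ndarray:
        return np.array([p.value for p in self._params.values()], dtype=float)

    def from_vector(self, vec: np.ndarray) -> "ParameterSet":
        if len(vec) != len(self._params):
            raise ValueError("parameter vector length mismatch")
        new = [replace(p, value=float(v))
               for p, v in zip(self._params.values(), vec)]
        return ParameterSet(new)

    def with_values(self, **values: float) -> "ParameterSet":
        new = []
        unknown = set(values) - set(self._params)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        for p in self._params.values():
            if p.name in values:
                new.append(replace(p, value=float(values[p.name])))
            else:
                new.append(p)
        return ParameterSet(new)

    def scaled(self, name: str, fold: float) -> "ParameterSet":
        return self.with_values(**{name: self[name] * fold})

    def to_dict(self) -> dict[str, float]:
        return {p.name: p.value for p in self._params.values()}

    def key(self) -> bytes:
        """Stable hash key for caching (values only; order is canonical)."""
        return self.vector().tobytes()


def default_parameters() -> ParameterSet:
    return ParameterSet()
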
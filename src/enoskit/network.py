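"""Reaction network of VEGF/TSP1-mediated eNOS signalling.

The network is specified as a list of rules over five sub-modules (receptor,
Src/Akt/Hsp90, calcium, eNOS, sGC) plus the TSP1 interactions, and expanded
by :func:`build_network` into explicit species and reactions.  The ODE
right-hand side is derived generically from the expanded network (see
:mod:`enoskit.odes`), so every mechanism is driven by exactly one named
constant in :class:`~enoskit.parameters.ParameterSet`.

Conventions
-----------
* concentrations in nM, time in minutes;
* all reaction fluxes are referenced to the cytosolic volume; species in
  other compartments pick up the volume ratio in the stoichiometric matrix;
* membrane species are book-kept as cytosol-referenced concentrations;
* ``clamped`` species (extracellular Ca, GTP, PIP2) are held constant --
  they act as boundary pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .parameters import ParameterSet, default_parameters

# Seed species of the rule set.  TSP1 defaults to zero; the other 18 carry
# non-zero initial concentrations.
SEED_SPECIES = (
    "VEGF", "TSP1", "R2", "CD47", "Src", "PLCg", "PIP2", "IP3R", "Akt",
    "Hsp90", "CaM", "eNOS", "Arg", "Ca_cyt", "Ca_ER", "Ca_ext", "sGC",
    "GTP", "PDE",
)

DEFAULT_INITIALS: dict[str, float] = {
    "VEGF": 0.389,      # reference stimulus; overridden per condition
    "TSP1": 0.0,
    "R2": 0.25,
    "CD47": 1.0,
    "Src": 100.0,
    "PLCg": 100.0,
    "PIP2": 4000.0,     # clamped (continuously replenished)
    "IP3R": 1.0,
    "Akt": 100.0,
    "Hsp90": 100.0,
    "CaM": 200.0,
    "eNOS": 100.0,
    "Arg": 1.0e5,
    "Ca_cyt": 50.0,
    "Ca_ER": 1.0e5,
    "Ca_ext": 1.5e6,    # clamped
    "sGC": 100.0,
    "GTP": 1.0e6,       # clamped
    "PDE": 100.0,
}

# Initial concentrations the perturbation screens may scale (all of these
# promote eNOS signalling: lowering them is inhibitory).
PERTURBABLE_INITIALS = ("CaM", "eNOS", "sGC", "GTP", "Src", "Hsp90",
                       "PIP2", "Ca_ext")


class ConfigurationError(ValueError):
    """Raised when a network config references unknown species/constants."""


@dataclass(frozen=True)
class Compartment:
    name: str
    volume_L: float | None  # None for the membrane (area-like, cytosol-referenced)

    def __post_init__(self):
        if self.volume_L is not None and self.volume_L <= 0:
            raise ValueError(f"compartment {self.name}: volume must be > 0")


@dataclass(frozen=True)
class Species:
    """A distinct chemical state.

    ``components`` counts the elementary molecules contained in the state
    (e.g. ``{"eNOS": 1, "CaM": 1, "Ca": 4}``); conservation laws are read
    off these counts.
    """
    name: str
    compartment: str
    components: dict[str, int]
    initial: float = 0.0
    clamped: bool = False

    def __post_init__(self):
        if self.initial < 0:
            raise ValueError(f"species {self.name}: initial must be >= 0")


@dataclass(frozen=True)
class RateConstant:
    """Product of named constants (with integer exponents) times a factor."""
    terms: tuple[tuple[str, int], ...]
    factor: float = 1.0

    @classmethod
    def of(cls, *names: str, factor: float = 1.0,
           inverse: tuple[str, ...] = ()) -> "RateConstant":
        terms = tuple((n, 1) for n in names) + tuple((n, -1) for n in inverse)
        return cls(terms, factor)

    def value(self, params: ParameterSet) -> float:
        v = self.factor
        for name, exp in self.terms:
            v *= params[name] ** exp
        return v


@dataclass(frozen=True)
class RateLaw:
    """One of three kinetic forms.

    mass_action
        flux = k * prod(reactant^stoich); ``kf`` only (irreversible
        reactions; a reversible rule is expanded to two reactions).
    michaelis_menten
        flux = kcat * [enzyme] * [substrate] / (Km + [substrate]); the
        enzyme is a modifier (not consumed).
    hill_flux
        flux = Imax * act^n/(K^n + act^n) (or the complement when
        ``inhibited``), optionally multiplied by a linear driving force
        [src]-[dst] and by a modifier concentration (channel density).
    """
    kind: str
    kf: RateConstant | None = None
    kcat: RateConstant | None = None
    Km: RateConstant | None = None
    enzyme: str | None = None
    Imax: RateConstant | None = None
    K: RateConstant | None = None
    n: float = 1.0
    activator: str | None = None
    inhibited: bool = False
    driving: tuple[str, str] | None = None
    modifier: tuple[str, float] | None = None  # (species, reference conc)

    def __post_init__(self):
        if self.kind == "mass_action":
            if self.kf is None:
                raise ValueError("mass_action needs kf")
        elif self.kind == "michaelis_menten":
            if self.kcat is None or self.Km is None or self.enzyme is None:
                raise ValueError("michaelis_menten needs kcat, Km, enzyme")
        elif self.kind == "hill_flux":
            if self.Imax is None or self.K is None or self.activator is None:
                raise ValueError("hill_flux needs Imax, K, activator")
            if self.n < 1:
                raise ValueError("hill exponent must be >= 1")
        else:
            raise ValueError(f"unknown rate law kind {self.kind!r}")


@dataclass(frozen=True)
class Reaction:
    name: str
    reactants: dict[str, int]
    products: dict[str, int]
    rate_law: RateLaw
    module_tag: str

    def __post_init__(self):
        for d in (self.reactants, self.products):
            for sp, st in d.items():
                if not (isinstance(st, int) and st > 0):
                    raise ValueError(
                        f"reaction {self.name}: stoichiometry for {sp} "
                        "must be a positive integer")


@dataclass
class ReactionNetwork:
    compartments: dict[str, Compartment]
    species: list[Species]
    reactions: list[Reaction]
    params: ParameterSet
    index: dict[str, int] = field(init=False)

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(names) != len(set(names)):
            raise ConfigurationError("duplicate species names")
        self.index = {n: i for i, n in enumerate(names)}
        self._check()

    def _check(self) -> None:
        for rxn in self.reactions:
            for sp in list(rxn.reactants) + list(rxn.products):
                if sp not in self.index:
                    raise ConfigurationError(
                        f"reaction {rxn.name} references unknown species {sp}")
            rl = rxn.rate_law
            for sp in (rl.enzyme, rl.activator):
                if sp is not None and sp not in self.index:
                    raise ConfigurationError(
                        f"rate law of {rxn.name} references unknown "
                        f"species {sp}")
            if rl.driving is not None:
                for sp in rl.driving:
                    if sp not in self.index:
                        raise ConfigurationError(
                            f"driving force of {rxn.name} references "
                            f"unknown species {sp}")
            if rl.modifier is not None and rl.modifier[0] not in self.index:
                raise ConfigurationError(
                    f"modifier of {rxn.name} unknown")
            for rc in (rl.kf, rl.kcat, rl.Km, rl.Imax, rl.K):
                if rc is None:
                    continue
                for pname, _ in rc.terms:
                    if pname not in self.params:
                        raise ConfigurationError(
                            f"reaction {rxn.name}: missing rate constant "
                            f"{pname}")

    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def initials(self) -> dict[str, float]:
        return {s.name: s.initial for s in self.species}

    def conservation_components(self) -> list[str]:
        """Molecules whose total content is conserved by every reaction."""
        return ["CaM", "sGC", "PDE", "Src", "Akt", "Hsp90", "PLCg", "CD47",
                "eNOS", "ArgCit"]


def load_config(path) -> dict:
    """Read a model config from YAML or JSON (sections: species,
    parameters, geometry, options); missing sections fall back to the
    defaults inside :func:`build_network`."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError("config file must contain a mapping")
    base = default_config()
    for section in ("species", "parameters", "geometry", "options"):
        merged = dict(base[section])
        merged.update(cfg.get(section, {}))
        cfg[section] = merged
    return cfg


def default_config() -> dict:
    """Default model configuration (species, parameters, geometry, options)."""
    params = default_parameters()
    return {
        "species": dict(DEFAULT_INITIALS),
        "parameters": params.to_dict(),
        "geometry": {"V_cyt": params["V_cyt"], "V_ER": params["V_ER"],
                     "V_ext": params["V_ext"]},
        "options": {"tsp1_rules": True},
    }


def _ma(name, reactants, products, k, tag, factor=1.0, inverse=()):
    if isinstance(k, str):
        k = RateConstant.of(k, factor=factor, inverse=inverse)
    return Reaction(name, reactants, products,
                    RateLaw("mass_action", kf=k), tag)


def _rev(name, lhs, rhs, kf, kr, tag):
    """Reversible mass-action rule expanded into two reactions."""
    return [_ma(name + "_f", lhs, rhs, kf, tag),
            _ma(name + "_r", rhs, lhs, kr, tag)]


def _mm(name, enzyme, substrate, products, kcat, Km, tag,
        consume_substrate=True):
    if isinstance(kcat, str):
        kcat = RateConstant.of(kcat)
    if isinstance(Km, str):
        Km = RateConstant.of(Km)
    reactants = {substrate: 1} if consume_substrate else {}
    return Reaction(name, reactants, products,
                    RateLaw("michaelis_menten", kcat=kcat, Km=Km,
                            enzyme=enzyme), tag)


def build_network(config: dict | None = None) -> ReactionNetwork:
    """Expand the rule set into an explicit :class:`ReactionNetwork`.

    ``config`` follows :func:`default_config`; unknown species or missing
    rate constants raise :class:`ConfigurationError`.
    """
    if config is None:
        config = default_config()
    initials = dict(config.get("species", {}))
    unknown = set(initials) - set(SEED_SPECIES)
    if unknown:
        raise ConfigurationError(f"unknown seed species: {sorted(unknown)}")
    missing = set(SEED_SPECIES) - set(initials)
    if missing:
        raise ConfigurationError(f"missing seed species: {sorted(missing)}")

    pdict = dict(default_parameters().to_dict())
    pdict.update(config.get("parameters", {}))
    geometry = config.get("geometry", {})
    for gname in ("V_cyt", "V_ER", "V_ext"):
        if gname in geometry:
            pdict[gname] = geometry[gname]
    base = default_parameters()
    unknown_p = set(pdict) - set(base.names())
    if unknown_p:
        raise ConfigurationError(f"unknown parameters: {sorted(unknown_p)}")
    params = base.with_values(**pdict)
    tsp1_rules = bool(config.get("options", {}).get("tsp1_rules", True))

    compartments = {
        "extracellular": Compartment("extracellular", params["V_ext"]),
        "cytosol": Compartment("cytosol", params["V_cyt"]),
        "ER": Compartment("ER", params["V_ER"]),
        "membrane": Compartment("membrane", None),
    }

    ic = initials
    S: list[Species] = []

    def sp(name, comp, components, initial=0.0, clamped=False):
        S.append(Species(name, comp, components, initial, clamped))

    # seed species
    sp("VEGF", "extracellular", {"VEGF": 1}, ic["VEGF"])
    sp("TSP1", "extracellular", {"TSP1": 1}, ic["TSP1"])
    sp("R2", "membrane", {"R2": 1}, ic["R2"])
    sp("CD47", "membrane", {"CD47": 1}, ic["CD47"])
    sp("Src", "cytosol", {"Src": 1}, ic["Src"])
    sp("PLCg", "cytosol", {"PLCg": 1}, ic["PLCg"])
    sp("PIP2", "membrane", {"PIP2": 1}, ic["PIP2"], clamped=True)
    sp("IP3R", "ER", {"IP3R": 1}, ic["IP3R"], clamped=True)
    sp("Akt", "cytosol", {"Akt": 1}, ic["Akt"])
    sp("Hsp90", "cytosol", {"Hsp90": 1}, ic["Hsp90"])
    sp("CaM", "cytosol", {"CaM": 1}, ic["CaM"])
    sp("eNOS", "cytosol", {"eNOS": 1}, ic["eNOS"])
    sp("Arg", "cytosol", {"Arg": 1, "ArgCit": 1}, ic["Arg"])
    sp("Ca_cyt", "cytosol", {"Ca": 1}, ic["Ca_cyt"])
    sp("Ca_ER", "ER", {"Ca": 1}, ic["Ca_ER"])
    sp("Ca_ext", "extracellular", {"Ca": 1}, ic["Ca_ext"], clamped=True)
    sp("sGC", "cytosol", {"sGC": 1}, ic["sGC"])
    sp("GTP", "cytosol", {"GTP": 1}, ic["GTP"], clamped=True)
    sp("PDE", "cytosol", {"PDE": 1}, ic["PDE"])

    # receptor states
    sp("VEGF_R2", "membrane", {"VEGF": 1, "R2": 1})
    sp("pR2", "membrane", {"VEGF": 1, "R2": 1, "phos": 1})
    sp("CD47_R2", "membrane", {"CD47": 1, "R2": 1})
    sp("CD47_VEGF_R2", "membrane", {"CD47": 1, "VEGF": 1, "R2": 1})
    sp("CD47_pR2", "membrane", {"CD47": 1, "VEGF": 1, "R2": 1, "phos": 1})
    sp("R2_int", "cytosol", {"R2": 1})
    if tsp1_rules:
        sp("TSP1_VEGF", "extracellular", {"TSP1": 1, "VEGF": 1})
        sp("TSP1_CD47", "membrane", {"TSP1": 1, "CD47": 1})

    # Src / Akt / Hsp90
    sp("pSrc", "cytosol", {"Src": 1, "phos": 1})
    sp("pAkt", "cytosol", {"Akt": 1, "phos": 1})
    sp("aHsp90", "cytosol", {"Hsp90": 1})

    # calcium
    sp("pPLCg", "cytosol", {"PLCg": 1, "phos": 1})
    sp("IP3", "cytosol", {"IP3": 1})

    # CaM / eNOS
    sp("CaM2", "cytosol", {"CaM": 1, "Ca": 2})
    sp("CaM4", "cytosol", {"CaM": 1, "Ca": 4})
    sp("eNOS_p", "cytosol", {"eNOS": 1, "phos": 1})
    sp("eNOS_CaM", "cytosol", {"eNOS": 1, "CaM": 1, "Ca": 4})
    sp("eNOS_CaM_p", "cytosol", {"eNOS": 1, "CaM": 1, "Ca": 4, "phos": 1})
    sp("eNOS_Hsp90", "cytosol", {"eNOS": 1, "Hsp90": 1})
    sp("eNOS_Hsp90_p", "cytosol", {"eNOS": 1, "Hsp90": 1, "phos": 1})
    sp("eNOS_CaM_Hsp90", "cytosol", {"eNOS": 1, "CaM": 1, "Ca": 4,
                                     "Hsp90": 1})
    sp("eNOS_CaM_Hsp90_p", "cytosol", {"eNOS": 1, "CaM": 1, "Ca": 4,
                                       "Hsp90": 1, "phos": 1})
    sp("NO", "cytosol", {"NO": 1})
    sp("Cit", "cytosol", {"Cit": 1, "ArgCit": 1})

    # sGC / cGMP / PDE
    sp("sGC_NO", "cytosol", {"sGC": 1, "NO": 1})
    sp("sGC_act", "cytosol", {"sGC": 1, "NO": 1})
    sp("sGC_2NO", "cytosol", {"sGC": 1, "NO": 2})
    sp("cGMP", "cytosol", {"cGMP": 1})
    sp("cGMP_PDE", "cytosol", {"PDE": 1, "cGMP": 1})
    sp("PDE_a1", "cytosol", {"PDE": 1, "cGMP": 1})
    sp("PDE_a2", "cytosol", {"PDE": 1, "cGMP": 1})

    R: list[Reaction] = []

    # ----- receptor module ------------------------------------------------
    R += _rev("vegf_r2", {"VEGF": 1, "R2": 1}, {"VEGF_R2": 1},
              "k_on_VEGF_R2", "k_off_VEGF_R2", "receptor")
    R += _rev("vegf_cr2", {"VEGF": 1, "CD47_R2": 1}, {"CD47_VEGF_R2": 1},
              "k_on_VEGF_R2", "k_off_VEGF_R2", "receptor")
    R.append(_ma("phos_r2", {"VEGF_R2": 1}, {"pR2": 1},
                 RateConstant.of("k_phos_R2", "phos_eff_uncoupled"),
                 "receptor"))
    R.append(_ma("phos_cr2", {"CD47_VEGF_R2": 1}, {"CD47_pR2": 1},
                 "k_phos_R2", "receptor"))
    R.append(_ma("dephos_r2", {"pR2": 1}, {"VEGF_R2": 1}, "k_dephos_R2",
                 "receptor"))
    R.append(_ma("dephos_cr2", {"CD47_pR2": 1}, {"CD47_VEGF_R2": 1},
                 "k_dephos_R2", "receptor"))
    R.append(_ma("int_r2", {"R2": 1}, {"R2_int": 1}, "k_int_R2", "receptor"))
    R.append(_ma("int_vr2", {"VEGF_R2": 1}, {"R2_int": 1}, "k_int_VR2",
                 "receptor"))
    R.append(_ma("int_pr2", {"pR2": 1}, {"R2_int": 1}, "k_int_VR2",
                 "receptor"))
    R.append(_ma("int_cr2", {"CD47_R2": 1}, {"R2_int": 1, "CD47": 1},
                 "k_int_R2", "receptor"))
    R.append(_ma("int_cvr2", {"CD47_VEGF_R2": 1}, {"R2_int": 1, "CD47": 1},
                 "k_int_VR2", "receptor"))
    R.append(_ma("int_cpr2", {"CD47_pR2": 1}, {"R2_int": 1, "CD47": 1},
                 "k_int_VR2", "receptor"))
    R.append(_ma("syn_r2", {}, {"R2": 1}, "k_syn_R2", "receptor"))
    R.append(_ma("deg_r2int", {"R2_int": 1}, {}, "k_deg_R2int", "receptor"))
    for x, cx in (("R2", "CD47_R2"), ("VEGF_R2", "CD47_VEGF_R2"),
                  ("pR2", "CD47_pR2")):
        R += _rev(f"couple_{x}", {"CD47": 1, x: 1}, {cx: 1},
                  "k_couple_CD47_R2", "k_uncouple_CD47_R2", "receptor")
    if tsp1_rules:
        R += _rev("tsp1_cd47", {"TSP1": 1, "CD47": 1}, {"TSP1_CD47": 1},
                  "k_on_TSP1_CD47", "k_off_TSP1_CD47", "tsp1")
        for x, cx in (("R2", "CD47_R2"), ("VEGF_R2", "CD47_VEGF_R2"),
                      ("pR2", "CD47_pR2")):
            R.append(_ma(f"tsp1_uncouple_{x}", {"TSP1": 1, cx: 1},
                         {"TSP1_CD47": 1, x: 1}, "k_on_TSP1_CD47", "tsp1"))
        R += _rev("tsp1_vegf", {"TSP1": 1, "VEGF": 1}, {"TSP1_VEGF": 1},
                  "k_on_TSP1_VEGF", "k_off_TSP1_VEGF", "tsp1")

    # ----- Src / Akt / Hsp90 ----------------------------------------------
    for cat in ("pR2", "CD47_pR2"):
        R.append(_ma(f"p_src_by_{cat}", {cat: 1, "Src": 1},
                     {cat: 1, "pSrc": 1}, "k_p_Src", "src_akt_hsp90"))
        R.append(_ma(f"p_plcg_by_{cat}", {cat: 1, "PLCg": 1},
                     {cat: 1, "pPLCg": 1}, "k_p_PLCg", "calcium"))
    R.append(_ma("dp_src", {"pSrc": 1}, {"Src": 1}, "k_dp_Src",
                 "src_akt_hsp90"))
    R.append(_ma("p_akt", {"pSrc": 1, "Akt": 1}, {"pSrc": 1, "pAkt": 1},
                 "k_p_Akt", "src_akt_hsp90"))
    R.append(_ma("dp_akt", {"pAkt": 1}, {"Akt": 1}, "k_dp_Akt",
                 "src_akt_hsp90"))
    R.append(_ma("a_hsp90", {"pSrc": 1, "Hsp90": 1}, {"pSrc": 1, "aHsp90": 1},
                 "k_a_Hsp90", "src_akt_hsp90"))
    R.append(_ma("d_hsp90", {"aHsp90": 1}, {"Hsp90": 1}, "k_d_Hsp90",
                 "src_akt_hsp90"))
    # Hsp90 association; the phosphorylated CaM-bound complex is mutually
    # stabilised (same gamma on both unbinding legs keeps the binding cycle
    # thermodynamically consistent -- only the ATP-driven phosphorylation
    # step breaks detailed balance between the two layers).
    for x, hx, stab in (("eNOS", "eNOS_Hsp90", False),
                        ("eNOS_p", "eNOS_Hsp90_p", False),
                        ("eNOS_CaM", "eNOS_CaM_Hsp90", False),
                        ("eNOS_CaM_p", "eNOS_CaM_Hsp90_p", True)):
        koff_h = (RateConstant.of("k_off_Hsp90_CaMeNOS",
                                  inverse=("gamma_Hsp90CaM",))
                  if stab else RateConstant.of("k_off_Hsp90_CaMeNOS"))
        R.append(_ma(f"hsp90_{x}_f", {"aHsp90": 1, x: 1}, {hx: 1},
                     "k_on_Hsp90_CaMeNOS", "src_akt_hsp90"))
        R.append(_ma(f"hsp90_{x}_r", {hx: 1}, {"aHsp90": 1, x: 1}, koff_h,
                     "src_akt_hsp90"))
    for x, px in (("eNOS_Hsp90", "eNOS_Hsp90_p"),
                  ("eNOS_CaM_Hsp90", "eNOS_CaM_Hsp90_p")):
        R.append(_ma(f"p_enos_{x}", {"pAkt": 1, x: 1}, {"pAkt": 1, px: 1},
                     "k_p_eNOS", "src_akt_hsp90"))
    for px, x in (("eNOS_p", "eNOS"), ("eNOS_CaM_p", "eNOS_CaM"),
                  ("eNOS_Hsp90_p", "eNOS_Hsp90"),
                  ("eNOS_CaM_Hsp90_p", "eNOS_CaM_Hsp90")):
        R.append(_ma(f"dp_enos_{px}", {px: 1}, {x: 1}, "k_dp_eNOS",
                     "src_akt_hsp90"))

    # ----- calcium ----------------------------------------------------------
    R.append(_ma("dp_plcg", {"pPLCg": 1}, {"PLCg": 1}, "k_dp_PLCg",
                 "calcium"))
    R.append(_mm("ip3_production", "pPLCg", "PIP2", {"IP3": 1},
                 "k_cat_PLCg", "K_M_PLCg", "calcium",
                 consume_substrate=False))  # PIP2 pool is replenished
    R.append(_ma("ip3_degradation", {"IP3": 1}, {}, "k_deg_IP3", "calcium"))
    R.append(Reaction(
        "ip3r_release", {"Ca_ER": 1}, {"Ca_cyt": 1},
        RateLaw("hill_flux", Imax=RateConstant.of("I_IP3R"),
                K=RateConstant.of("K_M_IP3R"), n=1.0, activator="IP3",
                driving=("Ca_ER", "Ca_cyt"), modifier=("IP3R", 1.0)),
        "calcium"))
    R.append(Reaction(
        "crac_influx", {"Ca_ext": 1}, {"Ca_cyt": 1},
        RateLaw("hill_flux", Imax=RateConstant.of("I_CRAC"),
                K=RateConstant.of("K_CRAC"), n=4.0, activator="Ca_ER",
                inhibited=True),
        "calcium"))
    R.append(Reaction(
        "serca_pump", {"Ca_cyt": 1}, {"Ca_ER": 1},
        RateLaw("hill_flux", Imax=RateConstant.of("I_SERCA"),
                K=RateConstant.of("K_M_SERCA"), n=2.0, activator="Ca_cyt"),
        "calcium"))
    R.append(Reaction(
        "pmca_pump", {"Ca_cyt": 1}, {"Ca_ext": 1},
        RateLaw("hill_flux", Imax=RateConstant.of("I_PMCA"),
                K=RateConstant.of("K_M_PMCA"), n=1.0, activator="Ca_cyt"),
        "calcium"))
    R += _rev("er_leak", {"Ca_ER": 1}, {"Ca_cyt": 1}, "k_leak", "k_leak",
              "calcium")
    R.append(_ma("ca_bg_influx", {"Ca_ext": 1}, {"Ca_cyt": 1},
                 "k_in_Ca_bg", "calcium"))

    # ----- eNOS activation ---------------------------------------------------
    R += _rev("cam_n_lobe", {"CaM": 1, "Ca_cyt": 2}, {"CaM2": 1},
              "k_on_Ca2N", "k_off_Ca2N", "enos")
    R += _rev("cam_c_lobe", {"CaM2": 1, "Ca_cyt": 2}, {"CaM4": 1},
              "k_on_Ca2C", "k_off_Ca2C", "enos")
    for x, cx, enhanced in (("eNOS", "eNOS_CaM", False),
                            ("eNOS_p", "eNOS_CaM_p", False),
                            ("eNOS_Hsp90", "eNOS_CaM_Hsp90", False),
                            ("eNOS_Hsp90_p", "eNOS_CaM_Hsp90_p", True)):
        koff = (RateConstant.of("k_off_CaMeNOS", inverse=("gamma_Hsp90CaM",))
                if enhanced else RateConstant.of("k_off_CaMeNOS"))
        R.append(_ma(f"cam_bind_{x}", {"CaM4": 1, x: 1}, {cx: 1},
                     "k_on_CaMeNOS", "enos"))
        R.append(_ma(f"cam_unbind_{cx}", {cx: 1}, {"CaM4": 1, x: 1}, koff,
                     "enos"))

    # ----- eNOS catalysis (Michaelis-Menten in arginine) ---------------------
    K_Arg = RateConstant.of("k_off_Arg", inverse=("k_on_Arg",))
    catalytic_forms = [
        ("eNOS_CaM", RateConstant.of("k_cat_eNOS")),
        ("eNOS_CaM_p", RateConstant.of("k_cat_eNOS", "alpha_phos")),
        ("eNOS_CaM_Hsp90", RateConstant.of("k_cat_eNOS_Hsp90")),
        ("eNOS_CaM_Hsp90_p", RateConstant.of("k_cat_eNOS_Hsp90",
                                             "alpha_phos")),
        # small Ca/CaM-independent basal activity
        ("eNOS", RateConstant.of("k_cat_eNOS", "f_basal_eNOS")),
        ("eNOS_p", RateConstant.of("k_cat_eNOS", "alpha_phos",
                                   "f_basal_eNOS")),
        ("eNOS_Hsp90", RateConstant.of("k_cat_eNOS_Hsp90", "f_basal_eNOS")),
        ("eNOS_Hsp90_p", RateConstant.of("k_cat_eNOS_Hsp90", "alpha_phos",
                                         "f_basal_eNOS")),
    ]
    for form, kcat in catalytic_forms:
        R.append(Reaction(
            f"no_synthesis_{form}", {"Arg": 1}, {"NO": 1, "Cit": 1},
            RateLaw("michaelis_menten", kcat=kcat, Km=K_Arg, enzyme=form),
            "enos"))
    R.append(_ma("no_clearance", {"NO": 1}, {}, "k_clear_NO", "enos"))
    R.append(_ma("cit_recycle", {"Cit": 1}, {"Arg": 1}, "k_recycle_Cit",
                 "enos"))

    # ----- sGC / cGMP / PDE ---------------------------------------------------
    R += _rev("no_sgc", {"NO": 1, "sGC": 1}, {"sGC_NO": 1},
              "k_on_NO_sGC", "k_off_NO_sGC", "sgc")
    R.append(_ma("sgc_activation", {"sGC_NO": 1}, {"sGC_act": 1}, "k_a_sGC",
                 "sgc"))
    R.append(_ma("sgc_deactivation", {"sGC_act": 1}, {"sGC": 1, "NO": 1},
                 "k_off_NO_sGC", "sgc"))
    R += _rev("sgc_desensitise", {"sGC_act": 1, "NO": 1}, {"sGC_2NO": 1},
              "k_f_NOGC_NO", "k_r_NOGC_NO", "sgc")
    R.append(_ma("sgc_recover", {"sGC_2NO": 1}, {"sGC_NO": 1, "NO": 1},
                 "k_off_NO_NOGC", "sgc"))
    R.append(_mm("cgmp_synthesis", "sGC_act", "GTP", {"cGMP": 1},
                 "k_cat_sGC", "K_M_sGC", "sgc", consume_substrate=False))
    R += _rev("cgmp_pde", {"cGMP": 1, "PDE": 1}, {"cGMP_PDE": 1},
              "k_on_cGMP_PDE", "k_off_cGMP_PDE", "sgc")
    R.append(_ma("pde_act1", {"cGMP_PDE": 1}, {"PDE_a1": 1}, "k_a_PDE",
                 "sgc"))
    R.append(_ma("pde_deact1", {"PDE_a1": 1}, {"cGMP_PDE": 1}, "k_d_PDE",
                 "sgc"))
    R.append(_ma("pde_act2", {"PDE_a1": 1}, {"PDE_a2": 1}, "k_a2_PDE",
                 "sgc"))
    R.append(_ma("pde_deact2", {"PDE_a2": 1}, {"PDE_a1": 1}, "k_d2_PDE",
                 "sgc"))
    # hydrolysis product GMP is a terminal sink and is not tracked
    R.append(_mm("cgmp_hydrolysis_a1", "PDE_a1", "cGMP", {},
                 "k_cat_PDE", "K_M_PDE", "sgc"))
    R.append(_mm("cgmp_hydrolysis_a2", "PDE_a2", "cGMP", {},
                 RateConstant.of("k_cat_PDE", factor=2.0), "K_M_PDE",
                 "sgc"))

    return ReactionNetwork(compartments, S, R, params)
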
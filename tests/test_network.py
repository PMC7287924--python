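"""Network construction, configuration validation, and structural laws."""

import numpy as np
import pytest

from enoskit import build_network, default_config, ConfigurationError
from enoskit.network import (SEED_SPECIES, Reaction, RateLaw, RateConstant,
                             Compartment)
from enoskit.odes import CompiledModel
from enoskit.parameters import default_parameters


def test_default_network_contains_tsp1_rules():
    net = build_network()
    names = {r.name for r in net.reactions}
    # reversible TSP1-VEGF sequestration
    assert "tsp1_vegf_f" in names and "tsp1_vegf_r" in names
    # TSP1 ligation of CD47, including removal of the coupled CD47-R2 state
    assert "tsp1_cd47_f" in names
    uncoupling = [r for r in net.reactions
                  if r.name.startswith("tsp1_uncouple")]
    assert uncoupling, "TSP1 binding must disrupt CD47-R2 coupling"
    for r in uncoupling:
        assert "TSP1_CD47" in r.products


def test_exactly_18_nonzero_seed_initials():
    net = build_network()
    seeds = {s.name: s.initial for s in net.species
             if s.name in SEED_SPECIES}
    assert len(seeds) == len(SEED_SPECIES) == 19
    nonzero = [n for n, v in seeds.items() if v > 0]
    assert len(nonzero) == 18
    assert seeds["TSP1"] == 0.0


def test_unknown_species_in_config_rejected():
    cfg = default_config()
    cfg["species"]["NotASpecies"] = 1.0
    with pytest.raises(ConfigurationError):
        build_network(cfg)


def test_missing_seed_species_rejected():
    cfg = default_config()
    del cfg["species"]["CaM"]
    with pytest.raises(ConfigurationError):
        build_network(cfg)


def test_unknown_parameter_rejected():
    cfg = default_config()
    cfg["parameters"]["k_made_up"] = 1.0
    with pytest.raises(ConfigurationError):
        build_network(cfg)


def test_network_without_tsp1_rules_is_well_formed(model):
    cfg = default_config()
    cfg["options"]["tsp1_rules"] = False
    net = build_network(cfg)
    assert "TSP1_CD47" not in net.index
    # simulation at zero TSP1 is unaffected by removing zero-flux rules
    from enoskit.simulate import Model, StimulusCondition, observable
    m2 = Model(net)
    cond = StimulusCondition(vegf_nM=0.389, duration_min=5.0)
    r1 = model.simulate(cond)
    r2 = m2.simulate(cond)
    for obs in ("pR2", "NO", "cGMP"):
        np.testing.assert_allclose(observable(r1, obs), observable(r2, obs),
                                   rtol=1e-4, atol=1e-8)


def test_stoichiometries_are_positive_integers():
    with pytest.raises(ValueError):
        Reaction("bad", {"A": 0}, {},
                 RateLaw("mass_action", kf=RateConstant.of("k_p_Src")),
                 "receptor")
    with pytest.raises(ValueError):
        Reaction("bad", {"A": 1.5}, {},
                 RateLaw("mass_action", kf=RateConstant.of("k_p_Src")),
                 "receptor")


def test_rate_law_field_validation():
    with pytest.raises(ValueError):
        RateLaw("mass_action")  # no constant
    with pytest.raises(ValueError):
        RateLaw("michaelis_menten", kcat=RateConstant.of("k_cat_sGC"))
    with pytest.raises(ValueError):
        RateLaw("hill_flux", Imax=RateConstant.of("I_CRAC"),
                K=RateConstant.of("K_CRAC"), n=0.5, activator="Ca_ER")
    with pytest.raises(ValueError):
        RateLaw("nonsense")


def test_compartment_volumes_validated():
    with pytest.raises(ValueError):
        Compartment("cytosol", -1.0)
    params = default_parameters()
    with pytest.raises(ValueError):
        params.with_values(V_ER=2e-12)  # ER must stay below cytosol


def test_module_tags_cover_all_six_modules():
    net = build_network()
    tags = {r.module_tag for r in net.reactions}
    assert tags == {"receptor", "src_akt_hsp90", "calcium", "enos", "sgc",
                    "tsp1"}


@pytest.mark.parametrize("component", [
    "CaM", "sGC", "PDE", "Src", "Akt", "Hsp90", "PLCg", "CD47", "eNOS",
    "ArgCit"])
def test_conservation_null_vectors(component):
    """Each conserved moiety's membership vector annihilates the raw
    stoichiometric matrix (symbolic conservation, exact)."""
    net = build_network()
    compiled = CompiledModel(net)
    w = compiled.conservation_vector(component)
    assert w.any()
    residual = w @ compiled.N_raw
    np.testing.assert_allclose(residual, 0.0, atol=1e-12)


def test_yaml_config_round_trip(tmp_path):
    import yaml
    from enoskit.network import load_config
    cfg = default_config()
    cfg["species"]["CaM"] = 150.0
    path = tmp_path / "model.yaml"
    path.write_text(yaml.safe_dump({"species": {"CaM": 150.0}}))
    loaded = load_config(path)
    net = build_network(loaded)
    assert net.species[net.index["CaM"]].initial == 150.0
    bad = tmp_path / "bad.yaml"
    bad.write_text("- just\n- a list\n")
    with pytest.raises(ConfigurationError):
        load_config(bad)


def test_parameter_set_vector_round_trip():
    params = default_parameters()
    vec = params.vector()
    back = params.from_vector(vec)
    assert back.to_dict() == params.to_dict()
    with pytest.raises(ValueError):
        params.from_vector(vec[:-1])


def test_parameter_direction_tags_present():
    params = default_parameters()
    for name in params.perturbable():
        assert params.meta(name).direction in ("promotes", "impedes")
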
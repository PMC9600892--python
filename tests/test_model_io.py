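"""Model container, file round-trips, curation, medium closure and fiber carbon."""

import json
import math

import pytest
from hypothesis import given, settings, strategies as st

import steadycross as sx
from steadycross.fba import fba
from steadycross.model_io import (CurationEdit, FiberSpec, Medium, ModelIOError,
                                  ValidationError, apply_curation, apply_medium,
                                  carbon_count, invert_edits, normalize_fiber_polymer,
                                  parse_formula, read_model, write_model)
from steadycross.synthetic import ToyCommunityParams, _degrader_network


@pytest.fixture()
def degrader():
    return _degrader_network(ToyCommunityParams())


# -- formula parsing ---------------------------------------------------------

@settings(derandomize=True, max_examples=50)
@given(st.dictionaries(
    st.sampled_from(["C", "H", "O", "N", "P", "S", "Fe", "Mg"]),
    st.integers(min_value=1, max_value=99), min_size=1, max_size=6))
def test_parse_formula_roundtrip(counts):
    formula = "".join(f"{el}{n}" for el, n in counts.items())
    assert parse_formula(formula) == counts


def test_parse_formula_implicit_one_and_errors():
    assert parse_formula("CH4") == {"C": 1, "H": 4}
    assert parse_formula("") == {} and parse_formula(None) == {}
    assert carbon_count("C6H12O6") == 6
    with pytest.raises(ValidationError):
        parse_formula("C6(H2O)3")


# -- container invariants ----------------------------------------------------

def test_network_invariants_enforced(degrader):
    with pytest.raises(ValidationError, match="undeclared"):
        sx.MetabolicNetwork("bad", list(degrader.metabolites),
                            [sx.Reaction("R1", stoichiometry={"ghost": 1.0})],
                            "R1", "R1")
    with pytest.raises(ValidationError, match="exactly one metabolite"):
        sx.MetabolicNetwork(
            "bad", list(degrader.metabolites),
            [sx.Reaction("EX", stoichiometry={"lac_e": -1.0, "ace_e": -1.0},
                         is_exchange=True)],
            "EX", "EX")
    with pytest.raises(ValidationError):
        sx.Reaction("R", stoichiometry={}, lower_bound=1.0, upper_bound=-1.0)


# -- JSON and SBML round-trips -----------------------------------------------

def test_json_roundtrip_is_fixed_point(degrader, tmp_path):
    p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
    write_model(degrader, p1)
    again = read_model(p1)
    write_model(again, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert again.model_id == degrader.model_id
    assert {r.id for r in again.reactions} == {r.id for r in degrader.reactions}
    for rxn in degrader.reactions:
        back = again.reaction(rxn.id)
        assert back.stoichiometry == pytest.approx(rxn.stoichiometry)
        assert (back.lower_bound, back.upper_bound) == (rxn.lower_bound, rxn.upper_bound)


def test_sbml_roundtrip_preserves_stoichiometry(degrader, tmp_path):
    path = tmp_path / "m.xml"
    write_model(degrader, path, format="sbml_fbc")
    again = read_model(path, format="sbml_fbc")
    assert {r.id for r in again.reactions} == {r.id for r in degrader.reactions}
    for rxn in degrader.reactions:
        back = again.reaction(rxn.id)
        assert back.stoichiometry == pytest.approx(rxn.stoichiometry)
        assert back.is_exchange == rxn.is_exchange
    assert again.biomass_reaction_id == degrader.biomass_reaction_id


def test_sbml_export_agrees_with_independent_parser(degrader, tmp_path):
    """The SBML written here must parse identically under cobra's reader."""
    cobra = pytest.importorskip("cobra")
    path = tmp_path / "m.xml"
    write_model(degrader, path, format="sbml_fbc")
    model = cobra.io.read_sbml_model(str(path))
    assert {r.id for r in model.reactions} == {r.id for r in degrader.reactions}
    for rxn in degrader.reactions:
        other = model.reactions.get_by_id(rxn.id)
        theirs = {m.id: c for m, c in other.metabolites.items()}
        assert theirs == pytest.approx(rxn.stoichiometry)


def test_malformed_files_raise_named_errors(tmp_path):
    bad = tmp_path / "bad.json"
    bad.write_text("{not json")
    with pytest.raises(ModelIOError, match="invalid JSON"):
        read_model(bad)
    nobio = tmp_path / "nobio.json"
    nobio.write_text(json.dumps({
        "model_id": "m", "metabolites": [], "reactions": [],
        "biomass_reaction_id": "BIO", "objective_reaction_id": "BIO"}))
    with pytest.raises(ModelIOError, match="BIO"):
        read_model(nobio)
    with pytest.raises(FileNotFoundError):
        read_model(tmp_path / "missing.json")


# -- curation ----------------------------------------------------------------

def test_curation_empty_and_inverse(degrader):
    same, log = apply_curation(degrader, [])
    assert log == [] and {r.id for r in same.reactions} == {r.id for r in degrader.reactions}

    edits = [
        CurationEdit("add_reaction", {"id": "NEW", "stoichiometry": {"lac_c": -1.0},
                                      "lower_bound": 0.0, "upper_bound": 5.0}),
        CurationEdit("set_bounds", {"id": "EX_lac", "upper_bound": 7.0}),
        CurationEdit("set_formula", {"id": "lac_c", "formula": "C3H6O3"}),
    ]
    edited, _ = apply_curation(degrader, edits)
    assert edited.reaction("EX_lac").upper_bound == 7.0
    restored, _ = apply_curation(edited, invert_edits(degrader, edits))
    assert {r.id for r in restored.reactions} == {r.id for r in degrader.reactions}
    assert restored.reaction("EX_lac").upper_bound == degrader.reaction("EX_lac").upper_bound
    assert restored.metabolite("lac_c").formula == degrader.metabolite("lac_c").formula


def test_curation_atomic_with_failing_index(degrader):
    edits = [CurationEdit("set_bounds", {"id": "EX_lac", "upper_bound": 7.0}),
             CurationEdit("remove_reaction", {"id": "NOT_THERE"})]
    with pytest.raises(ValidationError, match="edit 1"):
        apply_curation(degrader, edits)
    assert degrader.reaction("EX_lac").upper_bound != 7.0  # input untouched


def test_bound_widening_changes_fba_optimum():
    """Doubling the uptake cap doubles growth on a linear yield chain."""
    cm, medium = sx.make_single_yield_member(biomass_yield=0.1, uptake_cap=10.0)
    (tag, net), = cm.members
    net = apply_medium(net, medium)
    assert fba(net).objective_value == pytest.approx(1.0, abs=1e-9)
    widened, _ = apply_curation(net, [CurationEdit(
        "set_bounds", {"id": "EX_s", "lower_bound": -20.0})])
    assert fba(widened).objective_value == pytest.approx(2.0, abs=1e-9)


# -- medium ------------------------------------------------------------------

def test_medium_closure_rule(degrader):
    medium = Medium(uptake_bounds={"EX_fiber": 1.0}, carbon_source_id="EX_fiber",
                    excess_value=1000.0)
    out = apply_medium(degrader, medium)
    assert out.reaction("EX_fiber").lower_bound == -1.0
    # every other exchange carries carbon -> closed to uptake
    for rxn in out.exchanges():
        if rxn.id != "EX_fiber":
            assert rxn.lower_bound == 0.0
            assert rxn.upper_bound == degrader.reaction(rxn.id).upper_bound


def test_medium_missing_carbon_source_starves(degrader):
    # lactate as sole carbon source: the degrader cannot grow on its own product
    medium = Medium(uptake_bounds={"EX_lac": 10.0}, carbon_source_id="EX_lac")
    out = apply_medium(degrader, medium)
    assert fba(out).objective_value == pytest.approx(0.0, abs=1e-9)


def test_medium_unknown_exchange_listed(degrader):
    medium = Medium(uptake_bounds={"EX_nope": 1.0}, carbon_source_id="EX_nope")
    with pytest.raises(ValidationError, match="EX_nope"):
        apply_medium(degrader, medium)


def test_medium_invariants():
    with pytest.raises(ValidationError):
        Medium(uptake_bounds={"EX_a": 1.0}, carbon_source_id="EX_b")
    with pytest.raises(ValidationError):
        Medium(uptake_bounds={"EX_a": -1.0}, carbon_source_id="EX_a")


# -- fiber normalization -----------------------------------------------------

def test_fiber_carbon_accounting(degrader):
    fiber = FiberSpec(fiber_id="fiber_c", monomer_id="monomer_c",
                      average_dp=25, carbon_per_monomer=6)
    assert fiber.carbon_per_unit == 150
    out = normalize_fiber_polymer(degrader, fiber, degradation_id="HYD_fiber")
    hyd = out.reaction("HYD_fiber")
    assert hyd.stoichiometry["monomer_c"] == 25.0
    assert carbon_count(out.metabolite("fiber_c").formula) == 150


def test_fiber_imbalance_detected(degrader):
    # claim 4 C per monomer while the monomer formula says 6 C
    fiber = FiberSpec(fiber_id="fiber_c", monomer_id="monomer_c",
                      average_dp=5, carbon_per_monomer=4)
    with pytest.raises(ValidationError, match="[cC]arbon|C,"):
        normalize_fiber_polymer(degrader, fiber, degradation_id="HYD_fiber")


def test_growth_per_carbon_invariant_across_dp():
    """After normalization, fibers of different chain length give equal growth
    per carbon on a yield-only model: the polymer basis cancels out."""
    rates = {}
    for dp in (5, 10):
        cm, ans, _ = sx.make_toy_degrader_butyrogen(
            sx.ToyCommunityParams(average_dp=dp))
        sol = sx.max_community_growth(cm)
        carbon_in = dp * 6 * 1.0  # dp monomers x 6 C x uptake cap
        rates[dp] = sol.mu / carbon_in
    assert rates[5] == pytest.approx(rates[10], rel=1e-4)
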
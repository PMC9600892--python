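"""SteadyCom optimization: bisection, fiber minimization, duality, FVA."""

import numpy as np
import pytest

import steadycross as sx
from steadycross.community import CommunityError, MU_TOLERANCE, _CommunityLP


def test_single_member_reduces_to_scaled_fba():
    """One member, uptake cap 10, yield 0.1 -> community optimum 1.0 h^-1."""
    cm, _ = sx.make_single_yield_member(biomass_yield=0.1, uptake_cap=10.0)
    sol = sx.max_community_growth(cm)
    assert sol.mu == pytest.approx(1.0, abs=2 * MU_TOLERANCE)
    assert sol.abundances["single"] == pytest.approx(1.0, abs=1e-6)


def test_max_growth_matches_answer_sheet(toy_community):
    cm, ans, _ = toy_community
    sol = sx.max_community_growth(cm)
    assert sol.mu == pytest.approx(ans["mu_star"], abs=2 * MU_TOLERANCE)
    assert sol.abundances["degrader"] == pytest.approx(ans["x_degrader"], abs=1e-4)
    assert sol.abundances["butyrogen"] == pytest.approx(ans["x_butyrogen"], abs=1e-4)


def test_bisection_agrees_with_grid_oracle(toy_community, oracle_grid_max_growth):
    cm, ans, _ = toy_community
    oracle = oracle_grid_max_growth(cm)
    assert sx.max_community_growth(cm).mu == pytest.approx(oracle, abs=2 * MU_TOLERANCE)
    single, _ = sx.make_single_yield_member(0.1, 10.0)
    assert sx.max_community_growth(single).mu == pytest.approx(
        oracle_grid_max_growth(single), abs=2 * MU_TOLERANCE)


def test_min_fiber_uptake_analytic(toy_community):
    cm, ans, _ = toy_community
    mu = 0.3
    sol = sx.min_fiber_uptake(cm, mu, "fiber_e")
    assert sol.fiber_uptake == pytest.approx(mu * ans["u_min_per_mu"], rel=1e-6)
    # the fiber split: only the degrader consumes fiber in this topology
    assert sol.exchange_fluxes[("degrader", "fiber_e")] == pytest.approx(
        -sol.fiber_uptake, abs=1e-6)


def test_min_uptake_max_growth_duality(toy_community, coupled_pair):
    """Minimal fiber uptake at growth mu, then maximum growth at that fiber
    budget, returns mu: the two problems are dual formulations."""
    cm, ans, _ = toy_community
    for mu in (0.2, 0.3):
        sol = sx.min_fiber_uptake(cm, mu, "fiber_e")
        back = sx.max_community_growth(cm, fiber_budget=("fiber_e", sol.fiber_uptake))
        assert back.mu == pytest.approx(mu, abs=2 * MU_TOLERANCE)
    single, _ = sx.make_single_yield_member(0.1, 10.0)
    sol = sx.min_fiber_uptake(single, 0.5, "s_e")
    assert sol.fiber_uptake == pytest.approx(0.5 / 0.1, rel=1e-6)
    back = sx.max_community_growth(single, fiber_budget=("s_e", sol.fiber_uptake))
    assert back.mu == pytest.approx(0.5, abs=2 * MU_TOLERANCE)


def test_infeasible_growth_reports_max_feasible(toy_community):
    cm, ans, _ = toy_community
    with pytest.raises(CommunityError, match="maximum feasible"):
        sx.min_fiber_uptake(cm, ans["mu_star"] * 2.0, "fiber_e")


def test_unbounded_growth_detected():
    # no cap on the substrate: community growth has no finite optimum
    cm, medium = sx.make_single_yield_member(biomass_yield=1.0, uptake_cap=1e9)
    with pytest.raises(CommunityError, match="unbounded|bracket"):
        sx.max_community_growth(cm)


def test_suboptimal_budget_linearity(toy_community, toy_scenario):
    """On a linear yield chain u' = (1+eps) * u_min exactly; eps=0 is u_min."""
    cm, ans, _ = toy_community
    u_min = sx.min_fiber_uptake(cm, toy_scenario.mu_exp, "fiber_e").fiber_uptake
    eps0 = sx.ScenarioSpec(mu_exp=toy_scenario.mu_exp, fiber_id="fiber_e",
                           suboptimality_factor=0.0)
    assert sx.suboptimal_budget(cm, eps0) == pytest.approx(u_min, rel=1e-6)
    u_prime = sx.suboptimal_budget(cm, toy_scenario)
    assert u_prime == pytest.approx(1.05 * u_min, rel=1e-6)


def test_fva_matches_analytic_vertices(coupled_pair):
    """One-dimensional coupled pair: the polytope's two vertices are the closed
    chain at 0 and at the secretion cap; FVA must return exactly those."""
    cm, ans, _ = coupled_pair
    scenario = sx.ScenarioSpec(mu_exp=ans["mu0"], fiber_id=ans["fiber_pool_id"],
                               suboptimality_factor=0.0)
    ranges = {r.quantity_id: r for r in sx.community_fva(
        cm, scenario,
        quantities=[ans["producer_exchange"], ans["consumer_exchange"],
                    "abundance:producer", "abundance:consumer"],
        fiber_budget=ans["fiber_budget"])}
    lo, hi = ans["fva_range"]
    assert ranges[ans["producer_exchange"]].min == pytest.approx(lo, abs=1e-6)
    assert ranges[ans["producer_exchange"]].max == pytest.approx(hi, abs=1e-6)
    assert ranges[ans["consumer_exchange"]].min == pytest.approx(-hi, abs=1e-6)
    assert ranges[ans["consumer_exchange"]].max == pytest.approx(-lo, abs=1e-6)
    for tag, x in ans["abundances"].items():
        fr = ranges[f"abundance:{tag}"]
        assert fr.min == pytest.approx(x, abs=1e-6)
        assert fr.max == pytest.approx(x, abs=1e-6)


def test_fva_abundance_ranges_match_closed_form(toy_community, toy_scenario,
                                                toy_budget):
    """Degrader abundance ranges over [x*, (1+eps) x*]: fiber uptake is the only
    driver of degrader biomass, and the budget allows at most (1+eps) of it."""
    cm, ans, _ = toy_community
    ranges = {r.quantity_id: r for r in sx.community_fva(
        cm, toy_scenario, fiber_budget=toy_budget)}
    x = ans["x_degrader"]
    assert ranges["abundance:degrader"].min == pytest.approx(x, abs=1e-5)
    assert ranges["abundance:degrader"].max == pytest.approx(1.05 * x, abs=1e-5)
    assert ranges["abundance:butyrogen"].min == pytest.approx(1 - 1.05 * x, abs=1e-5)
    assert ranges["abundance:butyrogen"].max == pytest.approx(1 - x, abs=1e-5)


def test_fva_point_feasible_scenario_collapses(toy_community):
    """With eps=0 the fiber budget pins the optimum: all ranges have min == max."""
    cm, ans, _ = toy_community
    eps0 = sx.ScenarioSpec(mu_exp=0.3, fiber_id="fiber_e", suboptimality_factor=0.0)
    for fr in sx.community_fva(cm, eps0,
                               quantities=["abundance:degrader",
                                           "degrader:EX_fiber"]):
        assert fr.max - fr.min == pytest.approx(0.0, abs=1e-6)


def test_fva_contains_sampled_points(toy_community, toy_scenario, toy_budget,
                                     toy_samples):
    """Every feasible point's value lies inside its FVA range."""
    cm, _, _ = toy_community
    ranges = sx.community_fva(cm, toy_scenario, fiber_budget=toy_budget)
    idx = np.random.default_rng(5).choice(toy_samples.samples.shape[0], 100,
                                          replace=False)
    for fr in ranges:
        col = toy_samples.column(fr.quantity_id)[idx]
        assert np.all(col >= fr.min - 1e-6)
        assert np.all(col <= fr.max + 1e-6)


def test_growth_monotone_in_uptake_bound():
    mus = []
    for cap in (5.0, 10.0, 20.0):
        cm, _ = sx.make_single_yield_member(biomass_yield=0.1, uptake_cap=cap)
        mus.append(sx.max_community_growth(cm).mu)
    assert mus[0] <= mus[1] + 1e-9 <= mus[2] + 2e-9


def test_witness_satisfies_all_constraints(toy_community):
    """The attached solution obeys mass balance, biomass coupling, scaled bounds
    and abundance normalization within tolerance."""
    cm, _, _ = toy_community
    mu = 0.3
    sol = sx.min_fiber_uptake(cm, mu, "fiber_e")
    assert sum(sol.abundances.values()) == pytest.approx(1.0, abs=1e-6)
    lp = _CommunityLP(cm, mu)
    z = np.zeros(lp.n)
    for (tag, rid), j in lp.flux_index.items():
        z[j] = sol.member_fluxes[tag][rid]
    for tag, j in lp.abundance_index.items():
        z[j] = sol.abundances[tag]
    for pool, j in lp.exchange_index.items():
        z[j] = sol.community_exchange[pool]
    assert lp.to_polytope().contains(z, tol=1e-5)
    for tag, net in cm.members:
        assert sol.member_fluxes[tag][net.biomass_reaction_id] == pytest.approx(
            mu * sol.abundances[tag], abs=1e-6)


def test_assembly_pool_structure(toy_community):
    cm, _, _ = toy_community
    assert set(cm.pool_metabolites) == {"fiber_e", "lac_e", "suc_e", "ace_e", "but_e"}
    # closed lactate pool: community exchange pinned to zero
    assert cm.community_exchange_bounds["lac_e"] == (0.0, 0.0)
    # fiber supplied by the medium, carbon products closed to uptake
    assert cm.community_exchange_bounds["fiber_e"][0] == pytest.approx(-1.0)
    assert cm.community_exchange_bounds["ace_e"][0] == 0.0


def test_assembly_rejects_unknown_medium_exchange(toy_community):
    cm, _, medium = toy_community
    from steadycross.model_io import Medium
    bad = Medium(uptake_bounds={"EX_unobtainium": 1.0},
                 carbon_source_id="EX_unobtainium")
    with pytest.raises(CommunityError, match="EX_unobtainium"):
        sx.assemble_community(cm.members, bad)
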
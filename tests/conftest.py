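"""Shared fixtures: synthetic communities, scenarios and pre-computed samples.

Sampling fixtures are session-scoped so the hit-and-run chains run once for
the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest

import steadycross as sx
from steadycross.community import _feasible
from steadycross.sampling import LinearPolytope, SamplerConfig, sample_hit_and_run


def grid_max_growth(cm, bracket=(0.0, 2.0), fiber_budget=None,
                    steps=(1e-1, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6)):
    """Fine-grid feasibility oracle for the maximum balanced growth rate.

    Walks the growth-rate axis with successively refined steps, keeping the
    largest feasible μ at each resolution — an exhaustive search that shares
    no logic with the bisection routine it checks.
    """
    lo, hi = bracket
    mu = lo
    for step in steps:
        while mu + step <= hi and _feasible(cm, mu + step, fiber_budget) is not None:
            mu += step
    return mu


@pytest.fixture(scope="session")
def oracle_grid_max_growth():
    return grid_max_growth


def unit_box(n: int) -> LinearPolytope:
    return LinearPolytope(A_eq=np.zeros((0, n)), b_eq=np.zeros(0),
                          A_ub=np.zeros((0, n)), b_ub=np.zeros(0),
                          lb=np.zeros(n), ub=np.ones(n),
                          names=[f"x{i}" for i in range(n)])


@pytest.fixture(scope="session")
def box4() -> LinearPolytope:
    return unit_box(4)


@pytest.fixture(scope="session")
def toy_community():
    """Default degrader/butyrogen community with its analytic answer sheet."""
    return sx.make_toy_degrader_butyrogen()


@pytest.fixture(scope="session")
def toy_scenario():
    return sx.ScenarioSpec(mu_exp=0.3, fiber_id="fiber_e", suboptimality_factor=0.05)


@pytest.fixture(scope="session")
def toy_budget(toy_community, toy_scenario):
    cm, _, _ = toy_community
    return sx.suboptimal_budget(cm, toy_scenario)


@pytest.fixture(scope="session")
def toy_polytope(toy_community, toy_scenario, toy_budget):
    cm, _, _ = toy_community
    return sx.scenario_polytope(cm, toy_scenario, fiber_budget=toy_budget)


@pytest.fixture(scope="session")
def toy_samples(toy_polytope):
    cfg = SamplerConfig(n_samples=3000, thinning=20, seed=7)
    return sample_hit_and_run(toy_polytope, cfg)


@pytest.fixture(scope="session")
def coupled_pair():
    return sx.make_coupled_pair()


@pytest.fixture(scope="session")
def pair_polytope(coupled_pair):
    cm, ans, _ = coupled_pair
    scenario = sx.ScenarioSpec(mu_exp=ans["mu0"], fiber_id=ans["fiber_pool_id"],
                               suboptimality_factor=0.0)
    return sx.scenario_polytope(cm, scenario, fiber_budget=ans["fiber_budget"])


@pytest.fixture(scope="session")
def pair_samples(pair_polytope):
    cfg = SamplerConfig(n_samples=2000, thinning=10, seed=1)
    return sample_hit_and_run(pair_polytope, cfg)
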
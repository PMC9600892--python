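"""SteadyCom-style community flux balance analysis.

Members of a community are joined through a shared extracellular pool: each
member's exchange reaction is rewired into a transfer between the member's
own boundary metabolite and the pool species, and the pool itself exchanges
with the environment through community exchange reactions carrying the medium
bounds.  All members grow at a common rate μ, member fluxes are absolute
(per unit total community biomass) and scale with the member's abundance
X_k, giving the balanced-growth feasibility system

    S_k · V_k = 0                       (member steady state)
    LB_jk · X_k ≤ V_jk ≤ UB_jk · X_k    (abundance-scaled capacity)
    V_biomass,k = μ · X_k               (biomass coupling)
    Σ_k X_k = total_abundance           (normalization, default 1)
    pool balance: member transfers and community exchanges sum to zero.

For fixed μ this is a linear program; the maximum balanced community growth
rate is the largest μ for which it is feasible, located by bisection.  The
suboptimal scenario fixes μ at the experimentally observed community growth
rate while granting the fiber budget that would allow (1+ε)-fold faster
growth, opening a flux polytope explored by FVA and Monte Carlo sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model_io import Medium, MetabolicNetwork, ValidationError, carbon_count
from .sampling import LinearPolytope

__all__ = [
    "CommunityModel",
    "ScenarioSpec",
    "SteadyComSolution",
    "FluxRange",
    "CommunityError",
    "assemble_community",
    "max_community_growth",
    "min_fiber_uptake",
    "suboptimal_budget",
    "community_fva",
    "scenario_polytope",
]

MU_TOLERANCE = 1e-6        # h^-1, bisection convergence
LP_TOLERANCE = 1e-9        # primal feasibility tolerance passed to HiGHS
MU_BRACKET = (0.0, 10.0)   # h^-1, growth-rate search bracket

_LP_OPTIONS = {"primal_feasibility_tolerance": LP_TOLERANCE,
               "dual_feasibility_tolerance": LP_TOLERANCE}


class CommunityError(Exception):
    """Infeasible, unbounded or ill-posed community problem."""


@dataclass(frozen=True)
class ScenarioSpec:
    """Experimental scenario: fixed community growth and fiber relaxation.

    ``mu_exp`` is the observed community growth rate (0.35 h⁻¹ on inulin,
    0.09 h⁻¹ on xylan in the motivating system); ``suboptimality_factor`` is
    the growth headroom ε granted to the fiber budget (default 5%).
    """

    mu_exp: float
    fiber_id: str               # pool metabolite id of the fiber
    suboptimality_factor: float = 0.05
    total_abundance: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_exp <= 0:
            raise ValidationError("mu_exp must be positive")
        if self.suboptimality_factor < 0:
            raise ValidationError("suboptimality_factor must be non-negative")


@dataclass(frozen=True)
class SteadyComSolution:
    mu: float
    abundances: dict[str, float]                    # member tag -> X_k
    member_fluxes: dict[str, dict[str, float]]      # tag -> reaction -> absolute flux
    fiber_uptake: float                             # magnitude, mmol/h
    exchange_fluxes: dict[tuple[str, str], float]   # (tag, pool metabolite) -> flux
    community_exchange: dict[str, float]            # pool metabolite -> env. exchange flux


@dataclass(frozen=True)
class FluxRange:
    quantity_id: str
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.min > self.max + 1e-9:
            raise ValidationError(f"{self.quantity_id}: min {self.min} > max {self.max}")


@dataclass
class CommunityModel:
    """Member networks joined through a shared extracellular pool."""

    members: list[tuple[str, MetabolicNetwork]]
    pool_metabolites: list[str]
    community_exchange_bounds: dict[str, tuple[float, float]]
    pool_map: dict[tuple[str, str], str] = field(default_factory=dict)
    total_abundance: float = 1.0

    def member_tags(self) -> list[str]:
        return [tag for tag, _ in self.members]

    def pool_id(self, tag: str, met_id: str) -> str:
        return self.pool_map.get((tag, met_id), met_id)


def assemble_community(members: list[tuple[str, MetabolicNetwork]], medium: Medium,
                       pool_map: dict[tuple[str, str], str] | None = None,
                       total_abundance: float = 1.0) -> CommunityModel:
    """Join member models through a shared pool and apply the medium at its boundary.

    ``pool_map`` maps (member tag, boundary metabolite id) to a pool species id;
    unmapped boundary metabolites keep their own id, so members that name the
    same extracellular species automatically share it.  Medium uptake bounds
    are keyed by member exchange reaction ids; pool species supplied by the
    medium open at the stated magnitude, carbon-containing species not in the
    medium are closed to uptake, and carbon-free species open at the excess
    value.  Secretion to the environment is unbounded.
    """
    if not members:
        raise CommunityError("community needs at least one member")
    tags = [t for t, _ in members]
    if len(set(tags)) != len(tags):
        raise CommunityError(f"duplicate member tags: {tags}")
    pool_map = dict(pool_map or {})

    pool_mets: dict[str, bool] = {}   # pool id -> contains carbon
    medium_magnitude: dict[str, float] = {}
    for tag, net in members:
        for rxn in net.exchanges():
            met_id = net.exchange_metabolite(rxn)
            pool = pool_map.get((tag, met_id), met_id)
            met = net.metabolite(met_id)
            has_c = carbon_count(met.formula) > 0
            pool_mets[pool] = pool_mets.get(pool, False) or has_c
            if rxn.id in medium.uptake_bounds:
                mag = abs(medium.uptake_bounds[rxn.id])
                prev = medium_magnitude.get(pool)
                medium_magnitude[pool] = mag if prev is None else max(prev, mag)
    unknown = set(medium.uptake_bounds) - {
        rxn.id for _, net in members for rxn in net.exchanges()}
    if unknown:
        raise CommunityError(f"medium exchanges not found in any member: {sorted(unknown)}")

    exchange_bounds: dict[str, tuple[float, float]] = {}
    for pool, has_c in pool_mets.items():
        if pool in medium_magnitude:
            lb = -medium_magnitude[pool]
        elif has_c:
            lb = 0.0
        else:
            lb = -abs(medium.excess_value)
        exchange_bounds[pool] = (lb, math.inf)

    return CommunityModel(
        members=list(members),
        pool_metabolites=sorted(pool_mets),
        community_exchange_bounds=exchange_bounds,
        pool_map=pool_map,
        total_abundance=total_abundance,
    )


# ---------------------------------------------------------------------------
# LP assembly at fixed μ
# ---------------------------------------------------------------------------

class _CommunityLP:
    """The fixed-μ SteadyCom feasibility LP, with named variables.

    Variables, in order: member fluxes (absolute), member abundances,
    community exchange fluxes for pool species that have an environment
    exchange.  Quantity ids follow ``<tag>:<reaction>``, ``abundance:<tag>``
    and ``community:<pool metabolite>``.
    """

    def __init__(self, cm: CommunityModel, mu: float,
                 fiber_budget: tuple[str, float] | None = None):
        self.cm = cm
        self.mu = mu
        names: list[str] = []
        lb: list[float] = []
        ub: list[float] = []

        self.flux_index: dict[tuple[str, str], int] = {}
        for tag, net in cm.members:
            for rxn in net.reactions:
                self.flux_index[(tag, rxn.id)] = len(names)
                names.append(f"{tag}:{rxn.id}")
                lb.append(min(rxn.lower_bound, 0.0))
                ub.append(max(rxn.upper_bound, 0.0))
        self.abundance_index: dict[str, int] = {}
        for tag, _ in cm.members:
            self.abundance_index[tag] = len(names)
            names.append(f"abundance:{tag}")
            lb.append(0.0)
            ub.append(cm.total_abundance)
        self.exchange_index: dict[str, int] = {}
        for pool in cm.pool_metabolites:
            if pool in cm.community_exchange_bounds:
                e_lb, e_ub = cm.community_exchange_bounds[pool]
                self.exchange_index[pool] = len(names)
                names.append(f"community:{pool}")
                lb.append(e_lb)
                ub.append(e_ub)
        if fiber_budget is not None:
            fiber_id, budget = fiber_budget
            if fiber_id not in self.exchange_index:
                raise CommunityError(f"fiber {fiber_id!r} has no community exchange")
            j = self.exchange_index[fiber_id]
            lb[j] = max(lb[j], -abs(budget))

        self.names = names
        self.n = len(names)
        self.lb = np.array(lb)
        self.ub = np.array(ub)

        eq_rows: list[dict[int, float]] = []
        eq_rhs: list[float] = []
        ub_rows: list[dict[int, float]] = []
        ub_rhs: list[float] = []

        pool_rows: dict[str, dict[int, float]] = {p: {} for p in cm.pool_metabolites}
        for tag, net in cm.members:
            met_rows: dict[str, dict[int, float]] = {m.id: {} for m in net.metabolites}
            for rxn in net.reactions:
                j = self.flux_index[(tag, rxn.id)]
                for met_id, coeff in rxn.stoichiometry.items():
                    met_rows[met_id][j] = met_rows[met_id].get(j, 0.0) + coeff
                if rxn.is_exchange:
                    met_id = net.exchange_metabolite(rxn)
                    pool = cm.pool_id(tag, met_id)
                    coeff = rxn.stoichiometry[met_id]
                    # rewired exchange: flux leaving the member enters the pool
                    pool_rows[pool][j] = pool_rows[pool].get(j, 0.0) - coeff
            for row in met_rows.values():
                if row:
                    eq_rows.append(row)
                    eq_rhs.append(0.0)
            # biomass coupling V_bio = mu * X
            xj = self.abundance_index[tag]
            eq_rows.append({self.flux_index[(tag, net.biomass_reaction_id)]: 1.0,
                            xj: -mu})
            eq_rhs.append(0.0)
            # abundance-scaled capacity rows for finite nonzero bounds
            for rxn in net.reactions:
                j = self.flux_index[(tag, rxn.id)]
                if math.isfinite(rxn.lower_bound) and rxn.lower_bound != 0.0:
                    ub_rows.append({j: -1.0, xj: rxn.lower_bound})   # lb*X - V <= 0
                    ub_rhs.append(0.0)
                if math.isfinite(rxn.upper_bound) and rxn.upper_bound != 0.0:
                    ub_rows.append({j: 1.0, xj: -rxn.upper_bound})   # V - ub*X <= 0
                    ub_rhs.append(0.0)
        for pool, row in pool_rows.items():
            if pool in self.exchange_index:
                row[self.exchange_index[pool]] = row.get(self.exchange_index[pool], 0.0) - 1.0
            eq_rows.append(dict(row))
            eq_rhs.append(0.0)
        # abundance normalization
        eq_rows.append({self.abundance_index[t]: 1.0 for t in cm.member_tags()})
        eq_rhs.append(cm.total_abundance)

        self.A_eq = self._dense(eq_rows)
        self.b_eq = np.array(eq_rhs)
        self.A_ub = self._dense(ub_rows)
        self.b_ub = np.array(ub_rhs)

    def _dense(self, rows: list[dict[int, float]]) -> np.ndarray:
        A = np.zeros((len(rows), self.n))
        for i, row in enumerate(rows):
            for j, v in row.items():
                A[i, j] = v
        return A

    def quantity_index(self, quantity_id: str) -> int:
        try:
            return self.names.index(quantity_id)
        except ValueError:
            raise KeyError(quantity_id) from None

    def solve(self, c: np.ndarray | None = None) -> np.ndarray | None:
        """Solve min c·z (feasibility when c is None); None if infeasible."""
        cvec = np.zeros(self.n) if c is None else c
        res = linprog(cvec, A_eq=self.A_eq, b_eq=self.b_eq,
                      A_ub=self.A_ub if len(self.b_ub) else None,
                      b_ub=self.b_ub if len(self.b_ub) else None,
                      bounds=list(zip(self.lb, self.ub)),
                      method="highs", options=dict(_LP_OPTIONS))
        if res.status == 3:
            raise CommunityError("community LP unbounded — no limiting uptake bound")
        if res.status != 0:
            return None
        return res.x

    def to_polytope(self) -> LinearPolytope:
        return LinearPolytope(A_eq=self.A_eq, b_eq=self.b_eq, A_ub=self.A_ub,
                              b_ub=self.b_ub, lb=self.lb.copy(), ub=self.ub.copy(),
                              names=list(self.names))

    def solution(self, z: np.ndarray) -> SteadyComSolution:
        cm = self.cm
        abundances = {t: float(z[self.abundance_index[t]]) for t in cm.member_tags()}
        member_fluxes = {
            tag: {rxn.id: float(z[self.flux_index[(tag, rxn.id)]]) for rxn in net.reactions}
            for tag, net in cm.members
        }
        exchange_fluxes = {}
        for tag, net in cm.members:
            for rxn in net.exchanges():
                pool = cm.pool_id(tag, net.exchange_metabolite(rxn))
                exchange_fluxes[(tag, pool)] = float(z[self.flux_index[(tag, rxn.id)]])
        community_exchange = {p: float(z[j]) for p, j in self.exchange_index.items()}
        return SteadyComSolution(
            mu=self.mu, abundances=abundances, member_fluxes=member_fluxes,
            fiber_uptake=0.0, exchange_fluxes=exchange_fluxes,
            community_exchange=community_exchange,
        )


def _feasible(cm: CommunityModel, mu: float,
              fiber_budget: tuple[str, float] | None = None) -> np.ndarray | None:
    return _CommunityLP(cm, mu, fiber_budget).solve()


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def max_community_growth(cm: CommunityModel, mu_tolerance: float = MU_TOLERANCE,
                         bracket: tuple[float, float] = MU_BRACKET,
                         fiber_budget: tuple[str, float] | None = None
                         ) -> SteadyComSolution:
    """Largest balanced community growth rate, located by bisection on feasibility."""
    lo, hi = bracket
    if _feasible(cm, lo, fiber_budget) is None:
        raise CommunityError(f"community infeasible even at mu = {lo}")
    if _feasible(cm, hi, fiber_budget) is not None:
        raise CommunityError(
            f"community growth unbounded: feasible at bracket top mu = {hi} "
            "(check uptake bounds)")
    while hi - lo > mu_tolerance:
        mid = 0.5 * (lo + hi)
        if _feasible(cm, mid, fiber_budget) is not None:
            lo = mid
        else:
            hi = mid
    lp = _CommunityLP(cm, lo, fiber_budget)
    z = lp.solve()
    if z is None:  # numerically marginal at the bracket edge; step inward
        lp = _CommunityLP(cm, max(lo - mu_tolerance, bracket[0]), fiber_budget)
        z = lp.solve()
        if z is None:
            raise CommunityError("no witness solution at converged mu")
    sol = lp.solution(z)
    return sol


def _min_abs_exchange_secondary(lp: _CommunityLP, fiber_j: int, fiber_value: float
                                ) -> np.ndarray:
    """Resolve LP degeneracy: minimize Σ|member exchange fluxes| at the optimum.

    Splits each member exchange flux into an auxiliary magnitude variable
    t ≥ ±V and minimizes Σt with the fiber exchange pinned at its optimum.
    """
    cm = lp.cm
    ex_cols = [lp.flux_index[(tag, rxn.id)]
               for tag, net in cm.members for rxn in net.exchanges()]
    n, m = lp.n, len(ex_cols)
    lb = np.concatenate([lp.lb, np.zeros(m)])
    ub = np.concatenate([lp.ub, np.full(m, np.inf)])
    lb[fiber_j] = fiber_value - 1e-9
    ub[fiber_j] = fiber_value + 1e-9
    A_eq = np.hstack([lp.A_eq, np.zeros((lp.A_eq.shape[0], m))])
    rows = []
    for i, j in enumerate(ex_cols):
        r = np.zeros(n + m)
        r[j] = 1.0
        r[n + i] = -1.0
        rows.append(r.copy())       # V - t <= 0
        r[j] = -1.0
        rows.append(r)              # -V - t <= 0
    A_ub = np.vstack([np.hstack([lp.A_ub, np.zeros((lp.A_ub.shape[0], m))]),
                      np.array(rows)]) if len(lp.b_ub) else np.array(rows)
    b_ub = np.concatenate([lp.b_ub, np.zeros(2 * m)])
    c = np.zeros(n + m)
    c[n:] = 1.0
    res = linprog(c, A_eq=A_eq, b_eq=lp.b_eq, A_ub=A_ub, b_ub=b_ub,
                  bounds=list(zip(lb, ub)), method="highs", options=dict(_LP_OPTIONS))
    if res.status != 0:
        raise CommunityError(f"secondary exchange-minimization LP failed: {res.message}")
    return res.x[:n]


def min_fiber_uptake(cm: CommunityModel, mu_fixed: float, fiber_id: str
                     ) -> SteadyComSolution:
    """Minimal community fiber uptake sustaining balanced growth at ``mu_fixed``.

    Equivalent to maximum community growth under fixed fiber consumption.  The
    reported flux distribution additionally minimizes the total absolute
    member exchange flux, resolving LP degeneracy at the optimum.
    """
    lp = _CommunityLP(cm, mu_fixed)
    if fiber_id not in lp.exchange_index:
        raise CommunityError(f"fiber {fiber_id!r} has no community exchange")
    fiber_j = lp.exchange_index[fiber_id]
    c = np.zeros(lp.n)
    c[fiber_j] = -1.0  # uptake is negative: maximizing E minimizes its magnitude
    z = lp.solve(c)
    if z is None:
        best = max_community_growth(cm)
        raise CommunityError(
            f"infeasible at mu = {mu_fixed}; maximum feasible community growth "
            f"is {best.mu:.6f} h^-1")
    fiber_value = float(z[fiber_j])
    z = _min_abs_exchange_secondary(lp, fiber_j, fiber_value)
    sol = lp.solution(z)
    return SteadyComSolution(
        mu=sol.mu, abundances=sol.abundances, member_fluxes=sol.member_fluxes,
        fiber_uptake=abs(fiber_value), exchange_fluxes=sol.exchange_fluxes,
        community_exchange=sol.community_exchange,
    )


def suboptimal_budget(cm: CommunityModel, scenario: ScenarioSpec) -> float:
    """Fiber uptake budget u′ allowing (1+ε)-fold faster community growth.

    Downstream analyses run at μ = mu_exp with fiber uptake ≤ u′, which opens
    the flux variability the suboptimal scenario is designed to expose.
    """
    mu_target = (1.0 + scenario.suboptimality_factor) * scenario.mu_exp
    try:
        sol = min_fiber_uptake(cm, mu_target, scenario.fiber_id)
    except CommunityError as exc:
        raise CommunityError(
            f"suboptimal target growth {mu_target:.6f} h^-1 unreachable: {exc}") from exc
    return sol.fiber_uptake


def scenario_polytope(cm: CommunityModel, scenario: ScenarioSpec,
                      fiber_budget: float | None = None) -> LinearPolytope:
    """The suboptimal flux polytope: μ fixed at mu_exp, fiber uptake ≤ u′."""
    if fiber_budget is None:
        fiber_budget = suboptimal_budget(cm, scenario)
    lp = _CommunityLP(cm, scenario.mu_exp, (scenario.fiber_id, fiber_budget))
    if lp.solve() is None:
        raise CommunityError(
            f"suboptimal scenario infeasible at mu = {scenario.mu_exp}")
    return lp.to_polytope()


def community_fva(cm: CommunityModel, scenario: ScenarioSpec,
                  quantities: list[str] | None = None,
                  fiber_budget: float | None = None) -> list[FluxRange]:
    """Flux variability of abundances and exchange fluxes in the suboptimal scenario.

    ``quantities`` are variable names (``abundance:<tag>``, ``<tag>:<reaction>``
    or ``community:<pool metabolite>``); by default all abundances and member
    exchange fluxes are scanned.  Each range is the min/max of one LP pair over
    the constrained polytope.
    """
    if fiber_budget is None:
        fiber_budget = suboptimal_budget(cm, scenario)
    lp = _CommunityLP(cm, scenario.mu_exp, (scenario.fiber_id, fiber_budget))
    if lp.solve() is None:
        raise CommunityError(f"suboptimal scenario infeasible at mu = {scenario.mu_exp}")
    if quantities is None:
        quantities = [f"abundance:{t}" for t in cm.member_tags()]
        for tag, net in cm.members:
            quantities += [f"{tag}:{rxn.id}" for rxn in net.exchanges()]
    out = []
    for q in quantities:
        j = lp.quantity_index(q)
        c = np.zeros(lp.n)
        c[j] = 1.0
        z_min = lp.solve(c)
        c[j] = -1.0
        z_max = lp.solve(c)
        if z_min is None or z_max is None:
            raise CommunityError(f"FVA LP for {q} infeasible")
        lo, hi = float(z_min[j]), float(z_max[j])
        if lo > hi:  # numerically degenerate interval
            lo = hi = 0.5 * (lo + hi)
        out.append(FluxRange(quantity_id=q, min=lo, max=hi))
    return out
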
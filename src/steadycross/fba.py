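"""Single-organism flux balance analysis on a :class:`MetabolicNetwork`.

Solves max c·v subject to S·v = 0, lb ≤ v ≤ ub with the HiGHS solver through
scipy.  This is the workhorse behind phenotype prediction; the community-level
problems live in :mod:`steadycross.community`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import lil_matrix

from .model_io import MetabolicNetwork

__all__ = ["FBAResult", "InfeasibleError", "fba", "flux_variability"]


class InfeasibleError(Exception):
    """The steady-state LP has no feasible solution (or is unbounded)."""


@dataclass(frozen=True)
class FBAResult:
    objective_value: float
    fluxes: dict[str, float]


def _stoichiometric_matrix(net: MetabolicNetwork):
    met_index = {m.id: i for i, m in enumerate(net.metabolites)}
    S = lil_matrix((len(net.metabolites), len(net.reactions)))
    for j, r in enumerate(net.reactions):
        for met_id, coeff in r.stoichiometry.items():
            S[met_index[met_id], j] = coeff
    return S.tocsr()


def fba(net: MetabolicNetwork, objective_id: str | None = None,
        maximize: bool = True, extra_bounds: dict[str, tuple[float, float]] | None = None
        ) -> FBAResult:
    """Optimize one reaction flux at steady state.

    ``extra_bounds`` maps reaction ids to (lb, ub) overrides for this solve
    only, used e.g. to pin growth while maximizing a secretion flux.
    """
    objective_id = objective_id or net.objective_reaction_id
    rxn_index = {r.id: j for j, r in enumerate(net.reactions)}
    if objective_id not in rxn_index:
        raise KeyError(objective_id)
    n = len(net.reactions)
    c = np.zeros(n)
    c[rxn_index[objective_id]] = -1.0 if maximize else 1.0
    bounds = [(r.lower_bound, r.upper_bound) for r in net.reactions]
    if extra_bounds:
        for rid, (lb, ub) in extra_bounds.items():
            bounds[rxn_index[rid]] = (lb, ub)
    S = _stoichiometric_matrix(net)
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    if res.status != 0:
        raise InfeasibleError(
            f"{net.model_id}: LP {'in' if res.status == 2 else ''}feasible/unbounded "
            f"(status {res.status}: {res.message})"
        )
    fluxes = {r.id: float(res.x[j]) for j, r in enumerate(net.reactions)}
    sign = -1.0 if maximize else 1.0
    return FBAResult(objective_value=float(sign * res.fun), fluxes=fluxes)


def flux_variability(net: MetabolicNetwork, reaction_ids: list[str],
                     fraction_of_optimum: float = 1.0) -> dict[str, tuple[float, float]]:
    """Min/max each listed flux while growth stays ≥ fraction_of_optimum × μ*."""
    mu_star = fba(net).objective_value
    pin = {net.objective_reaction_id: (fraction_of_optimum * mu_star,
                                       net.reaction(net.objective_reaction_id).upper_bound)}
    out = {}
    for rid in reaction_ids:
        lo = fba(net, objective_id=rid, maximize=False, extra_bounds=pin).objective_value
        hi = fba(net, objective_id=rid, maximize=True, extra_bounds=pin).objective_value
        out[rid] = (lo, hi)
    return out
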
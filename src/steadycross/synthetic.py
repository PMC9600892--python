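"""Synthetic communities and fixtures with analytically known optima.

The flagship generator builds a two-member toy community that mirrors the
degrader/butyrogen topology of fiber fermentation in the gut: a primary
degrader hydrolyzes a fiber polymer into monomers and ferments them to
lactate, succinate and acetate, while a butyrogen grows on the degrader's
lactate (plus co-consumed acetate) and secretes butyrate.  Because every
member is a linear yield chain, the maximum balanced community growth rate,
the minimal fiber uptake at fixed growth and the optimal abundances all have
closed forms, recorded in an answer sheet next to the model:

    r        = min(l, a/q)                 effective lactate use per monomer
    Y        = dp · (y_d + y_b · r)        community biomass per fiber unit
    μ*       = Y · u_cap                   maximum balanced growth
    u_min(μ) = μ / Y                       minimal fiber uptake at growth μ
    X_d*     = y_d / (y_d + y_b · r)       degrader abundance at the optimum

where dp is the fiber's degree of polymerization, y_d/y_b the biomass yields,
l, s, a the degrader's lactate/succinate/acetate secretion per monomer and q
the butyrogen's acetate co-consumption per lactate.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .community import CommunityModel, ScenarioSpec, assemble_community
from .model_io import (FiberSpec, Medium, MetabolicNetwork, Metabolite, Reaction,
                       ValidationError, normalize_fiber_polymer, write_model)
from .validation import PhenotypeRow, PhenotypeTable

__all__ = [
    "ToyCommunityParams",
    "make_toy_degrader_butyrogen",
    "make_coupled_pair",
    "make_phenotype_fixture",
    "make_single_yield_member",
    "write_fixtures",
]

_FORMULAS = {
    "monomer": "C6H12O6",
    "lactate": "C3H5O3",
    "succinate": "C4H4O4",
    "acetate": "C2H3O2",
    "butyrate": "C4H7O2",
}
_CARBON = {"monomer": 6, "lactate": 3, "succinate": 4, "acetate": 2, "butyrate": 4}
_BIG = 1000.0


@dataclass(frozen=True)
class ToyCommunityParams:
    """Yields and caps of the degrader/butyrogen chain (defaults carbon-balanced).

    Yields are gDW biomass per mmol of the limiting substrate; secretion
    coefficients are mmol per mmol monomer (degrader) or per mmol lactate
    (butyrogen).  The degrader's fermentation must not emit more carbon than
    the monomer carries, and likewise for the butyrogen's butyrate output;
    the remainder is biomass carbon.
    """

    average_dp: int = 5
    degrader_biomass_yield: float = 0.02       # y_d, gDW/mmol monomer
    lactate_per_monomer: float = 1.0           # l
    succinate_per_monomer: float = 0.3         # s
    acetate_per_monomer: float = 0.6           # a
    butyrogen_biomass_yield: float = 0.05      # y_b, gDW/mmol lactate
    acetate_per_lactate: float = 0.5           # q
    butyrate_per_lactate: float = 0.7          # b
    fiber_uptake_cap: float = 1.0              # community uptake, mmol/h
    lactate_community_export: bool = False     # closed pool = fully coupled lactate
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("average_dp", "degrader_biomass_yield", "lactate_per_monomer",
                     "fiber_uptake_cap"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("succinate_per_monomer", "acetate_per_monomer",
                     "butyrogen_biomass_yield", "acetate_per_lactate",
                     "butyrate_per_lactate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        deg_c = (_CARBON["monomer"]
                 - _CARBON["lactate"] * self.lactate_per_monomer
                 - _CARBON["succinate"] * self.succinate_per_monomer
                 - _CARBON["acetate"] * self.acetate_per_monomer)
        if deg_c < -1e-9:
            raise ValidationError(
                f"degrader fermentation emits {-deg_c:.3f} mmol C per monomer more "
                "than the monomer carries")
        but_c = (_CARBON["lactate"] + _CARBON["acetate"] * self.acetate_per_lactate
                 - _CARBON["butyrate"] * self.butyrate_per_lactate)
        if but_c < -1e-9:
            raise ValidationError(
                f"butyrogen emits {-but_c:.3f} mmol C per lactate more than it takes up")

    @property
    def effective_lactate_use(self) -> float:
        """Butyrogen lactate throughput per monomer of fiber at the optimum.

        r = min(l, (1.5·l + a) / (1.5 + q)): when acetate is limiting, the
        degrader's lactate→acetate shunt (3 C lactate to 1.5 × 2 C acetate)
        reroutes just enough lactate to balance the butyrogen's co-consumption.
        """
        if self.butyrogen_biomass_yield == 0:
            return 0.0
        if self.acetate_per_lactate == 0:
            return self.lactate_per_monomer
        return min(self.lactate_per_monomer,
                   (1.5 * self.lactate_per_monomer + self.acetate_per_monomer)
                   / (1.5 + self.acetate_per_lactate))

    @property
    def community_yield_per_fiber(self) -> float:
        return self.average_dp * (self.degrader_biomass_yield
                                  + self.butyrogen_biomass_yield
                                  * self.effective_lactate_use)


def _degrader_network(p: ToyCommunityParams) -> MetabolicNetwork:
    y, l, s, a = (p.degrader_biomass_yield, p.lactate_per_monomer,
                  p.succinate_per_monomer, p.acetate_per_monomer)
    mets = [
        Metabolite("fiber_e", "fiber (extracellular)", "", "e"),
        Metabolite("fiber_c", "fiber (cytosolic)", "", "c"),
        Metabolite("monomer_c", "fiber monomer", _FORMULAS["monomer"], "c"),
        Metabolite("lac_c", "lactate", _FORMULAS["lactate"], "c"),
        Metabolite("lac_e", "lactate (extracellular)", _FORMULAS["lactate"], "e"),
        Metabolite("suc_c", "succinate", _FORMULAS["succinate"], "c"),
        Metabolite("suc_e", "succinate (extracellular)", _FORMULAS["succinate"], "e"),
        Metabolite("ace_c", "acetate", _FORMULAS["acetate"], "c"),
        Metabolite("ace_e", "acetate (extracellular)", _FORMULAS["acetate"], "e"),
    ]
    rxns = [
        Reaction("EX_fiber", "fiber exchange", {"fiber_e": -1.0}, -_BIG, 0.0, True),
        Reaction("T_fiber", "fiber import", {"fiber_e": -1.0, "fiber_c": 1.0}, 0.0, math.inf),
        Reaction("HYD_fiber", "fiber hydrolysis",
                 {"fiber_c": -1.0, "monomer_c": float(p.average_dp)}, 0.0, math.inf),
        Reaction("BIOMASS_degrader", "fermentative growth",
                 {"monomer_c": -1.0 / y, "lac_c": l / y, "suc_c": s / y, "ace_c": a / y},
                 0.0, 10.0),
        Reaction("LACTATE_SHUNT", "lactate to acetate rerouting",
                 {"lac_c": -1.0, "ace_c": 1.5}, 0.0, math.inf),
        Reaction("T_lac", "lactate export", {"lac_c": -1.0, "lac_e": 1.0}, 0.0, math.inf),
        Reaction("EX_lac", "lactate exchange", {"lac_e": -1.0}, 0.0, _BIG, True),
        Reaction("T_suc", "succinate export", {"suc_c": -1.0, "suc_e": 1.0}, 0.0, math.inf),
        Reaction("EX_suc", "succinate exchange", {"suc_e": -1.0}, 0.0, _BIG, True),
        Reaction("T_ace", "acetate export", {"ace_c": -1.0, "ace_e": 1.0}, 0.0, math.inf),
        Reaction("EX_ace", "acetate exchange", {"ace_e": -1.0}, 0.0, _BIG, True),
    ]
    net = MetabolicNetwork("toy_degrader", mets, rxns,
                           biomass_reaction_id="BIOMASS_degrader",
                           objective_reaction_id="BIOMASS_degrader")
    fiber = FiberSpec(fiber_id="fiber_c", monomer_id="monomer_c",
                      average_dp=p.average_dp, carbon_per_monomer=_CARBON["monomer"])
    net = normalize_fiber_polymer(net, fiber, degradation_id="HYD_fiber")
    # the boundary copy of the fiber gets the same normalized formula
    fib_c = net.metabolite("fiber_c")
    idx = net.metabolites.index(net.metabolite("fiber_e"))
    net.metabolites[idx] = Metabolite("fiber_e", "fiber (extracellular)",
                                      fib_c.formula, "e")
    return net


def _butyrogen_network(p: ToyCommunityParams) -> MetabolicNetwork:
    y, q, b = (p.butyrogen_biomass_yield, p.acetate_per_lactate, p.butyrate_per_lactate)
    mets = [
        Metabolite("lac_e", "lactate (extracellular)", _FORMULAS["lactate"], "e"),
        Metabolite("lac_b", "lactate", _FORMULAS["lactate"], "c"),
        Metabolite("ace_e", "acetate (extracellular)", _FORMULAS["acetate"], "e"),
        Metabolite("ace_b", "acetate", _FORMULAS["acetate"], "c"),
        Metabolite("but_b", "butyrate", _FORMULAS["butyrate"], "c"),
        Metabolite("but_e", "butyrate (extracellular)", _FORMULAS["butyrate"], "e"),
    ]
    y_eff = y if y > 0 else 1.0  # y == 0 disables growth via the zero upper bound
    rxns = [
        Reaction("EX_lac", "lactate exchange", {"lac_e": -1.0}, -_BIG, 0.0, True),
        Reaction("T_lac", "lactate import", {"lac_e": -1.0, "lac_b": 1.0}, 0.0, math.inf),
        Reaction("EX_ace", "acetate exchange", {"ace_e": -1.0}, -_BIG, 0.0, True),
        Reaction("T_ace", "acetate import", {"ace_e": -1.0, "ace_b": 1.0}, 0.0, math.inf),
        Reaction("BIOMASS_butyrogen", "butyrogenic growth",
                 {"lac_b": -1.0 / y_eff, "ace_b": -q / y_eff, "but_b": b / y_eff},
                 0.0, 10.0 if y > 0 else 0.0),
        Reaction("LACTATE_OVERFLOW", "growth-independent lactate to acetate rerouting",
                 {"lac_b": -1.0, "ace_b": 1.5}, 0.0, math.inf),
        Reaction("T_but", "butyrate export", {"but_b": -1.0, "but_e": 1.0}, 0.0, math.inf),
        Reaction("EX_but", "butyrate exchange", {"but_e": -1.0}, 0.0, _BIG, True),
    ]
    return MetabolicNetwork("toy_butyrogen", mets, rxns,
                            biomass_reaction_id="BIOMASS_butyrogen",
                            objective_reaction_id="BIOMASS_butyrogen")


def make_toy_degrader_butyrogen(params: ToyCommunityParams | None = None
                                ) -> tuple[CommunityModel, dict, Medium]:
    """Two-member degrader/butyrogen community plus its analytic answer sheet.

    The answer sheet carries the closed-form optimum (see module docstring),
    the limiting substrate of the butyrogen and the exchange pairs that are
    mass-balance coupled.  Carbon-imbalanced parameters raise
    :class:`ValidationError` at parameter construction.
    """
    p = params or ToyCommunityParams()
    degrader = _degrader_network(p)
    butyrogen = _butyrogen_network(p)
    medium = Medium(uptake_bounds={"EX_fiber": p.fiber_uptake_cap},
                    carbon_source_id="EX_fiber", excess_value=_BIG)
    cm = assemble_community([("degrader", degrader), ("butyrogen", butyrogen)], medium)
    if not p.lactate_community_export:
        # no environment sink: degrader secretion must equal butyrogen uptake
        cm.community_exchange_bounds["lac_e"] = (0.0, 0.0)

    r = p.effective_lactate_use
    Y = p.community_yield_per_fiber
    mu_star = Y * p.fiber_uptake_cap
    denom = p.degrader_biomass_yield + p.butyrogen_biomass_yield * r
    x_deg = p.degrader_biomass_yield / denom
    if p.acetate_per_lactate == 0:
        limiting = "lactate"
    else:
        limiting = ("lactate" if p.lactate_per_monomer
                    <= p.acetate_per_monomer / p.acetate_per_lactate else "acetate")
    answers = {
        "params": asdict(p),
        "mu_star": mu_star,
        "community_yield_per_fiber": Y,
        "u_min_per_mu": 1.0 / Y,
        "x_degrader": x_deg,
        "x_butyrogen": 1.0 - x_deg,
        "limiting_substrate": limiting,
        "fiber_pool_id": "fiber_e",
        "exchange_pairs": [
            ["degrader:EX_lac", "butyrogen:EX_lac"],
            ["degrader:EX_ace", "butyrogen:EX_ace"],
        ],
        # with the lactate pool closed to the environment the lactate pair is
        # mass-balance coupled: Pearson coefficient exactly -1 in sampling
        "coupled_pairs": ([] if p.lactate_community_export
                          else [["degrader:EX_lac", "butyrogen:EX_lac"]]),
    }
    return cm, answers, medium


def make_coupled_pair(seed: int = 0, mu0: float = 0.1, cap_m: float = 2.0
                      ) -> tuple[CommunityModel, dict, Medium]:
    """Minimal producer/consumer pair sharing one metabolite with no community sink.

    Each member's private biomass substrate cap equals exactly half the
    community biomass demand at growth ``mu0``, which pins both abundances at
    1/2.  The producer's overflow route converts a second substrate into the
    shared metabolite ``m``; pool ``m_e`` has no environment exchange, so the
    consumer must absorb the secretion flux-for-flux.  The one remaining
    degree of freedom is that overflow, ranging over [0, ``cap_m``].
    """
    producer = MetabolicNetwork(
        "toy_producer",
        metabolites=[
            Metabolite("sp_e", "producer substrate (extracellular)", "C6H12O6", "e"),
            Metabolite("sp_c", "producer substrate", "C6H12O6", "c"),
            Metabolite("so_e", "overflow substrate (extracellular)", "C6H12O6", "e"),
            Metabolite("so_c", "overflow substrate", "C6H12O6", "c"),
            Metabolite("m_c", "shared metabolite", "C3H5O3", "c"),
            Metabolite("m_e", "shared metabolite (extracellular)", "C3H5O3", "e"),
        ],
        reactions=[
            Reaction("EX_sp", "substrate exchange", {"sp_e": -1.0}, -_BIG, 0.0, True),
            Reaction("T_sp", "substrate import", {"sp_e": -1.0, "sp_c": 1.0}, 0.0, math.inf),
            Reaction("BIOMASS_producer", "growth", {"sp_c": -1.0}, 0.0, 10.0),
            Reaction("EX_so", "overflow substrate exchange", {"so_e": -1.0},
                     -_BIG, 0.0, True),
            Reaction("T_so", "overflow substrate import", {"so_e": -1.0, "so_c": 1.0},
                     0.0, math.inf),
            Reaction("OVERFLOW", "overflow secretion route",
                     {"so_c": -1.0, "m_c": 1.0}, 0.0, math.inf),
            Reaction("T_m", "shared metabolite export", {"m_c": -1.0, "m_e": 1.0},
                     0.0, math.inf),
            Reaction("EX_m", "shared metabolite exchange", {"m_e": -1.0},
                     0.0, 2.0 * cap_m, True),
        ],
        biomass_reaction_id="BIOMASS_producer",
        objective_reaction_id="BIOMASS_producer",
    )
    consumer = MetabolicNetwork(
        "toy_consumer",
        metabolites=[
            Metabolite("sc_e", "consumer substrate (extracellular)", "C6H12O6", "e"),
            Metabolite("sc_c", "consumer substrate", "C6H12O6", "c"),
            Metabolite("m_e", "shared metabolite (extracellular)", "C3H5O3", "e"),
            Metabolite("m_b", "shared metabolite", "C3H5O3", "c"),
        ],
        reactions=[
            Reaction("EX_sc", "substrate exchange", {"sc_e": -1.0}, -_BIG, 0.0, True),
            Reaction("T_sc", "substrate import", {"sc_e": -1.0, "sc_c": 1.0}, 0.0, math.inf),
            Reaction("BIOMASS_consumer", "growth", {"sc_c": -1.0}, 0.0, 10.0),
            Reaction("EX_m_upt", "shared metabolite uptake", {"m_e": -1.0}, -_BIG, 0.0, True),
            Reaction("T_m_upt", "shared metabolite import", {"m_e": -1.0, "m_b": 1.0},
                     0.0, math.inf),
            Reaction("DISPOSE_m", "shared metabolite disposal", {"m_b": -1.0},
                     0.0, math.inf),
        ],
        biomass_reaction_id="BIOMASS_consumer",
        objective_reaction_id="BIOMASS_consumer",
    )
    half = mu0 / 2.0
    medium = Medium(uptake_bounds={"EX_sp": half, "EX_so": cap_m, "EX_sc": half},
                    carbon_source_id="EX_sp", excess_value=_BIG)
    cm = assemble_community([("producer", producer), ("consumer", consumer)], medium)
    del cm.community_exchange_bounds["m_e"]  # no environment sink for the shared pool
    answers = {
        "seed": seed,
        "mu0": mu0,
        "cap_m": cap_m,
        "shared_pool_id": "m_e",
        "producer_exchange": "producer:EX_m",
        "consumer_exchange": "consumer:EX_m_upt",
        "fva_range": [0.0, cap_m],
        "abundances": {"producer": 0.5, "consumer": 0.5},
        "fiber_pool_id": "sp_e",
        "fiber_budget": half,
    }
    return cm, answers, medium


def make_single_yield_member(biomass_yield: float = 0.1, uptake_cap: float = 10.0
                             ) -> tuple[CommunityModel, Medium]:
    """One-member community with analytic optimum μ* = yield × uptake cap."""
    net = MetabolicNetwork(
        "toy_single",
        metabolites=[
            Metabolite("s_e", "substrate (extracellular)", "C6H12O6", "e"),
            Metabolite("s_c", "substrate", "C6H12O6", "c"),
        ],
        reactions=[
            Reaction("EX_s", "substrate exchange", {"s_e": -1.0}, -_BIG, 0.0, True),
            Reaction("T_s", "substrate import", {"s_e": -1.0, "s_c": 1.0}, 0.0, math.inf),
            Reaction("BIOMASS", "growth", {"s_c": -1.0 / biomass_yield}, 0.0, 10.0),
        ],
        biomass_reaction_id="BIOMASS",
        objective_reaction_id="BIOMASS",
    )
    medium = Medium(uptake_bounds={"EX_s": uptake_cap}, carbon_source_id="EX_s",
                    excess_value=_BIG)
    return assemble_community([("single", net)], medium), medium


def make_phenotype_fixture(n_rows: int = 12, error_rate: float = 0.0, seed: int = 0
                           ) -> tuple[MetabolicNetwork, PhenotypeTable, Medium, dict]:
    """Network plus phenotype truth table with known confusion counts.

    The network can grow on a seeded random subset of ``n_rows`` substrates;
    the table's experimental column disagrees with the model's behavior on
    exactly ``round(error_rate · n_rows)`` rows.  Expected TP/FP/TN/FN counts
    are returned alongside.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValidationError("error_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    usable = rng.random(n_rows) < 0.5
    usable[0] = True  # the base medium needs one growth-supporting carbon source
    mets = [Metabolite("prec_c", "growth precursor", "C6H12O6", "c")]
    rxns = [Reaction("BIOMASS", "growth", {"prec_c": -1.0}, 0.0, _BIG)]
    for i in range(n_rows):
        mets += [Metabolite(f"sub{i}_e", f"substrate {i} (extracellular)", "C6H12O6", "e"),
                 Metabolite(f"sub{i}_c", f"substrate {i}", "C6H12O6", "c")]
        rxns += [Reaction(f"EX_sub{i}", f"substrate {i} exchange",
                          {f"sub{i}_e": -1.0}, -10.0, 0.0, True),
                 Reaction(f"T_sub{i}", f"substrate {i} import",
                          {f"sub{i}_e": -1.0, f"sub{i}_c": 1.0}, 0.0, math.inf)]
        if usable[i]:
            rxns.append(Reaction(f"CONV_sub{i}", f"substrate {i} catabolism",
                                 {f"sub{i}_c": -1.0, "prec_c": 1.0}, 0.0, math.inf))
    net = MetabolicNetwork("toy_phenotype", mets, rxns,
                           biomass_reaction_id="BIOMASS",
                           objective_reaction_id="BIOMASS")
    medium = Medium(uptake_bounds={"EX_sub0": 10.0}, carbon_source_id="EX_sub0",
                    excess_value=_BIG)

    n_flips = round(error_rate * n_rows)
    flip_rows = set(rng.choice(n_rows, size=n_flips, replace=False).tolist())
    rows, counts = [], {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for i in range(n_rows):
        experimental = bool(usable[i]) ^ (i in flip_rows)
        rows.append(PhenotypeRow(compound_id=f"EX_sub{i}", assay_kind="substrate_growth",
                                 experimental=experimental,
                                 source_note="synthetic truth table"))
        if usable[i] and experimental:
            counts["tp"] += 1
        elif usable[i] and not experimental:
            counts["fp"] += 1
        elif not usable[i] and experimental:
            counts["fn"] += 1
        else:
            counts["tn"] += 1
    expected = dict(counts)
    tp, fp, fn, tn = counts["tp"], counts["fp"], counts["fn"], counts["tn"]
    expected["f_score"] = (2 * tp / (2 * tp + fp + fn)) if (2 * tp + fp + fn) else 0.0
    expected["accuracy"] = (tp + tn) / n_rows
    expected["precision"] = tp / (tp + fp) if (tp + fp) else 0.0
    return net, PhenotypeTable(tuple(rows)), medium, expected


def write_fixtures(out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write the toy models, media, phenotype table and answer sheets to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    cm, answers, medium = make_toy_degrader_butyrogen(ToyCommunityParams(seed=seed))
    for tag, net in cm.members:
        path = out / f"{tag}.json"
        write_model(net, path)
        written.append(path)
    (out / "toy_community_answers.json").write_text(json.dumps(answers, indent=2) + "\n")
    written.append(out / "toy_community_answers.json")
    medium_doc = {"uptake_bounds": dict(medium.uptake_bounds),
                  "carbon_source_id": medium.carbon_source_id,
                  "excess_value": medium.excess_value}
    (out / "toy_medium.yaml").write_text(yaml.safe_dump(medium_doc))
    written.append(out / "toy_medium.yaml")

    net, table, ph_medium, expected = make_phenotype_fixture(seed=seed)
    write_model(net, out / "toy_phenotype.json")
    written.append(out / "toy_phenotype.json")
    ph_medium_doc = {"uptake_bounds": dict(ph_medium.uptake_bounds),
                     "carbon_source_id": ph_medium.carbon_source_id,
                     "excess_value": ph_medium.excess_value}
    (out / "toy_phenotype_medium.yaml").write_text(yaml.safe_dump(ph_medium_doc))
    written.append(out / "toy_phenotype_medium.yaml")
    with open(out / "toy_phenotypes.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "assay_kind", "experimental", "note"])
        for row in table.rows:
            w.writerow([row.compound_id, row.assay_kind,
                        "positive" if row.experimental else "negative",
                        row.source_note])
    written.append(out / "toy_phenotypes.csv")
    (out / "toy_phenotype_expected.json").write_text(json.dumps(expected, indent=2) + "\n")
    written.append(out / "toy_phenotype_expected.json")
    return written
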
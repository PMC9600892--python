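"""End-to-end scenario orchestration.

One YAML config drives the full analysis: load member models, apply curation
edits and the medium, optionally validate against phenotype tables, assemble
the community, solve the SteadyCom problems at the experimental growth rate,
compute the suboptimal fiber budget, run FVA, sample the flux polytope and
classify exchanged metabolites.  Every run leaves a manifest with the config
snapshot, seed, software version, per-stage timings and a checksum per
written file; re-running with the same config and seed reproduces all
outputs byte-identically.

Config schema (YAML)::

    members:
      - tag: degrader
        model: degrader.json          # JSON dialect or SBML (.xml)
        curation: edits.yaml          # optional
        phenotypes: phenotypes.csv    # optional, enables validation
    medium: medium.yaml
    scenario:
      mu_exp: 0.2                     # h^-1, experimental community growth
      fiber_id: fiber_e               # pool metabolite of the fiber
      suboptimality_factor: 0.05
    sampler:
      n_samples: 2000
      thinning: 100
    alpha: 0.01
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .community import (ScenarioSpec, assemble_community, community_fva,
                        max_community_growth, min_fiber_uptake, scenario_polytope,
                        suboptimal_budget)
from .model_io import apply_curation, apply_medium, load_curation_file, \
    load_medium_file, read_model
from .sampling import SamplerConfig, sample_hit_and_run
from .stats import classify_exchanges, summarize_densities
from .validation import load_phenotype_table, predict_phenotypes, score_validation

logger = logging.getLogger(__name__)

__all__ = ["StageError", "run_scenario", "write_outputs"]


class StageError(Exception):
    """A pipeline stage failed; carries the stage name and the config hash."""

    def __init__(self, stage: str, config_hash: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed (config {config_hash}): {cause}")
        self.stage = stage
        self.config_hash = config_hash
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_scenario(config_path: str | Path, out_dir: str | Path, seed: int = 0,
                 force: bool = False) -> dict:
    """Execute all stages in order and write all reports under ``out_dir``.

    Returns the run record (also written as ``manifest.json``).  A stage
    failure leaves the completed stages' outputs on disk next to an
    ``error_manifest.json`` and raises :class:`StageError`.
    """
    config_path = Path(config_path)
    config = yaml.safe_load(config_path.read_text())
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    base = config_path.parent

    record: dict = {"config": config, "config_hash": config_hash, "seed": seed,
                    "version": __version__, "stages": {}, "files": {}}
    artifacts: dict[str, object] = {}
    stage = "load"
    t0 = time.perf_counter()
    try:
        medium = load_medium_file(base / config["medium"])
        members = []
        validations = {}
        for spec in config["members"]:
            net = read_model(base / spec["model"])
            if spec.get("curation"):
                edits = load_curation_file(base / spec["curation"])
                net, applied = apply_curation(net, edits)
                logger.info("member %s: applied %d curation edits", spec["tag"],
                            len(applied))
            members.append((spec["tag"], net))
        record["stages"][stage] = time.perf_counter() - t0

        stage = "validate"
        t0 = time.perf_counter()
        for spec, (tag, net) in zip(config["members"], members):
            if not spec.get("phenotypes"):
                continue
            table = load_phenotype_table(base / spec["phenotypes"])
            preds = predict_phenotypes(net, table, medium)
            validations[tag] = score_validation(preds, table)
        artifacts["validations"] = validations
        record["stages"][stage] = time.perf_counter() - t0

        stage = "steadycom"
        t0 = time.perf_counter()
        cm = assemble_community(members, medium)
        # pool-level bound overrides, e.g. closing an environment sink so an
        # exchanged metabolite must be absorbed by the partner: {lac_e: [0, 0]}
        for pool, bnds in (config.get("community_exchange_overrides") or {}).items():
            if pool not in cm.community_exchange_bounds and bnds is not None:
                raise KeyError(f"override references unknown pool metabolite {pool!r}")
            if bnds is None:
                del cm.community_exchange_bounds[pool]
            else:
                cm.community_exchange_bounds[pool] = (float(bnds[0]), float(bnds[1]))
        scn = config["scenario"]
        scenario = ScenarioSpec(
            mu_exp=float(scn["mu_exp"]), fiber_id=scn["fiber_id"],
            suboptimality_factor=float(scn.get("suboptimality_factor", 0.05)),
            total_abundance=float(scn.get("total_abundance", 1.0)))
        optimum = min_fiber_uptake(cm, scenario.mu_exp, scenario.fiber_id)
        mu_star = max_community_growth(cm).mu
        artifacts["optimum"] = optimum
        artifacts["mu_star"] = mu_star
        record["stages"][stage] = time.perf_counter() - t0

        stage = "fva"
        t0 = time.perf_counter()
        budget = suboptimal_budget(cm, scenario)
        ranges = community_fva(cm, scenario, fiber_budget=budget)
        artifacts["fiber_budget"] = budget
        artifacts["fva"] = ranges
        record["stages"][stage] = time.perf_counter() - t0

        stage = "sample"
        t0 = time.perf_counter()
        sampler_cfg = config.get("sampler", {})
        cfg = SamplerConfig(
            n_samples=int(sampler_cfg.get("n_samples", 200_000)),
            thinning=int(sampler_cfg.get("thinning", 100)),
            n_warmup=sampler_cfg.get("n_warmup"),
            seed=seed)
        polytope = scenario_polytope(cm, scenario, fiber_budget=budget)
        samples = sample_hit_and_run(polytope, cfg)
        artifacts["samples"] = samples
        record["stages"][stage] = time.perf_counter() - t0

        stage = "classify"
        t0 = time.perf_counter()
        exchange_cols = [f"abundance:{t}" for t in cm.member_tags()]
        exchange_cols += [f"{tag}:{rxn.id}" for tag, net in cm.members
                          for rxn in net.exchanges()]
        report = classify_exchanges(samples, alpha=float(config.get("alpha", 0.01)),
                                    columns=exchange_cols)
        artifacts["report"] = report
        artifacts["densities"] = summarize_densities(samples, columns=exchange_cols)
        record["stages"][stage] = time.perf_counter() - t0
    except Exception as exc:
        record["error"] = {"stage": stage, "message": str(exc)}
        write_outputs(record, artifacts, out)
        (out / "error_manifest.json").write_text(
            json.dumps(record["error"], indent=2) + "\n")
        raise StageError(stage, config_hash, exc) from exc

    return write_outputs(record, artifacts, out)


def write_outputs(record: dict, artifacts: dict, out_dir: str | Path) -> dict:
    """Serialize artifacts to ``out_dir`` and finish the manifest.

    Produces the exchange table in the style of the optimal-plus-FVA figure
    (optimal value and min/max per quantity), the density and correlation
    tables for the sampling figure, validation reports, the raw samples and
    ``manifest.json`` listing every written file with its checksum.
    Idempotent: writing the same record and artifacts twice yields identical
    files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"version": record.get("version", __version__),
                  "seed": record.get("seed"), "config_hash": record.get("config_hash")}

    for tag, result in (artifacts.get("validations") or {}).items():
        _dump_json({"provenance": provenance,
                    "tp": result.tp, "tn": result.tn, "fp": result.fp, "fn": result.fn,
                    "precision": result.precision, "recall": result.recall,
                    "accuracy": result.accuracy, "f_score": result.f_score,
                    "verdicts": list(result.per_row_verdicts)},
                   out / f"validation_{tag}.json")

    optimum = artifacts.get("optimum")
    if optimum is not None:
        _dump_json({"provenance": provenance, "mu": optimum.mu,
                    "mu_star": artifacts.get("mu_star"),
                    "fiber_uptake": optimum.fiber_uptake,
                    "fiber_budget": artifacts.get("fiber_budget"),
                    "abundances": optimum.abundances,
                    "exchange_fluxes": {f"{t}:{m}": v for (t, m), v
                                        in optimum.exchange_fluxes.items()},
                    "community_exchange": optimum.community_exchange},
                   out / "steadycom_solution.json")

    ranges = artifacts.get("fva")
    if ranges is not None:
        rows = []
        opt_values = {}
        if optimum is not None:
            for tag, fluxes in optimum.member_fluxes.items():
                opt_values.update({f"{tag}:{rid}": v for rid, v in fluxes.items()})
            opt_values.update({f"abundance:{t}": v
                               for t, v in optimum.abundances.items()})
        for fr in ranges:
            rows.append({"quantity": fr.quantity_id,
                         "optimal": opt_values.get(fr.quantity_id),
                         "min": fr.min, "max": fr.max})
        pd.DataFrame(rows).to_csv(out / "exchange_table.csv", index=False)

    samples = artifacts.get("samples")
    if samples is not None:
        samples.to_csv(out / "samples.csv")

    report = artifacts.get("report")
    if report is not None:
        report.classification_frame().to_csv(out / "classifications.csv", index=False)
        report.correlations.to_csv(out / "correlations.csv")
        report.to_json(out / "crossfeeding_report.json")

    densities = artifacts.get("densities")
    if densities is not None:
        _dump_json({"provenance": provenance, "densities": densities},
                   out / "densities.json")

    files = {p.name: _sha256(p) for p in sorted(out.iterdir())
             if p.name not in ("manifest.json", "error_manifest.json")}
    record = dict(record)
    record["files"] = files
    _dump_json(record, out / "manifest.json")
    return record
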
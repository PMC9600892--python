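"""Scoring model phenotype predictions against experimental truth tables.

A curated genome-scale model is judged by whether it grows on the substrates
the organism is known to use, and secretes the fermentation products it is
known to form.  Each table row is an independent binary assay; the confusion
counts give precision, recall, accuracy and the F-score (harmonic mean of
precision and recall, 2·TP / (2·TP + FP + FN)).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

from .fba import InfeasibleError, fba
from .model_io import Medium, MetabolicNetwork, ValidationError, apply_medium

__all__ = [
    "PhenotypeRow",
    "PhenotypeTable",
    "ValidationResult",
    "predict_phenotypes",
    "score_validation",
    "load_phenotype_table",
]

GROWTH_EPSILON = 1e-6   # h^-1: growth below this is a negative substrate call
FLUX_EPSILON = 1e-6     # mmol/gDW/h: secretion below this is a negative product call
FRACTION_OF_OPTIMUM = 0.9  # product formation must be possible near optimal growth


@dataclass(frozen=True)
class PhenotypeRow:
    compound_id: str            # exchange reaction id of the assayed compound
    assay_kind: str             # substrate_growth | product_formation
    experimental: bool          # True = positive phenotype observed
    source_note: str = ""

    def __post_init__(self) -> None:
        if self.assay_kind not in ("substrate_growth", "product_formation"):
            raise ValidationError(f"unknown assay kind {self.assay_kind!r}")


@dataclass(frozen=True)
class PhenotypeTable:
    rows: tuple[PhenotypeRow, ...]

    def __post_init__(self) -> None:
        seen = set()
        for r in self.rows:
            key = (r.compound_id, r.assay_kind)
            if key in seen:
                raise ValidationError(f"duplicate phenotype row {key}")
            seen.add(key)


@dataclass(frozen=True)
class Prediction:
    compound_id: str
    assay_kind: str
    predicted: bool
    flagged: bool = False       # compound had no exchange reaction
    value: float = 0.0          # optimal growth or max secretion flux


@dataclass(frozen=True)
class ValidationResult:
    tp: int
    tn: int
    fp: int
    fn: int
    precision: float
    recall: float
    accuracy: float
    f_score: float
    per_row_verdicts: tuple[dict, ...] = field(default_factory=tuple)


def load_phenotype_table(path: str | Path) -> PhenotypeTable:
    """Read a CSV with columns compound_id, assay_kind, experimental, note."""
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            exp = str(rec["experimental"]).strip().lower()
            rows.append(PhenotypeRow(
                compound_id=rec["compound_id"].strip(),
                assay_kind=rec["assay_kind"].strip(),
                experimental=exp in ("1", "true", "positive", "yes"),
                source_note=rec.get("note", ""),
            ))
    return PhenotypeTable(tuple(rows))


def predict_phenotypes(net: MetabolicNetwork, table: PhenotypeTable, medium: Medium,
                       growth_epsilon: float = GROWTH_EPSILON,
                       flux_epsilon: float = FLUX_EPSILON,
                       fraction_of_optimum: float = FRACTION_OF_OPTIMUM
                       ) -> list[Prediction]:
    """Predict each table row's phenotype by FBA.

    substrate_growth rows: the compound replaces the medium's carbon source as
    the sole carbon supply; positive iff optimal growth exceeds
    ``growth_epsilon``.  product_formation rows: on the base medium, positive
    iff the compound's maximal secretion flux exceeds ``flux_epsilon`` while
    growth is held at ≥ ``fraction_of_optimum`` of its optimum.  Compounds
    without an exchange reaction are predicted negative and flagged.
    """
    base = apply_medium(net, medium)
    try:
        mu_star = fba(base).objective_value
    except InfeasibleError as exc:
        raise InfeasibleError(f"base medium infeasible for {net.model_id}: {exc}") from exc

    exchange_ids = {r.id for r in net.exchanges()}
    preds: list[Prediction] = []
    for row in table.rows:
        if row.compound_id not in exchange_ids:
            preds.append(Prediction(row.compound_id, row.assay_kind, False, flagged=True))
            continue
        if row.assay_kind == "substrate_growth":
            medium_row = medium.with_carbon_source(
                row.compound_id, medium.uptake_bounds[medium.carbon_source_id])
            try:
                growth = fba(apply_medium(net, medium_row)).objective_value
            except InfeasibleError:
                growth = 0.0
            preds.append(Prediction(row.compound_id, row.assay_kind,
                                    growth > growth_epsilon, value=growth))
        else:
            pin = {net.biomass_reaction_id: (
                fraction_of_optimum * mu_star,
                net.reaction(net.biomass_reaction_id).upper_bound)}
            try:
                sec = fba(base, objective_id=row.compound_id, maximize=True,
                          extra_bounds=pin).objective_value
            except InfeasibleError:
                sec = 0.0
            preds.append(Prediction(row.compound_id, row.assay_kind,
                                    sec > flux_epsilon, value=sec))
    return preds


def score_validation(predicted: Sequence[Prediction | bool],
                     table: PhenotypeTable) -> ValidationResult:
    """Confusion counts and derived scores, in exact rational arithmetic.

    Conventions: an experimentally positive phenotype predicted positive is a
    true positive.  precision = TP/(TP+FP), recall = TP/(TP+FN),
    accuracy = (TP+TN)/total, F-score = 2·TP/(2·TP+FP+FN); an undefined ratio
    (empty denominator) is reported as 0.
    """
    if len(predicted) != len(table.rows):
        raise ValidationError(
            f"{len(predicted)} predictions for {len(table.rows)} table rows")
    tp = tn = fp = fn = 0
    verdicts = []
    for pred, row in zip(predicted, table.rows):
        p = pred.predicted if isinstance(pred, Prediction) else bool(pred)
        if p and row.experimental:
            tp += 1
            verdict = "TP"
        elif p and not row.experimental:
            fp += 1
            verdict = "FP"
        elif not p and row.experimental:
            fn += 1
            verdict = "FN"
        else:
            tn += 1
            verdict = "TN"
        verdicts.append({"compound_id": row.compound_id, "assay_kind": row.assay_kind,
                         "experimental": row.experimental, "predicted": p,
                         "verdict": verdict})

    def ratio(num: int, den: int) -> float:
        return float(Fraction(num, den)) if den else 0.0

    total = tp + tn + fp + fn
    return ValidationResult(
        tp=tp, tn=tn, fp=fp, fn=fn,
        precision=ratio(tp, tp + fp),
        recall=ratio(tp, tp + fn),
        accuracy=ratio(tp + tn, total),
        f_score=ratio(2 * tp, 2 * tp + fp + fn),
        per_row_verdicts=tuple(verdicts),
    )
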
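"""Phenotype prediction and confusion-table scoring."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linprog

import steadycross as sx
from steadycross.model_io import Medium
from steadycross.validation import (PhenotypeRow, PhenotypeTable, predict_phenotypes,
                                    score_validation)


def _table(*rows):
    return PhenotypeTable(tuple(
        PhenotypeRow(compound_id=f"EX_sub{i}", assay_kind="substrate_growth",
                     experimental=exp) for i, exp in enumerate(rows)))


# -- scoring formulas --------------------------------------------------------

def test_scores_match_hand_arithmetic():
    table = _table(True, True, True, False, False, False)
    predicted = [True, True, False, True, False, False]  # tp=2 fn=1 fp=1 tn=2
    res = score_validation(predicted, table)
    assert (res.tp, res.tn, res.fp, res.fn) == (2, 2, 1, 1)
    assert res.precision == pytest.approx(2 / 3)
    assert res.accuracy == pytest.approx(2 / 3)
    assert res.f_score == pytest.approx(2 / 3)
    assert res.recall == pytest.approx(2 / 3)


def test_all_correct_gives_unit_scores():
    table = _table(True, False, True)
    res = score_validation([True, False, True], table)
    assert (res.precision, res.recall, res.accuracy, res.f_score) == (1.0, 1.0, 1.0, 1.0)


def test_scores_exact_on_enumerated_confusion_tables():
    """Formulas hold exactly for every confusion table with up to 4 of each kind."""
    for tp, tn, fp, fn in itertools.product(range(4), repeat=4):
        if tp + tn + fp + fn == 0:
            continue
        truth = [True] * tp + [False] * tn + [False] * fp + [True] * fn
        pred = [True] * tp + [False] * tn + [True] * fp + [False] * fn
        res = score_validation(pred, _table(*truth))
        assert (res.tp, res.tn, res.fp, res.fn) == (tp, tn, fp, fn)
        total = tp + tn + fp + fn
        assert res.accuracy == pytest.approx((tp + tn) / total, abs=0)
        assert res.f_score == pytest.approx(
            2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0, abs=0)
        assert res.precision == pytest.approx(
            tp / (tp + fp) if (tp + fp) else 0.0, abs=0)


def test_row_permutation_leaves_scores_unchanged():
    rng = np.random.default_rng(0)
    truth = [True, False, True, True, False, False, True]
    pred = [True, True, False, True, False, True, True]
    base = score_validation(pred, _table(*truth))
    order = rng.permutation(len(truth))
    permuted = score_validation([pred[i] for i in order],
                                _table(*[truth[i] for i in order]))
    for attr in ("tp", "tn", "fp", "fn", "precision", "recall", "accuracy", "f_score"):
        assert getattr(base, attr) == getattr(permuted, attr)


def test_flipping_a_correct_row_never_increases_accuracy():
    truth = [True, False, True, False, True]
    pred = [True, False, True, True, False]
    base = score_validation(pred, _table(*truth)).accuracy
    for i in range(len(pred)):
        if pred[i] == truth[i]:
            worse = list(pred)
            worse[i] = not worse[i]
            assert score_validation(worse, _table(*truth)).accuracy < base


def test_length_mismatch_rejected():
    with pytest.raises(Exception, match="predictions"):
        score_validation([True], _table(True, False))


# -- phenotype prediction ----------------------------------------------------

def test_growth_on_own_substrate_and_missing_exchange_flag():
    net, table, medium, _ = sx.make_phenotype_fixture(n_rows=4, error_rate=0.0, seed=0)
    preds = predict_phenotypes(net, table, medium)
    assert preds[0].predicted  # substrate 0 always supports growth
    ghost = PhenotypeTable((PhenotypeRow("EX_ghost", "substrate_growth", True),))
    (pred,) = predict_phenotypes(net, ghost, medium)
    assert not pred.predicted and pred.flagged


def _bruteforce_growth(net, carbon_exchange, cap=10.0):
    """Independent per-substrate LP: bounds assembled by hand, one linprog call."""
    met_index = {m.id: i for i, m in enumerate(net.metabolites)}
    n = len(net.reactions)
    S = np.zeros((len(net.metabolites), n))
    bounds = []
    c = np.zeros(n)
    for j, rxn in enumerate(net.reactions):
        for met, coeff in rxn.stoichiometry.items():
            S[met_index[met], j] = coeff
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if rxn.is_exchange:
            lb = -cap if rxn.id == carbon_exchange else 0.0
        bounds.append((lb, min(ub, 1e6)))
        if rxn.id == net.biomass_reaction_id:
            c[j] = -1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    assert res.status == 0
    return -res.fun


def test_substrate_predictions_match_bruteforce_lp_oracle():
    net, table, medium, _ = sx.make_phenotype_fixture(n_rows=6, error_rate=0.0, seed=3)
    preds = predict_phenotypes(net, table, medium)
    for row, pred in zip(table.rows, preds):
        expected = _bruteforce_growth(net, row.compound_id) > 1e-6
        assert pred.predicted == expected


def test_product_formation_assay():
    """A fermentation product is predicted iff secretable near optimal growth."""
    from steadycross.synthetic import ToyCommunityParams, _degrader_network
    net = _degrader_network(ToyCommunityParams())
    medium = Medium(uptake_bounds={"EX_fiber": 1.0}, carbon_source_id="EX_fiber")
    table = PhenotypeTable((
        PhenotypeRow("EX_lac", "product_formation", True),
        PhenotypeRow("EX_but", "product_formation", False),  # degrader makes no butyrate
    ))
    preds = predict_phenotypes(net, table, medium)
    assert preds[0].predicted
    assert not preds[1].predicted and preds[1].flagged  # no butyrate exchange at all
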
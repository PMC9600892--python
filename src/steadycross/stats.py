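"""Statistical classification of exchanged metabolites from flux samples.

Each sampled exchange flux column is tested against zero with the one-sample
Wilcoxon signed-rank test: a metabolite is *produced* by a member when the
median exchange flux is significantly greater than zero, *consumed* when
significantly less, and *indeterminate* otherwise.  Pairwise Pearson
correlations between exchange columns quantify the coupling of the members'
exchanges; a secreted metabolite whose only fate is uptake by the partner is
perfectly anticorrelated (coefficient −1) by mass balance.

The samples come from a thinned Markov chain and are autocorrelated, which
inflates nominal significance; reports carry an effective-sample-size caveat
but apply the test to the retained samples directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sampling import FluxSampleMatrix

__all__ = [
    "ExchangeClassification",
    "ExchangeReport",
    "classify_exchanges",
    "correlation_matrix",
    "summarize_densities",
]

DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class ExchangeClassification:
    quantity_id: str
    median: float
    p_value: float
    classification: str     # produced | consumed | indeterminate
    flagged: bool = False   # constant-zero column


@dataclass
class ExchangeReport:
    classifications: list[ExchangeClassification]
    correlations: pd.DataFrame
    alpha: float
    caveat: str = ("retained Markov-chain samples are autocorrelated; nominal "
                   "p-values understate uncertainty")

    def classification_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"quantity_id": c.quantity_id, "median": c.median, "p_value": c.p_value,
              "classification": c.classification, "flagged": c.flagged}
             for c in self.classifications]
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "alpha": self.alpha,
            "caveat": self.caveat,
            "classifications": self.classification_frame().to_dict(orient="records"),
            "correlations": json.loads(self.correlations.to_json()),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _classify_column(values: np.ndarray, alpha: float) -> tuple[float, float, str, bool]:
    med = float(np.median(values))
    nonzero = values[values != 0.0]
    if nonzero.size == 0:
        return med, 1.0, "indeterminate", True
    # signed-rank test against zero; zeros dropped per the classical procedure
    try:
        p = float(sps.wilcoxon(nonzero, alternative="two-sided").pvalue)
    except ValueError:
        return med, 1.0, "indeterminate", True
    if p < alpha and med > 0:
        return med, p, "produced", False
    if p < alpha and med < 0:
        return med, p, "consumed", False
    return med, p, "indeterminate", False


def classify_exchanges(samples: FluxSampleMatrix, alpha: float = DEFAULT_ALPHA,
                       columns: list[str] | None = None) -> ExchangeReport:
    """Classify each sampled quantity as produced / consumed / indeterminate.

    Uses the one-sample Wilcoxon signed-rank test of the column against zero
    at significance ``alpha`` (default 0.01).  Constant-zero columns are
    indeterminate with p-value 1 and flagged.
    """
    if samples.samples.shape[0] < 2:
        raise ValueError("need at least 2 samples per column")
    columns = columns if columns is not None else list(samples.names)
    classifications = []
    for name in columns:
        med, p, cls, flagged = _classify_column(samples.column(name), alpha)
        classifications.append(ExchangeClassification(
            quantity_id=name, median=med, p_value=p, classification=cls,
            flagged=flagged))
    corr = correlation_matrix(samples, columns=columns)
    return ExchangeReport(classifications=classifications, correlations=corr,
                          alpha=alpha)


def correlation_matrix(samples: FluxSampleMatrix,
                       columns: list[str] | None = None,
                       method: str = "pearson") -> pd.DataFrame:
    """Pairwise correlation of sampled quantities (constant columns excluded).

    ``method`` is ``pearson`` (default) or ``spearman``.  The matrix is
    symmetric with unit diagonal; entries lie in [−1, 1].
    """
    if samples.samples.shape[0] < 3:
        raise ValueError("need at least 3 samples for correlations")
    columns = columns if columns is not None else list(samples.names)
    frame = pd.DataFrame({c: samples.column(c) for c in columns})
    stds = frame.std(ddof=0)
    keep = [c for c in columns if stds[c] > 0]
    corr = frame[keep].corr(method=method)
    return corr.clip(-1.0, 1.0)


def summarize_densities(samples: FluxSampleMatrix, n_bins: int = 50,
                        columns: list[str] | None = None) -> dict[str, dict]:
    """Per-column density summaries for plotting: fixed-width histogram over the
    observed range (``n_bins`` bins), median and central 95% interval.

    Medians are computed from the same columns as :func:`classify_exchanges`,
    so the two reports agree exactly.
    """
    columns = columns if columns is not None else list(samples.names)
    out: dict[str, dict] = {}
    for name in columns:
        col = samples.column(name)
        lo, hi = float(col.min()), float(col.max())
        if hi == lo:
            edges = np.array([lo - 0.5, lo + 0.5])
            counts = np.array([col.size])
        else:
            counts, edges = np.histogram(col, bins=n_bins, range=(lo, hi))
        q_lo, med, q_hi = np.percentile(col, [2.5, 50.0, 97.5])
        out[name] = {
            "median": float(np.median(col)),
            "p2.5": float(q_lo),
            "p97.5": float(q_hi),
            "bin_edges": edges.tolist(),
            "counts": counts.tolist(),
        }
    return out
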
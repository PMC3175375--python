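"""Classic two-rater agreement statistics: percent agreement and kappa.

These are the comparator summaries the log-linear ladder is meant to
improve on: a single kappa collapses agreement across categories, whereas
category-specific log-linear strengths localize it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import ContingencyTable

__all__ = ["PercentAgreement", "KappaResult", "percent_agreement", "kappa"]

WEIGHTINGS = ("none", "linear", "quadratic")


@dataclass(frozen=True)
class PercentAgreement:
    """Per-category agreement with the reference (second) rater.

    ``proportion = numerator / denominator`` where the numerator is the
    diagonal cell for the category and the denominator is the reference
    rater's margin.  ``defined`` is False when the margin is empty.
    """

    category: str
    numerator: int
    denominator: int
    proportion: float
    defined: bool


@dataclass(frozen=True)
class KappaResult:
    """(Weighted) kappa: beyond-chance agreement of two raters.

    estimate = (observed - expected) / (1 - expected), with agreement
    weights w_ij = 1 for unweighted, 1 - |i-j|/(C-1) for linear, and
    1 - (|i-j|/(C-1))^2 for quadratic, over the declared category order.
    """

    estimate: float
    weighting: str
    observed_agreement: float
    expected_agreement: float
    defined: bool


def _require_two_raters(table: ContingencyTable) -> None:
    if table.n_raters != 2:
        raise ValueError("this statistic requires a 2-rater table")


def percent_agreement(table: ContingencyTable, category: str) -> PercentAgreement:
    """Diagonal agreement proportion for one category.

    The SECOND rater of the table is the reference reader (e.g. the expert
    consensus): its margin for the category is the denominator.
    """
    _require_two_raters(table)
    if category not in table.categories:
        raise ValueError(f"unknown category {category!r}")
    c = table.categories.index(category)
    numerator = int(table.counts[c, c])
    denominator = int(table.counts[:, c].sum())
    if denominator == 0:
        return PercentAgreement(category, numerator, 0, float("nan"), False)
    return PercentAgreement(category, numerator, denominator, numerator / denominator, True)


def _weights(C: int, weighting: str) -> np.ndarray:
    if weighting not in WEIGHTINGS:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}")
    i, j = np.indices((C, C))
    if weighting == "none":
        return (i == j).astype(float)
    d = np.abs(i - j) / (C - 1)
    return 1.0 - (d if weighting == "linear" else d**2)


def kappa(table: ContingencyTable, weighting: str = "none") -> KappaResult:
    """Cohen's kappa, optionally weighted over the declared category order."""
    _require_two_raters(table)
    n = table.n
    if n < 1:
        raise ValueError("table must contain at least one subject")
    w = _weights(table.n_categories, weighting)
    p = table.counts / n
    po = float((w * p).sum())
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    pe = float((w * np.outer(row, col)).sum())
    if pe >= 1.0 - 1e-12:
        return KappaResult(float("nan"), weighting, po, pe, False)
    return KappaResult((po - pe) / (1.0 - pe), weighting, po, pe, True)
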
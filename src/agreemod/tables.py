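"""Contingency tables of multi-rater categorical readings.

A reader study records, for each subject (e.g. a kidney in a diuresis
renography study), the category assigned by each of K raters (human experts,
a consensus reading, or a computer-aided diagnosis system).  The complete
cross-classification is a dense K-way table with C^K cells, one per
combination of category assignments.  Zero cells are stored explicitly
because the log-linear fitter needs them.

Canonical cell order
--------------------
Cells are enumerated in odometer order over category indices with the LAST
rater varying fastest, i.e. ``itertools.product(range(C), repeat=K)``.  All
flattened vectors (observed counts, fitted counts, design-matrix rows) use
this order.
"""

from __future__ import annotations

import csv
import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RatingRecord",
    "ContingencyTable",
    "build_table",
    "marginalize",
    "read_ratings",
    "write_ratings",
    "read_counts",
    "write_counts",
]


@dataclass(frozen=True)
class RatingRecord:
    """One rater's categorical reading of one subject."""

    subject_id: str
    rater_id: str
    category: str


class ContingencyTable:
    """Dense K-way cross-classification of subjects by rater assignments.

    Parameters
    ----------
    raters
        Ordered rater identifiers (length K).
    categories
        Ordered category labels shared by all raters (length C >= 2).  The
        order is user-declared and fixed; it determines the canonical cell
        order and the meaning of weighted kappa.
    counts
        Integer array of shape ``(C,) * K``; ``counts[c1, ..., cK]`` is the
        number of subjects assigned category ``c1`` by the first rater,
        ``c2`` by the second, and so on.
    """

    def __init__(
        self,
        raters: Sequence[str],
        categories: Sequence[str],
        counts: np.ndarray,
    ) -> None:
        self.raters = tuple(str(r) for r in raters)
        self.categories = tuple(str(c) for c in categories)
        if len(self.raters) < 1:
            raise ValueError("at least one rater is required")
        if len(set(self.raters)) != len(self.raters):
            raise ValueError("rater identifiers must be unique")
        if len(self.categories) < 2:
            raise ValueError("at least two categories are required")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError("category labels must be unique")
        arr = np.asarray(counts)
        expected = (len(self.categories),) * len(self.raters)
        if arr.shape != expected:
            raise ValueError(f"counts shape {arr.shape} does not match {expected}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            arr = np.round(arr).astype(np.int64)
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = arr.astype(np.int64)

    # -- basic geometry -------------------------------------------------

    @property
    def n_raters(self) -> int:
        return len(self.raters)

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    @property
    def n(self) -> int:
        """Total number of subjects."""
        return int(self.counts.sum())

    def flat(self) -> np.ndarray:
        """Counts as a 1-D vector in canonical cell order."""
        return self.counts.reshape(-1)

    def cells(self) -> list[tuple[int, ...]]:
        """Category-index tuples in canonical cell order."""
        return list(
            itertools.product(range(self.n_categories), repeat=self.n_raters)
        )

    def margin(self, rater: str) -> np.ndarray:
        """Marginal counts of one rater over the category order."""
        axis = self.raters.index(rater)
        other = tuple(i for i in range(self.n_raters) if i != axis)
        return self.counts.sum(axis=other)

    # -- transformations ------------------------------------------------

    def marginalize(self, keep: Sequence[str]) -> "ContingencyTable":
        """Collapse the table onto a subset of raters.

        Each output cell sums the input cells that agree on the kept
        raters' categories; the total n is preserved.
        """
        keep = tuple(keep)
        if not keep:
            raise ValueError("keep must name at least one rater")
        unknown = [r for r in keep if r not in self.raters]
        if unknown:
            raise ValueError(f"raters not in table: {unknown}")
        if len(set(keep)) != len(keep):
            raise ValueError("keep contains duplicate raters")
        axes = [self.raters.index(r) for r in keep]
        dropped = [i for i in range(self.n_raters) if i not in axes]
        arr = self.counts.transpose(axes + dropped)
        if dropped:
            arr = arr.sum(axis=tuple(range(len(axes), self.n_raters)))
        return ContingencyTable(keep, self.categories, arr)

    def to_records(self) -> list[RatingRecord]:
        """Expand the table back into per-subject rating records.

        Subjects receive sequential synthetic identifiers in canonical
        cell order; re-tabulating the records reproduces the counts.
        """
        records: list[RatingRecord] = []
        sid = 0
        for cell, count in zip(self.cells(), self.flat()):
            for _ in range(int(count)):
                sid += 1
                for rater, ci in zip(self.raters, cell):
                    records.append(
                        RatingRecord(f"s{sid:06d}", rater, self.categories[ci])
                    )
        return records

    def to_dataframe(self) -> pd.DataFrame:
        """Two-rater table as a rows-by-columns DataFrame (K = 2 only)."""
        if self.n_raters != 2:
            raise ValueError("to_dataframe requires a 2-rater table")
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.categories, name=self.raters[0]),
            columns=pd.Index(self.categories, name=self.raters[1]),
        )

    # -- dunder ----------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContingencyTable):
            return NotImplemented
        return (
            self.raters == other.raters
            and self.categories == other.categories
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return (
            f"ContingencyTable(raters={self.raters}, "
            f"categories={self.categories}, n={self.n})"
        )


def build_table(
    records: Iterable[RatingRecord],
    raters: Sequence[str],
    categories: Sequence[str],
) -> ContingencyTable:
    """Tabulate per-subject ratings into a dense K-way table.

    Only subjects rated by ALL listed raters contribute (complete-case);
    incomplete subjects are dropped with a logged count.  A subject with two
    different readings from the same rater is rejected.
    """
    raters = tuple(raters)
    categories = tuple(categories)
    cat_index = {c: i for i, c in enumerate(categories)}
    readings: dict[str, dict[str, int]] = {}
    for rec in records:
        if rec.rater_id not in raters:
            raise ValueError(f"unknown rater {rec.rater_id!r}")
        if rec.category not in cat_index:
            raise ValueError(f"unknown category label {rec.category!r}")
        by_rater = readings.setdefault(rec.subject_id, {})
        ci = cat_index[rec.category]
        if rec.rater_id in by_rater and by_rater[rec.rater_id] != ci:
            raise ValueError(
                f"conflicting duplicate reading for subject {rec.subject_id!r}"
                f" by rater {rec.rater_id!r}"
            )
        by_rater[rec.rater_id] = ci
    counts = np.zeros((len(categories),) * len(raters), dtype=np.int64)
    dropped = 0
    for by_rater in readings.values():
        if len(by_rater) < len(raters):
            dropped += 1
            continue
        counts[tuple(by_rater[r] for r in raters)] += 1
    if dropped:
        logger.info("dropped %d subjects missing at least one rater", dropped)
    return ContingencyTable(raters, categories, counts)


def marginalize(table: ContingencyTable, keep: Sequence[str]) -> ContingencyTable:
    """Functional alias for :meth:`ContingencyTable.marginalize`."""
    return table.marginalize(keep)


# -- plain-text I/O ------------------------------------------------------


def read_ratings(path) -> list[RatingRecord]:
    """Read a long-format ratings CSV with header ``subject,rater,category``."""
    df = pd.read_csv(path, dtype=str)
    required = ["subject", "rater", "category"]
    if list(df.columns) != required:
        raise ValueError(
            f"ratings CSV must have header {','.join(required)}; got {list(df.columns)}"
        )
    return [
        RatingRecord(row.subject, row.rater, row.category)
        for row in df.itertuples(index=False)
    ]


def write_ratings(table_or_records, path) -> None:
    """Write rating records (or an expanded table) as a long-format CSV."""
    if isinstance(table_or_records, ContingencyTable):
        records = table_or_records.to_records()
    else:
        records = list(table_or_records)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject", "rater", "category"])
        for rec in records:
            writer.writerow([rec.subject_id, rec.rater_id, rec.category])


def read_counts(path, categories: Sequence[str] | None = None) -> ContingencyTable:
    """Read a cell-count CSV: one row per cell, header ``r1,...,rK,count``.

    Rater names come from the header; the category order is taken from
    ``categories`` if given, otherwise from first appearance scanning rows
    left-to-right (which reproduces the order used by :func:`write_counts`).
    """
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 3 or df.columns[-1] != "count":
        raise ValueError("counts CSV must end with a 'count' column")
    raters = tuple(df.columns[:-1])
    cat_cols = df.iloc[:, :-1]
    if categories is None:
        seen: dict[str, None] = {}
        for row in cat_cols.itertuples(index=False):
            for label in row:
                seen.setdefault(label, None)
        categories = tuple(seen)
    categories = tuple(categories)
    cat_index = {c: i for i, c in enumerate(categories)}
    counts = np.zeros((len(categories),) * len(raters), dtype=np.int64)
    filled = np.zeros_like(counts, dtype=bool)
    for irow, row in enumerate(df.itertuples(index=False), start=2):
        *labels, raw = row
        try:
            value = int(raw)
        except (TypeError, ValueError):
            raise ValueError(f"row {irow}: count {raw!r} is not an integer")
        if value < 0:
            raise ValueError(f"row {irow}: negative count {value}")
        try:
            cell = tuple(cat_index[label] for label in labels)
        except KeyError as exc:
            raise ValueError(f"row {irow}: unknown category label {exc.args[0]!r}")
        if filled[cell]:
            raise ValueError(f"row {irow}: duplicate cell {tuple(labels)}")
        filled[cell] = True
        counts[cell] = value
    return ContingencyTable(raters, categories, counts)


def write_counts(table: ContingencyTable, path) -> None:
    """Write the dense cell-count CSV (all C^K cells, canonical order)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(table.raters) + ["count"])
        for cell, count in zip(table.cells(), table.flat()):
            writer.writerow(
                [table.categories[ci] for ci in cell] + [int(count)]
            )
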
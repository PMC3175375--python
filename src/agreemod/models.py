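"""Agreement-model specifications and their design matrices.

The models form a nested ladder over the cells of a K-way rater table.  The
log expected count of every cell is a linear combination of

* an intercept (overall effect),
* per-rater main effects (C - 1 free levels each, the "chance" component),
* beyond-chance agreement terms: an indicator is switched on in cells where
  every rater in a given subset assigned the same category, either with one
  shared strength (homogeneous) or one strength per category
  (non-homogeneous).

Ladder names:

========================  =========================================================
independence              main effects only (agreement due to chance alone)
homogeneous               one shared strength for all-raters agreement
nonhomogeneous            one all-raters strength per category
pairwise_homogeneous      one shared strength per unordered rater pair
pairwise_nonhomogeneous   one strength per (pair, category)
threeway_homogeneous      one shared strength per unordered rater triple
threeway_nonhomogeneous   one strength per (triple, category)
========================  =========================================================

Three-way specs carry triple terms ONLY (no pairwise terms): on a 3^4 table
that yields residual dfs 68 (homogeneous) and 60 (non-homogeneous),
consistent with the degrees of freedom such panels report.

Codings
-------
Main effects use reference-category dummy coding by default (last declared
category is the baseline) or sum-to-zero coding; agreement-parameter
estimates, fitted counts and all deviances are invariant to this choice.
Agreement indicators are coded either ``"effects"`` (+1 if the subset
agrees, -1 otherwise — the SAS CATMOD convention, and the scale on which
published agreement coefficients in this literature are reported) or
``"indicator"`` (1/0).  An effects-coded estimate is exactly half the
indicator-coded one; model fit is identical.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AgreementTerm",
    "AgreementModelSpec",
    "ColumnLabel",
    "DesignMatrix",
    "LADDER_NAMES",
    "make_spec",
    "build_design",
    "nested",
]

LADDER_NAMES = (
    "independence",
    "homogeneous",
    "nonhomogeneous",
    "pairwise_homogeneous",
    "pairwise_nonhomogeneous",
    "threeway_homogeneous",
    "threeway_nonhomogeneous",
    "custom",
)


@dataclass(frozen=True)
class AgreementTerm:
    """One beyond-chance agreement component.

    ``raters`` is the subset of raters whose joint agreement activates the
    term (size >= 2); ``category_specific`` selects one strength per
    category instead of a single shared strength.
    """

    raters: tuple[str, ...]
    category_specific: bool = False

    def __post_init__(self):
        object.__setattr__(self, "raters", tuple(self.raters))
        if len(self.raters) < 2:
            raise ValueError("an agreement term needs at least two raters")
        if len(set(self.raters)) != len(self.raters):
            raise ValueError("agreement term raters must be distinct")


@dataclass(frozen=True)
class AgreementModelSpec:
    """Declarative description of one model in the agreement ladder."""

    raters: tuple[str, ...]
    categories: tuple[str, ...]
    terms: tuple[AgreementTerm, ...] = ()
    name: str = "custom"

    def __post_init__(self):
        object.__setattr__(self, "raters", tuple(self.raters))
        object.__setattr__(self, "categories", tuple(self.categories))
        object.__setattr__(self, "terms", tuple(self.terms))
        if len(self.raters) < 2:
            raise ValueError("a model needs at least two raters")
        if len(self.categories) < 2:
            raise ValueError("a model needs at least two categories")
        if self.name not in LADDER_NAMES:
            raise ValueError(f"unknown model name {self.name!r}")
        seen: set[tuple[frozenset[str], bool]] = set()
        for term in self.terms:
            unknown = [r for r in term.raters if r not in self.raters]
            if unknown:
                raise ValueError(f"term raters not in model: {unknown}")
            key = (frozenset(term.raters), term.category_specific)
            if key in seen:
                raise ValueError(f"duplicate agreement term {sorted(key[0])}")
            seen.add(key)

    @property
    def n_raters(self) -> int:
        return len(self.raters)

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    @property
    def n_parameters(self) -> int:
        K, C = self.n_raters, self.n_categories
        extra = sum(C if t.category_specific else 1 for t in self.terms)
        return 1 + K * (C - 1) + extra

    @property
    def residual_df(self) -> int:
        """C^K cells minus free parameters."""
        return self.n_categories**self.n_raters - self.n_parameters

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "raters": list(self.raters),
                "categories": list(self.categories),
                "terms": [
                    {
                        "subset": list(t.raters),
                        "category_specific": t.category_specific,
                    }
                    for t in self.terms
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "AgreementModelSpec":
        doc = json.loads(text)
        return cls(
            raters=tuple(doc["raters"]),
            categories=tuple(doc["categories"]),
            terms=tuple(
                AgreementTerm(tuple(t["subset"]), bool(t["category_specific"]))
                for t in doc.get("terms", ())
            ),
            name=doc.get("name", "custom"),
        )


def _as_labels(items: int | Sequence[str], prefix: str) -> tuple[str, ...]:
    if isinstance(items, int):
        return tuple(f"{prefix}{i + 1}" for i in range(items))
    return tuple(items)


def make_spec(
    name: str,
    raters: int | Sequence[str],
    categories: int | Sequence[str],
) -> AgreementModelSpec:
    """Build one of the named ladder models.

    ``raters`` / ``categories`` may be explicit label sequences or bare
    counts (labels ``rater1..K`` / ``cat1..C`` are then generated).
    Pairwise and three-way models require K >= 3.
    """
    rater_labels = _as_labels(raters, "rater")
    cat_labels = _as_labels(categories, "cat")
    K = len(rater_labels)
    if name not in LADDER_NAMES or name == "custom":
        raise ValueError(f"unknown ladder model {name!r}")
    if name.startswith(("pairwise", "threeway")) and K < 3:
        raise ValueError(f"{name} requires at least 3 raters; got K={K}")
    specific = name.endswith("nonhomogeneous")
    if name == "independence":
        terms: tuple[AgreementTerm, ...] = ()
    elif name in ("homogeneous", "nonhomogeneous"):
        terms = (AgreementTerm(rater_labels, specific),)
    elif name.startswith("pairwise"):
        terms = tuple(
            AgreementTerm(pair, specific)
            for pair in itertools.combinations(rater_labels, 2)
        )
    else:  # threeway_*: triples replace pairs
        terms = tuple(
            AgreementTerm(triple, specific)
            for triple in itertools.combinations(rater_labels, 3)
        )
    return AgreementModelSpec(rater_labels, cat_labels, terms, name)


@dataclass(frozen=True)
class ColumnLabel:
    """Descriptor of one design column."""

    kind: str  # "intercept" | "main" | "agreement"
    rater: str | None = None  # main effects
    raters: tuple[str, ...] | None = None  # agreement subsets
    category: str | None = None

    def __str__(self) -> str:
        if self.kind == "intercept":
            return "intercept"
        if self.kind == "main":
            return f"{self.rater}[{self.category}]"
        body = "agree(" + "*".join(self.raters) + ")"
        return body + (f"[{self.category}]" if self.category is not None else "")


@dataclass
class DesignMatrix:
    """Cell-by-parameter encoding of an :class:`AgreementModelSpec`.

    Rows follow the canonical odometer cell order (last rater fastest);
    columns are intercept, main effects, then agreement terms in spec
    order.  Construction guarantees full column rank.
    """

    spec: AgreementModelSpec
    X: np.ndarray
    labels: tuple[ColumnLabel, ...]
    cells: tuple[tuple[int, ...], ...]
    main_coding: str = "reference"
    agreement_coding: str = "effects"

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_parameters(self) -> int:
        return self.X.shape[1]

    @property
    def residual_df(self) -> int:
        return self.n_cells - self.n_parameters

    def label_strings(self) -> tuple[str, ...]:
        return tuple(str(lab) for lab in self.labels)

    def column(self, label: str) -> int:
        """Index of the column whose label renders as ``label``."""
        for i, lab in enumerate(self.labels):
            if str(lab) == label:
                return i
        raise KeyError(f"no design column labelled {label!r}")

    def agreement_indicator(self, j: int) -> np.ndarray:
        """The 0/1 version of agreement column ``j`` regardless of coding."""
        if self.labels[j].kind != "agreement":
            raise ValueError(f"column {j} is not an agreement column")
        col = self.X[:, j]
        return (col + 1.0) / 2.0 if self.agreement_coding == "effects" else col

    def to_tsv(self, path) -> None:
        """Audit export: one row per cell with rater categories + values."""
        spec = self.spec
        with open(path, "w") as fh:
            header = list(spec.raters) + [str(lab) for lab in self.labels]
            fh.write("\t".join(header) + "\n")
            for cell, row in zip(self.cells, self.X):
                cats = [spec.categories[ci] for ci in cell]
                fh.write("\t".join(cats + [f"{v:g}" for v in row]) + "\n")


def build_design(
    spec: AgreementModelSpec,
    main_coding: str = "reference",
    agreement_coding: str = "effects",
) -> DesignMatrix:
    """Materialize the full-rank design matrix of a model spec.

    Raises ``ValueError`` if the requested columns are linearly dependent
    (possible for pathological custom specs), naming the offending columns.
    """
    if main_coding not in ("reference", "sum_to_zero"):
        raise ValueError(f"unknown main-effect coding {main_coding!r}")
    if agreement_coding not in ("effects", "indicator"):
        raise ValueError(f"unknown agreement coding {agreement_coding!r}")
    K, C = spec.n_raters, spec.n_categories
    cells = tuple(itertools.product(range(C), repeat=K))
    idx = np.array(cells)  # (C^K, K)
    ncell = len(cells)

    cols: list[np.ndarray] = [np.ones(ncell)]
    labels: list[ColumnLabel] = [ColumnLabel("intercept")]
    for k, rater in enumerate(spec.raters):
        for c in range(C - 1):
            col = (idx[:, k] == c).astype(float)
            if main_coding == "sum_to_zero":
                col = col - (idx[:, k] == C - 1).astype(float)
            cols.append(col)
            labels.append(ColumnLabel("main", rater=rater, category=spec.categories[c]))
    for term in spec.terms:
        axes = [spec.raters.index(r) for r in term.raters]
        sub = idx[:, axes]
        cats = range(C) if term.category_specific else (None,)
        for c in cats:
            if c is None:
                ind = (sub == sub[:, [0]]).all(axis=1).astype(float)
                lab = ColumnLabel("agreement", raters=term.raters)
            else:
                ind = (sub == c).all(axis=1).astype(float)
                lab = ColumnLabel(
                    "agreement", raters=term.raters, category=spec.categories[c]
                )
            if agreement_coding == "effects":
                ind = 2.0 * ind - 1.0
            cols.append(ind)
            labels.append(lab)

    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        dependent = _dependent_columns(X, labels)
        raise ValueError(
            "design matrix is rank deficient; dependent columns: "
            + ", ".join(dependent)
        )
    return DesignMatrix(
        spec=spec,
        X=X,
        labels=tuple(labels),
        cells=cells,
        main_coding=main_coding,
        agreement_coding=agreement_coding,
    )


def _dependent_columns(X: np.ndarray, labels: Sequence[ColumnLabel]) -> list[str]:
    """Greedy scan for columns in the span of their predecessors."""
    out: list[str] = []
    for j in range(1, X.shape[1]):
        prev = X[:, :j]
        coef, *_ = np.linalg.lstsq(prev, X[:, j], rcond=None)
        if np.linalg.norm(X[:, j] - prev @ coef) < 1e-8 * max(
            1.0, np.linalg.norm(X[:, j])
        ):
            out.append(str(labels[j]))
    return out


def nested(spec_a: AgreementModelSpec, spec_b: AgreementModelSpec) -> bool:
    """True iff spec_a's design column space is contained in spec_b's.

    Containment is decided by projecting each column of A's design onto
    B's column space and checking the residual; the answer is coding-
    independent because both codings span the same space.
    """
    if spec_a.raters != spec_b.raters or spec_a.categories != spec_b.categories:
        raise ValueError("nested() requires specs over the same raters and categories")
    A = build_design(spec_a).X
    B = build_design(spec_b).X
    coef, *_ = np.linalg.lstsq(B, A, rcond=None)
    resid = A - B @ coef
    scale = np.maximum(1.0, np.linalg.norm(A, axis=0))
    return bool((np.linalg.norm(resid, axis=0) < 1e-8 * scale).all())
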
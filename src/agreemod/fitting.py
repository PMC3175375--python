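"""Poisson maximum-likelihood fitting of log-linear agreement models.

Cell counts ``y`` over the C^K cells of a rater table are modeled as
independent Poisson with ``log mu = X beta``, where ``X`` is the design of
an :class:`~agreemod.models.AgreementModelSpec`.  Because every design
contains an intercept, the Poisson likelihood is proportional to the
multinomial likelihood with fixed total n, so the same fit is valid for
reader studies with a fixed number of subjects.

Estimation is Newton iteration on the log-likelihood
``l(beta) = sum(y * log mu - mu)`` (iteratively reweighted least squares)
with step-halving, started from the closed-form independence fit.  The
parameter covariance is the inverse observed Fisher information
``(X' diag(mu) X)^{-1}``; goodness of fit is the deviance
``G2 = 2 * sum_{y>0} y * log(y / mu_hat)`` referred to a chi-square on the
residual degrees of freedom.

Model-vs-model comparison uses likelihood-ratio tests on nested specs;
linear hypotheses among coefficients (e.g. equality of agreement strengths,
or expert-pair strengths versus CAD-pair strengths) use Wald chi-square
tests.  :func:`run_model_ladder` automates the select-then-test procedure:
climb the nested ladder until the first model whose goodness-of-fit p-value
clears ``selection_alpha``, then read coefficient and equivalence tests at
the more conservative ``test_alpha``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    AgreementModelSpec,
    ColumnLabel,
    DesignMatrix,
    build_design,
    make_spec,
    nested,
)
from .tables import ContingencyTable

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "HypothesisResult",
    "LadderRung",
    "LadderResult",
    "FitError",
    "NonConvergenceError",
    "DivergentParameterError",
    "fit",
    "likelihood_ratio_test",
    "wald_linear_test",
    "named_equivalence_tests",
    "run_model_ladder",
]


class FitError(RuntimeError):
    """Base class for fitting failures."""


class NonConvergenceError(FitError):
    """Newton iteration did not converge within the iteration budget."""

    def __init__(self, message: str, beta: np.ndarray, score_norm: float):
        super().__init__(message)
        self.beta = beta
        self.score_norm = score_norm


class DivergentParameterError(FitError):
    """A parameter's MLE is infinite (e.g. an agreement pattern with zero
    observed count), named in the message."""


@dataclass
class FitResult:
    """Maximum-likelihood fit of one agreement model on one table."""

    spec: AgreementModelSpec
    design: DesignMatrix
    table: ContingencyTable
    coefficients: np.ndarray
    covariance: np.ndarray
    fitted_counts: np.ndarray
    deviance: float
    residual_df: int
    converged: bool
    n_iter: int

    @property
    def se(self) -> np.ndarray:
        """Standard errors: square roots of the covariance diagonal."""
        return np.sqrt(np.diag(self.covariance))

    @property
    def z_values(self) -> np.ndarray:
        return self.coefficients / self.se

    @property
    def p_values(self) -> np.ndarray:
        """Two-sided Wald z-test p-value per coefficient."""
        return 2.0 * stats.norm.sf(np.abs(self.z_values))

    @property
    def gof_p_value(self) -> float:
        """Chi-square upper-tail probability of the deviance."""
        if self.residual_df == 0:
            return 1.0
        return float(stats.chi2.sf(self.deviance, self.residual_df))

    @property
    def labels(self) -> tuple[ColumnLabel, ...]:
        return self.design.labels

    def coef(self, label: str) -> float:
        return float(self.coefficients[self.design.column(label)])

    def coef_se(self, label: str) -> float:
        return float(self.se[self.design.column(label)])

    def coef_p(self, label: str) -> float:
        return float(self.p_values[self.design.column(label)])

    def coefficient_table(self, kind: str | None = None) -> pd.DataFrame:
        """Per-parameter estimates/SEs/z/p, optionally filtered by kind."""
        rows = []
        for j, lab in enumerate(self.labels):
            if kind is not None and lab.kind != kind:
                continue
            rows.append(
                {
                    "parameter": str(lab),
                    "kind": lab.kind,
                    "category": lab.category,
                    "estimate": float(self.coefficients[j]),
                    "se": float(self.se[j]),
                    "z": float(self.z_values[j]),
                    "p_value": float(self.p_values[j]),
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.spec.name,
                "raters": list(self.spec.raters),
                "categories": list(self.spec.categories),
                "main_coding": self.design.main_coding,
                "agreement_coding": self.design.agreement_coding,
                "parameters": self.design.label_strings(),
                "coefficients": self.coefficients.tolist(),
                "se": self.se.tolist(),
                "covariance": self.covariance.tolist(),
                "fitted_counts": self.fitted_counts.tolist(),
                "deviance_G2": self.deviance,
                "residual_df": self.residual_df,
                "gof_p_value": self.gof_p_value,
                "converged": self.converged,
                "iterations": self.n_iter,
                "n": self.table.n,
            },
            indent=2,
        )

    def summary(self) -> str:
        """Text report shaped like the agreement-coefficient tables of
        reader-study publications (parameter, estimate, SE, p)."""
        lines = [
            f"model: {self.spec.name}   "
            f"G2 = {self.deviance:.2f}  df = {self.residual_df}  "
            f"p = {self.gof_p_value:.2g}",
            f"{'parameter':<42}{'estimate':>10}{'SE':>8}{'p':>10}",
        ]
        for _, row in self.coefficient_table().iterrows():
            lines.append(
                f"{row.parameter:<42}{row.estimate:>10.2f}"
                f"{row.se:>8.2f}{row.p_value:>10.2g}"
            )
        return "\n".join(lines)


@dataclass
class HypothesisResult:
    """One chi-square test of a linear hypothesis or model comparison."""

    kind: str  # "likelihood_ratio" | "wald"
    statistic: float
    df: int
    p_value: float
    constraint: str
    name: str | None = None
    category: str | None = None

    def as_dict(self) -> dict:
        return {
            "kind": self.kind,
            "name": self.name,
            "category": self.category,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "constraint": self.constraint,
        }


def _independence_start(table: ContingencyTable) -> np.ndarray:
    """Closed-form independence fitted counts n * prod margins, floored."""
    n = table.n
    mu = np.full((table.n_categories,) * table.n_raters, float(n))
    for k, rater in enumerate(table.raters):
        p = table.margin(rater) / n
        shape = [1] * table.n_raters
        shape[k] = table.n_categories
        mu = mu * p.reshape(shape)
    return np.maximum(mu.reshape(-1), 1e-6)


def fit(
    table: ContingencyTable,
    spec: AgreementModelSpec,
    *,
    main_coding: str = "reference",
    agreement_coding: str = "effects",
    tol_score: float = 1e-8,
    tol_loglik: float = 1e-10,
    max_iter: int = 100,
) -> FitResult:
    """Fit one agreement model to a contingency table by Poisson ML.

    Parameters
    ----------
    table, spec
        The observed K-way table and the model; rater/category labels must
        match.
    main_coding, agreement_coding
        Column codings (see :mod:`agreemod.models`).  The default
        ``"effects"`` agreement coding reports beyond-chance strengths on
        the +/-1-indicator scale conventional in the agreement-model
        literature; indicator (0/1) estimates are exactly twice as large.
        Deviance, fitted counts and all test statistics are unaffected.

    Raises
    ------
    DivergentParameterError
        If an agreement pattern has zero observed total, so its strength
        diverges to -infinity.
    NonConvergenceError
        If Newton iteration does not meet the score and log-likelihood
        tolerances within ``max_iter``.
    """
    if spec.raters != table.raters or spec.categories != table.categories:
        raise ValueError("spec raters/categories do not match the table")
    if table.n < 1:
        raise ValueError("table must contain at least one subject")
    design = build_design(spec, main_coding, agreement_coding)
    X = design.X
    y = table.flat().astype(float)

    # MLE existence pre-check: a diagonal-agreement pattern that is never
    # observed sends its strength to -infinity.
    for j, lab in enumerate(design.labels):
        if lab.kind != "agreement":
            continue
        ind = design.agreement_indicator(j)
        if float(ind @ y) == 0.0:
            raise DivergentParameterError(
                f"agreement pattern {lab} has zero observed count; "
                "its maximum-likelihood estimate diverges"
            )

    beta, *_ = np.linalg.lstsq(X, np.log(_independence_start(table)), rcond=None)
    eta = X @ beta
    mu = np.exp(eta)
    loglik = float(y @ eta - mu.sum())
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        score = X.T @ (y - mu)
        H = X.T @ (mu[:, None] * X)
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            raise NonConvergenceError(
                "singular Fisher information during Newton iteration",
                beta,
                float(np.abs(score).max()),
            )
        # step-halving keeps the log-likelihood monotone
        new_loglik = -np.inf
        for _ in range(40):
            cand = beta + step
            eta = X @ cand
            if eta.max() > 700.0:  # exp overflow guard
                step = step / 2.0
                continue
            mu_c = np.exp(eta)
            new_loglik = float(y @ eta - mu_c.sum())
            if new_loglik >= loglik - 1e-11 * max(1.0, abs(loglik)):
                break
            step = step / 2.0
        else:
            raise NonConvergenceError(
                "step-halving failed to improve the log-likelihood",
                beta,
                float(np.abs(score).max()),
            )
        beta, mu = cand, mu_c
        rel = abs(new_loglik - loglik) / max(1.0, abs(new_loglik))
        loglik = new_loglik
        score_max = float(np.abs(X.T @ (y - mu)).max())
        # the score is a sum of O(n) terms, so its attainable floor in
        # double precision scales with the table total
        if rel < tol_loglik and score_max < tol_score * max(1.0, y.sum()):
            converged = True
            break
    if not converged:
        raise NonConvergenceError(
            f"no convergence in {max_iter} iterations "
            f"(max score component {score_max:.3g})",
            beta,
            score_max,
        )
    if np.abs(beta).max() > 30.0:
        j = int(np.abs(beta).argmax())
        raise DivergentParameterError(
            f"estimate for {design.labels[j]} diverged (|beta| > 30)"
        )

    H = X.T @ (mu[:, None] * X)
    covariance = np.linalg.inv(H)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(y > 0, y / mu, 1.0)
        deviance = float(2.0 * np.sum(y * np.log(ratio) - (y - mu)))
    deviance = max(deviance, 0.0)
    small = float(np.mean(mu < 5.0))
    if small > 0.2:
        logger.warning(
            "%.0f%% of fitted counts are < 5; the chi-square approximation "
            "to G2 may be unreliable",
            100 * small,
        )
    return FitResult(
        spec=spec,
        design=design,
        table=table,
        coefficients=beta,
        covariance=covariance,
        fitted_counts=mu,
        deviance=deviance,
        residual_df=design.residual_df,
        converged=converged,
        n_iter=it,
    )


def likelihood_ratio_test(fit_reduced: FitResult, fit_full: FitResult) -> HypothesisResult:
    """Likelihood-ratio test of a reduced model against a nesting full model.

    The statistic is the drop in deviance; its null distribution is
    chi-square on the difference in residual dfs.
    """
    if not np.array_equal(fit_reduced.table.counts, fit_full.table.counts):
        raise ValueError("fits are not on the same table")
    if not nested(fit_reduced.spec, fit_full.spec):
        raise ValueError(
            f"{fit_reduced.spec.name} is not nested in {fit_full.spec.name}"
        )
    df = fit_reduced.residual_df - fit_full.residual_df
    if df < 1:
        raise ValueError("degenerate comparison: models have the same dimension")
    statistic = max(fit_reduced.deviance - fit_full.deviance, 0.0)
    return HypothesisResult(
        kind="likelihood_ratio",
        statistic=statistic,
        df=df,
        p_value=float(stats.chi2.sf(statistic, df)),
        constraint=f"{fit_reduced.spec.name} vs {fit_full.spec.name}",
    )


def wald_linear_test(
    fit_result: FitResult,
    constraint: Mapping[str, float] | Sequence[Mapping[str, float]],
    *,
    description: str | None = None,
    name: str | None = None,
    category: str | None = None,
) -> HypothesisResult:
    """Wald chi-square test of ``L beta = 0``.

    ``constraint`` is one row (a mapping from parameter label to
    coefficient) or a sequence of rows; an equality of three strengths is
    encoded as 2 independent difference rows.  The statistic is
    ``(L b)' (L Cov L')^{-1} (L b)`` on df = number of rows.
    """
    rows = [constraint] if isinstance(constraint, Mapping) else list(constraint)
    if not rows:
        raise ValueError("constraint must contain at least one row")
    p = len(fit_result.coefficients)
    L = np.zeros((len(rows), p))
    for i, row in enumerate(rows):
        if not row or all(v == 0 for v in row.values()):
            raise ValueError(f"constraint row {i} is all-zero (degenerate)")
        for label, value in row.items():
            L[i, fit_result.design.column(label)] = value
    if np.linalg.matrix_rank(L) < len(rows):
        raise ValueError("constraint rows are linearly dependent")
    Lb = L @ fit_result.coefficients
    S = L @ fit_result.covariance @ L.T
    try:
        statistic = float(Lb @ np.linalg.solve(S, Lb))
    except np.linalg.LinAlgError:
        raise ValueError(
            "singular constraint covariance L Cov L'; the constraint is "
            "collinear with the model parameterization"
        )
    df = len(rows)
    text = description or "; ".join(
        " + ".join(f"{v:+g}*{k}" for k, v in row.items()) + " = 0" for row in rows
    )
    return HypothesisResult(
        kind="wald",
        statistic=statistic,
        df=df,
        p_value=float(stats.chi2.sf(statistic, df)),
        constraint=text,
        name=name,
        category=category,
    )


def _agreement_labels(fit_result: FitResult, subset_filter) -> dict[str, list[str]]:
    """Category -> labels of category-specific agreement columns whose
    rater subset satisfies ``subset_filter``."""
    out: dict[str, list[str]] = {c: [] for c in fit_result.spec.categories}
    for lab in fit_result.labels:
        if lab.kind == "agreement" and lab.category is not None:
            if subset_filter(set(lab.raters)):
                out[lab.category].append(str(lab))
    return out


def _equality_rows(labels: Sequence[str]) -> list[dict[str, float]]:
    first = labels[0]
    return [{first: 1.0, other: -1.0} for other in labels[1:]]


def named_equivalence_tests(
    fit_result: FitResult, cad_rater: str
) -> list[HypothesisResult]:
    """The standard equivalence hypotheses of a CAD-vs-experts panel.

    For a ``pairwise_nonhomogeneous`` fit, per category m:

    * ``experts_equal``   — all expert-expert pair strengths equal;
    * ``cad_pairs_equal`` — all CAD-expert pair strengths equal;
    * ``experts_vs_cad``  — mean expert-pair strength equals mean
      CAD-pair strength (with three pairs on each side this is the usual
      sum-versus-sum hypothesis).

    For a ``threeway_nonhomogeneous`` fit, per category m:

    * ``experts_vs_cad``  — the all-experts triple strength equals the
      mean of the triples in which the CAD rater replaces one expert.

    Pair/triple terms are split into "within experts" and "involving CAD"
    by membership of ``cad_rater``.
    """
    spec = fit_result.spec
    if cad_rater not in spec.raters:
        raise ValueError(f"CAD rater {cad_rater!r} not among {spec.raters}")
    if spec.name not in ("pairwise_nonhomogeneous", "threeway_nonhomogeneous"):
        raise ValueError(
            "named equivalence tests require a pairwise_nonhomogeneous or "
            f"threeway_nonhomogeneous fit; got {spec.name!r}"
        )
    expert = _agreement_labels(fit_result, lambda s: cad_rater not in s)
    with_cad = _agreement_labels(fit_result, lambda s: cad_rater in s)
    results: list[HypothesisResult] = []
    for cat in spec.categories:
        e, c = expert[cat], with_cad[cat]
        if not e or not c:
            raise ValueError(f"spec lacks expert or CAD agreement terms for {cat!r}")
        if spec.name == "pairwise_nonhomogeneous":
            if len(e) > 1:
                results.append(
                    wald_linear_test(
                        fit_result,
                        _equality_rows(e),
                        description=" = ".join(e),
                        name="experts_equal",
                        category=cat,
                    )
                )
            if len(c) > 1:
                results.append(
                    wald_linear_test(
                        fit_result,
                        _equality_rows(c),
                        description=" = ".join(c),
                        name="cad_pairs_equal",
                        category=cat,
                    )
                )
        row = {lab: 1.0 / len(e) for lab in e}
        for lab in c:
            row[lab] = row.get(lab, 0.0) - 1.0 / len(c)
        results.append(
            wald_linear_test(
                fit_result,
                row,
                description=f"mean({', '.join(e)}) = mean({', '.join(c)})",
                name="experts_vs_cad",
                category=cat,
            )
        )
    return results


@dataclass
class LadderRung:
    name: str
    deviance: float
    df: int
    p_value: float
    adequate: bool


@dataclass
class LadderResult:
    """Outcome of goodness-of-fit model selection along a nested ladder."""

    rungs: list[LadderRung]
    fits: dict[str, FitResult]
    selected_name: str
    adequate: bool
    selection_alpha: float
    test_alpha: float

    @property
    def selected(self) -> FitResult:
        return self.fits[self.selected_name]

    @property
    def trace(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "model": r.name,
                    "G2": r.deviance,
                    "df": r.df,
                    "p_value": r.p_value,
                    "adequate": r.adequate,
                }
                for r in self.rungs
            ]
        )


def run_model_ladder(
    table: ContingencyTable,
    ladder: Sequence[str | AgreementModelSpec] = (
        "independence",
        "homogeneous",
        "nonhomogeneous",
    ),
    selection_alpha: float = 0.05,
    test_alpha: float = 0.01,
    **fit_kwargs,
) -> LadderResult:
    """Climb a nested model ladder and select the first adequate model.

    Each rung is fitted and judged adequate when the chi-square upper-tail
    probability of its deviance is at or above ``selection_alpha``; the
    first adequate rung is selected and later rungs are not fitted.  If no
    rung is adequate the last one is returned flagged inadequate.
    Downstream coefficient and equivalence tests should be read at the more
    conservative ``test_alpha`` (multiple comparisons).
    """
    specs: list[AgreementModelSpec] = []
    for item in ladder:
        if isinstance(item, AgreementModelSpec):
            specs.append(item)
        else:
            specs.append(make_spec(item, table.raters, table.categories))
    if not specs:
        raise ValueError("ladder must contain at least one model")
    for prev, cur in zip(specs, specs[1:]):
        if not nested(prev, cur):
            raise ValueError(f"ladder is not nested: {prev.name} vs {cur.name}")
    rungs: list[LadderRung] = []
    fits: dict[str, FitResult] = {}
    selected: str | None = None
    for spec in specs:
        result = fit(table, spec, **fit_kwargs)
        fits[spec.name] = result
        adequate = result.gof_p_value >= selection_alpha
        rungs.append(
            LadderRung(
                spec.name,
                result.deviance,
                result.residual_df,
                result.gof_p_value,
                adequate,
            )
        )
        if adequate:
            selected = spec.name
            break
    if selected is None:
        selected = specs[-1].name
        logger.warning(
            "no ladder model adequate at alpha=%.3g; returning %s flagged "
            "inadequate",
            selection_alpha,
            selected,
        )
    return LadderResult(
        rungs=rungs,
        fits=fits,
        selected_name=selected,
        adequate=rungs[-1].adequate if selected == rungs[-1].name else True,
        selection_alpha=selection_alpha,
        test_alpha=test_alpha,
    )
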
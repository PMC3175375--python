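# Methods

## Data model

A reader study is a set of subjects each assigned one of C nominal
categories by each of K raters. `agreemod` works on the dense K-way
contingency table of all C^K reading combinations (zeros stored
explicitly; the fitter needs them). Tabulation is complete-case: subjects
missing any rater's reading are dropped with a logged count — the intended
study designs have complete readings, so no imputation machinery exists.
Cells are ordered "odometer" style with the last rater varying fastest;
every flattened vector (counts, fitted counts, design rows) uses this
order so results are comparable across runs.

Categories are treated as nominal. The declared category order matters
only for weighted kappa and for reporting; no ordinal association
structure is modeled.

## The model ladder

Log-linear models for the cell counts y with expected counts u:

* **independence** — log u = intercept + per-rater main effects. Agreement
  is what chance produces under the raters' marginal reading frequencies.
* **homogeneous agreement** — adds one shared strength on the indicator
  "all raters in the term's subset chose the same category".
* **non-homogeneous agreement** — one strength per category: the indicator
  "all raters in the subset chose category m".

For K ≥ 3 the subsets are all unordered rater pairs
(`pairwise_homogeneous` / `pairwise_nonhomogeneous`, K(K−1)/2 terms) or
all unordered rater triples (`threeway_*`). Three-way specs contain
*only* triple terms — on a 3^4 table this gives residual dfs 68
(homogeneous) and 60 (non-homogeneous), the df accounting such panel
analyses report; retaining pairwise terms alongside triples would give
62/42 instead. Arbitrary custom subsets are supported as a
generalization; the named ladder is the documented, tested surface.

### Codings

Main effects use reference-category dummy coding (last declared category
is baseline) or, optionally, sum-to-zero coding. Agreement-parameter
estimates, SEs, fitted counts, deviances and all test statistics are
invariant to this choice (tested to 1e-6); only main-effect estimates
change meaning.

Agreement indicators have two codings. `"indicator"` is the plain 0/1
column. `"effects"` (the default) codes the same column as +1/−1, the SAS
CATMOD convention for two-level variables; the agreement literature built
on CATMOD reports strengths on this scale. The two parameterizations span
the same column space: an effects-coded estimate and SE are exactly half
the indicator-coded ones, and every fit statistic, LRT and Wald statistic
is identical. The default is "effects" so reported coefficients are
directly comparable with published agreement tables.

With C = 2 the per-category pair indicators are linearly dependent on the
main effects (I₂ = 1 − m₁ − m₂ + I₁), so the 2-rater non-homogeneous
design is genuinely rank deficient; construction refuses it and names the
dependent column. Every design is rank-checked at build time.

## Estimation

Poisson maximum likelihood: log μ = Xβ, ℓ(β) = Σ(y·log μ − μ). Because
every design contains an intercept, the fit is equally valid under
multinomial sampling with fixed total n (the reader-study design) for all
parameters of interest.

* **Algorithm.** Newton/IRLS with step-halving (log-likelihood forced
  monotone), started from the closed-form independence fit
  (product-of-marginals expected counts, floored at 1e-6 before taking
  logs).
* **Convergence.** Relative log-likelihood change < 1e-10 *and* maximum
  score component < 1e-8 × max(1, n); the score is a sum of O(n) terms,
  so its attainable floor in double precision scales with the table
  total. Iteration cap 100; non-convergence raises an error carrying the
  last iterate and score norm rather than returning a silent partial fit.
* **Existence.** An agreement pattern with zero observed total has its
  MLE at −∞; this is detected up front and reported as a divergent
  parameter naming the column (sampling zeros elsewhere are fine and are
  retained). A post-fit guard (|β| > 30) catches other separations.
* **Inference.** Covariance = inverse observed Fisher information
  (X' diag(μ̂) X)⁻¹; SEs are its diagonal roots; per-coefficient tests are
  two-sided Wald z. Goodness of fit is the deviance
  G² = 2 Σ_{y>0} y ln(y/μ̂) against chi-square on C^K − p df. The
  chi-square approximation is used regardless of sparsity, matching
  standard practice for these analyses; a warning is logged when more
  than 20% of fitted counts are below 5.

## Testing and model selection

* **Likelihood-ratio tests** compare nested models (nesting verified by
  column-space containment, not by name): statistic = drop in deviance,
  df = drop in residual df.
* **Wald tests** handle linear hypotheses among coefficients:
  (Lβ̂)'(LΣ̂L')⁻¹(Lβ̂) on df = rank of L. Equality of three strengths is
  encoded as two independent difference rows. A single-row test equals
  the squared z-test (tested).
* **Named equivalence tests** for a CAD rater on a category-specific
  pairwise fit, per category: experts-equal, CAD-pairs-equal, and
  experts-vs-CAD (mean expert-pair strength = mean CAD-pair strength;
  with three pairs a side this is the usual sum-vs-sum hypothesis). On a
  three-way fit: all-experts triple strength = mean of the CAD-containing
  triple strengths. Wald statistics are invariant to the agreement
  coding and to common rescaling of the strengths.
* **`run_model_ladder`** fits rungs in order and selects the first whose
  goodness-of-fit p-value is at or above `selection_alpha` (default
  0.05). Post-selection coefficient and equivalence tests are read at
  the more conservative `test_alpha` (default 0.01, a multiple-comparison
  precaution). If no rung is adequate the last one is returned flagged
  inadequate.

## Synthetic panels

The generator is the model's exact probabilistic mirror: cell
probabilities ∝ exp(X·β), subjects drawn multinomially with fixed total n
and an explicit integer seed (numpy `default_rng`; no global state).

Why it exists: published analyses print 2-rater tables but essentially
never the full K-rater cross-classification, so the K-rater machinery is
validated property-based — parameter recovery, SE calibration, interval
coverage and test type-I error on panels with known truth.

* **Margin calibration.** Published analyses report agreement strengths
  but not main effects, and strong agreement terms pull the marginal
  reading frequencies far from what main effects alone give (naively
  combining published strengths with margin-matched-under-independence
  main effects concentrates ~98% of mass on the all-agree cell).
  `calibrate_main_effects` therefore solves the moment conditions
  "each rater's marginal = target" for the main effects with the
  agreement coefficients held fixed. The conditions are the score
  equations of a concave multinomial likelihood whose sufficient
  statistics are the target margins, so damped Newton ascent is globally
  convergent.
* **Presets.** `preset_renex_panel`: K = 4 (three experts + CAD), C = 3,
  n = 185, pairwise category-specific strengths set to the published
  panel estimates, margins calibrated to the study's ~59/16/25% reading
  split. `preset_renex_consensus`: 2-rater generator whose coefficients
  are the ML fit of the bundled table (a parametric-bootstrap generator).
* **`recovery_study`**: replicated simulate-and-refit; reports per
  agreement parameter the bias, empirical SE, mean model SE and Wald
  interval coverage. Replicate-level fit failures are counted, not
  fatal; >10% failures flags the study. Minimum 50 replicates.

What the generator does **not** emulate: rater-specific drift or bias
processes, missing readings, within-patient correlation between paired
organs, or ordinal latent traits. Passing Monte-Carlo checks therefore
demonstrate correctness of the estimator and tests under the stated
sampling model, not robustness to those real-data features.

## Classic comparators

Per-category percent agreement uses the second rater of a 2-rater table
as the reference reader (its margin is the denominator); a zero margin is
flagged undefined, not an error. Cohen's kappa supports unweighted,
linear and quadratic weights over the declared category order; degenerate
margins (expected agreement 1) are flagged undefined. No kappa SE/CI is
provided — the statistic is a comparator here, not an inferential target.

## Problem sizes and determinism

The bundled analyses are desk-scale (9- and 81-cell tables; each fit is
milliseconds). Monte-Carlo validation uses n = 20,000 subjects per
replicate with 500 replicates for recovery and type-I-error studies, and
200 replicates for the power check — sizes chosen so Monte-Carlo noise is
small relative to the property bands being checked. All stochastic tests
and scripts run from fixed or caller-supplied seeds; repeated runs are
byte-identical apart from log timestamps.

## Known limitations

* Within-patient correlation (two kidneys per patient) is not modeled;
  subjects are treated as independent units, replicating standard
  practice for this design.
* Sparse tables rely on the asymptotic chi-square for G²; no exact or
  bootstrap alternatives are provided.
* Weighted-kappa values depend on the weighting scheme and category
  order; cross-study comparisons of single kappa values are exactly the
  ambiguity the model ladder is meant to replace.
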
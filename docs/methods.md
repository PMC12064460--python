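# Methods

## The measurement model

All analyses are built on Samejima's graded response model (GRM) for
polytomous items. Each item j has a discrimination a_j > 0 and ordered
thresholds b_j1 ≤ … ≤ b_j4 (five response categories). The probability of
answering in category k or higher is a logistic curve in the latent trait θ,

    P*_jk(θ) = 1 / (1 + exp(−a_j (θ − b_jk))),    k = 1..4,

and category probabilities are adjacent differences of these curves. The
scaling constant is D = 1 (the mirt-style logistic metric); the bundled
Swedish pediatric PROMIS anxiety (15 items) and depressive-symptoms
(14 items) calibrations are on that metric, so no 1.7 normal-ogive factor is
applied anywhere. θ lives on a standard-normal reference scale; the PROMIS
T-score is T = 10θ + 50, and reliability at a given precision is 1 − SE².

Item Fisher information is Σ_k (∂P_jk/∂θ)² / P_jk with
∂P*_jk/∂θ = a_j P*_jk (1 − P*_jk); test information adds over items and
SE(θ) = 1/√I(θ) for full-bank reliability curves.

## Numerical quadrature

One fixed grid serves calibration, EAP scoring, and information summaries:
61 equally spaced nodes on [−4, 4] with standard-normal density weights
renormalized to sum to one. The trait range follows the convention that
PROMIS traits are scored on roughly ±4. The grid is an explicit argument
everywhere, so tests that need tighter integration (e.g. the EAP
fine-grid-oracle comparison) pass a denser grid (601 nodes on [−6, 6])
rather than changing the default.

## EAP scoring

The trait estimate is the posterior mean under a standard-normal prior; the
reported standard error is the posterior standard deviation (not 1/√I at the
point estimate), matching common CAT practice (catR-style EAP). Missing
items are simply skipped in the likelihood; with nothing answered the prior
mean 0 and SD 1 are returned.

## Calibration

`fit_grm` is Bock–Aitkin marginal maximum likelihood EM. The E-step computes
person posteriors over the grid; the M-step maximizes each item's expected
complete-data log-likelihood by BFGS on the unconstrained parameterization
(log a, b1, log successive threshold differences), which enforces a > 0 and
threshold ordering. A proposed M-step that fails to improve an item's
expected objective is rejected, preserving the EM monotone-likelihood
guarantee. Convergence: maximum absolute parameter change < 1e−4 (default)
or 500 cycles, with a warning and the full likelihood trace on
non-convergence. Starting values: unit-ish slopes (1.5) with thresholds from
inverse-logistic transforms of the marginal cumulative proportions.

## Item fit (S-X²)

Observed versus expected category frequencies conditional on the summed
score, with summed-score likelihoods from the Lord–Wingersky recursion
extended to polytomous items. Adjacent summed-score levels, then adjacent
category cells within a level, are collapsed until every expected count
reaches 1. Degrees of freedom: collapsed cells − score levels − item
parameters (5 per item), floored at 1; adequacy is declared at p > 0.001.
The statistic is calibrated when the analyzed parameters were estimated from
the same data — the type-I simulation in the test suite therefore refits the
model on every replicate.

## Assumption checks

* **Polychoric correlations** — two-step ML: thresholds from normal
  quantiles of the marginal category proportions, then Brent maximization of
  the bivariate-normal contingency likelihood over ρ ∈ (−0.999, 0.999). The
  matrix is eigenvalue-clipped to the nearest positive semi-definite
  correlation matrix when sampling noise pushes it indefinite.
* **KMO** — Σr² / (Σr² + Σq²) over off-diagonals, q the anti-image partial
  correlations; 0.90+ is conventionally "excellent", 0.70+ "moderate".
* **Parallel analysis** — observed polychoric eigenvalues against the mean
  eigenvalues of random datasets with matched marginals (per-item
  permutation). Mean (not 95th-percentile) reference with 100 replicates by
  default; both are configurable since conventions differ.
* **EFA** — iterated principal factors (unit-weight least squares) on the
  polychoric matrix; unidimensionality requires a ≥ 20% first-factor
  variance share and a first/second eigenvalue ratio > 4.
* **One-factor CFA** — least-squares loadings on the polychoric matrix;
  residual correlations above 0.20 flag local dependence. CFI/TLI/RMSEA/SRMR
  are computed from the unscaled ML discrepancy of the fitted structure.
  These indices approximate, but do not equal, the scaled DWLS values that
  ordinal-CFA software (lavaan WLSMV) reports; they are for screening, not
  for reproducing published fit indices.
* **Mokken scalability** — H coefficients as observed / maximal covariance,
  the maximum from the comonotonic (Guttman) coupling of the item marginals;
  item H > 0.30 and scale H > 0.50 support monotone homogeneity. The scale-H
  standard error is a person bootstrap (default 100 resamples).

The pipeline honors the split-sample convention: EFA-side checks (KMO,
parallel analysis, EFA) on a random half, the confirmatory fit on the other
half, monotonicity on the pooled sample.

## DIF

Proportional-odds ordinal logistic regression with the EAP theta from the
full bank as the matching variable, three nested models per item
(θ; θ+group; θ+group+θ×group), and McFadden pseudo-R² changes as the effect
size. ΔR² ≥ 0.02 flags uniform (M0→M1) or non-uniform (M1→M2) DIF. One
purification round — rescoring on unflagged items and rescanning — runs by
default and can be disabled; iteration counts beyond one give no measurable
benefit on the synthetic cohorts. Model fits go through statsmodels'
`OrderedModel`; tiny optimizer slack between nested fits is clamped so the
ΔR² values are never negative. Fixed-threshold flagging only; Monte-Carlo
empirical thresholds are out of scope.

## Linking

Stocking–Lord: the constants (A, B) minimize the squared distance between
the reference test characteristic curve and the transformed focal TCC
(a ↦ a/A, b ↦ Ab + B) under the standard-normal grid weights. Under this
loss, `apply_transform(focal, constants)` lands the focal items on the
reference metric, which is exactly what hybrid-bank assembly needs:
reference parameters everywhere, linked focal parameters for the DIF items,
with the constants estimated on the non-DIF anchors. Optimization is
Nelder–Mead from (1, 0) with a coarse multi-start fallback. Because official
U.S. parameters are not public in the sources this package draws on, demos
use a synthetically perturbed copy of the Swedish bank as the "reference";
it is labelled synthetic wherever it appears.

## Post-hoc CAT

Responses are always looked up from the recorded matrix, never generated by
the engine. Selection is maximum Fisher information at the interim EAP
estimate, starting from the most informative item at θ = 0; stopping at
SE ≤ 0.316 (reliability 0.90) after at least `min_items`, or bank
exhaustion. Decile summaries rank persons by the reference theta (full-bank
EAP by default, the generating theta on request) and split them into ten
equal parts; bias and RMSE are CAT-estimate minus reference. EAP posterior
SDs can occasionally rise when a response is surprising, so SE monotonicity
holds as an aggregate (≥95% of steps), not per step.

## Synthetic cohorts

The generator emulates a two-group school/psychiatric-clinic cohort:
637 + 291 respondents by default, group latent means −0.23 and 0.50
(the published known-group T-scores 47.7 and 55.0 inverted through
θ = (T−50)/10), within-group SD 1.0 (within-group latent SDs are not
published; 1.2 — implied by pooled T-score SDs — is a documented
alternative), MCAR missingness at 3.4%, and sex labels at the published
proportions (61.1% / 71.4% female) used purely as DIF grouping variables.
Validation samples for the CAT replication are rebuilt from the published
decile profiles (per-decile mean thetas and simulee counts, n = 196 anxiety
/ 199 depressive) with N(0, 0.15) jitter — small relative to the decile
spacing — so the trait distribution matches the published one without
copying any respondent data.

What the generator does **not** emulate: multidimensionality, locally
dependent item pairs (unless planted), non-normal latent distributions,
MNAR missingness, careless responding. Passing assumption checks on
generated data therefore demonstrates that the *decision rules* are
implemented correctly, not that any real dataset satisfies them.

## Problem sizes and tolerances

Statistical tests use the sizes at which their properties are sharp but
cheap: parameter recovery at n = 1000 (corr(a, â) > 0.9, mean |b̂ − b| <
0.15), S-X² type-I calibration over 200 replicates of n = 700 on a 5-item
subbank, DIF operating characteristics over 20 seeds at 750 per group, CAT
replication over 10 seeds of the published validation-sample sizes.
Exact-arithmetic oracles are asserted at 1e−10..1e−12; integration-based
comparisons at 1e−4; simulation bands are stated per test.

## Known limitations

* CFA fit indices are least-squares approximations (see above); published
  scaled-DWLS index values are out of reach by design.
* The EM standard errors of item parameters are not computed (no
  information-matrix inversion); calibration uncertainty is assessed by
  simulation instead.
* Only two-level DIF comparisons; no Mantel–Haenszel/SIBTEST, no empirical
  ΔR² thresholds.
* No exposure control or content balancing in the CAT engine.
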
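# Methods

## Model and assumptions

For a variant j with exposure association (β̂_Xj, σ_Xj) and outcome
association (β̂_Yj, σ_Yj) measured in non-overlapping samples, the
instrumental-variable model is

    β_Yj = θ β_Xj + α_j ,

where θ is the causal effect of the exposure on the outcome and α_j is the
variant's direct (pleiotropic) effect on the outcome.  Valid instruments
have α_j = 0 (exclusion restriction) and must be associated with the
exposure (relevance) and independent of confounders.  Binary traits are
handled on the log-odds scale throughout, so θ exponentiates to an odds
ratio per exposure unit; continuous traits are in SD units.

## Harmonization

Both samples must refer to the same effect allele.  For each shared
variant: identical allele pairs are kept; swapped pairs flip the sign of
the outcome beta (and reflect its allele frequency); a strand complement is
tried, and logged, before a variant is dropped as irreconcilable.
Palindromic variants (A/T, C/G) are intrinsically strand-ambiguous, so they
are retained only when both allele frequencies are informative: after
mapping the outcome frequency onto the exposure's effect allele, both
frequencies must lie outside [limit, 1−limit] (default limit 0.42) and on
the same side of 0.5; palindromes with missing frequencies are dropped.
Finally every pair is oriented to the exposure-increasing allele
(β̂_X ≥ 0).  This convention is what makes the Egger intercept identifiable,
and it makes every Wald ratio invariant to the arbitrary allele choice of
the input files (property-tested).

## Instrument selection

Variants pass at p < 5×10⁻⁸ (strict inequality), then greedy LD clumping
retains, repeatedly, the remaining variant with the smallest p (ties broken
by variant id) and discards everything with r² ≥ 0.001 against it.  The LD
matrix is caller-supplied (synthetic block-diagonal in tests); no reference
panel is consulted.  Instrument strength is summarized by
F = R²(n−k−1)/(k(1−R²)) with R² = Σ 2f_j(1−f_j)β̂²_Xj, the standard
approximation for standardized traits; for binary exposures the same
expression on the log-odds scale is used and flagged approximate.  The
F > 10 gate is advisory: failing it flags downstream estimates
`weak_instruments` rather than aborting, since F is a quality diagnostic,
not an estimator input.

## Univariable estimators

* **Wald ratio**: θ̂_j = β̂_Yj/β̂_Xj with first-order SE σ_Yj/|β̂_Xj|.  The
  exposure-noise term is deliberately omitted so the implied weights match
  the IVW weights; a second-order SE is available behind a flag.
* **IVW**: the weighted mean of ratios with weights β̂²_Xj/σ²_Yj, computed
  in the equivalent regression form Σwβ̂_Xβ̂_Y/Σwβ̂²_X (w = 1/σ²_Y), which
  stays defined when some β̂_X = 0.  Fixed-effects SE is 1/√(Σwβ̂²_X).
  Cochran's Q = Σw(β̂_Y − θ̂β̂_X)² is referred to χ²(k−1); when its p-value
  is below `het_alpha` (default 0.05) the SE is multiplied by
  max(1, √(Q/(k−1))) — multiplicative random effects, chosen over an
  additive between-variant variance because it is the natural companion of
  the regression formulation.  A single instrument reduces exactly to the
  Wald ratio.
* **MR-Egger**: weighted regression of β̂_Y on β̂_X with a free intercept
  (weights 1/σ²_Y), after orienting to β̂_X ≥ 0.  The slope estimates θ
  under the weaker InSIDE assumption; the intercept estimates the mean
  directional pleiotropy and is tested two-sided against t(k−2).  SEs carry
  the multiplicative overdispersion max(1, √(RSS_w/(k−2))); the weighted
  RSS (Rucker's Q′) is reported as the heterogeneity statistic.
* **Weighted median**: ratios are ordered and the standardized cumulative
  weight p_j = (Σ_{i≤j} w_i − w_j/2)/Σw is interpolated at 1/2; consistent
  whenever valid instruments carry more than half the weight.  SE by
  parametric bootstrap: (β̂_X, β̂_Y) redrawn from normals at the observed
  SEs, default 1000 replicates, seed mandatory.
* **Modes**: the argmax over a 512-point grid of a Gaussian-kernel density
  of the ratios, bandwidth φ·0.9·min(sd, MAD/0.6745)·k^(−1/5) (φ default 1).
  The simple mode weights ratios equally, the weighted mode by inverse
  first-order ratio variance.  Degenerate zero bandwidth (all ratios equal)
  returns the common ratio.  Bootstrap SEs as for the median.

P-values use the normal reference except MR-Egger (t with k−2 df);
everything is two-sided; 95% CIs use the matching quantile.

## MR-PRESSO

For each variant the IVW slope is re-fitted leaving it out; the observed
residual sum of squares RSS = Σ_j (β̂_Yj − θ̂_{−j}β̂_Xj)²/σ²_Yj is compared
with n_sim ≥ 1000 Monte-Carlo replicates drawn as
β̂*_Xj ~ N(β̂_Xj, σ_Xj), β̂*_Yj ~ N(θ̂_{−j}β̂_Xj, σ_Yj), each replicate
re-fitted leave-one-out.  Monte-Carlo p-values use the add-one convention
(1 + #exceed)/(n_sim + 1), so the smallest attainable p is 1/(n_sim+1).
Per-variant residual contributions get the analogous tail p, Bonferroni
adjusted across the k tested variants at α = 0.05.  The corrected estimate
is exactly plain IVW on the unflagged set.  The distortion test compares
the raw-minus-corrected shift against shifts from removing random subsets
of the same size.  A known geometric limitation: because raw and corrected
estimates share the noise of the clean variants, the probability that the
corrected estimate is closer to the truth in a *single* dataset is bounded
near Φ(s√(k−1)/(2k)) for an outlier shifted by s outcome-SEs — removal
eliminates the outlier's bias on average, but not in every realization.

## Multivariable MR

The outcome effects are regressed on the k×m matrix of exposure effects
(no intercept, weights 1/σ²_Y) over the union of per-exposure instruments,
jointly re-clumped ranked by minimum p across exposures and assembled
complete-case: a variant missing from any exposure table is dropped and
logged, never zero-imputed, because silent imputation biases coefficients
toward the null invisibly.  Coefficient j is the direct effect of exposure
j given the others.  The residual overdispersion √(RSS_w/(k−m)) (floored
at 1) is applied under the same heterogeneity gate as univariable IVW —
this keeps the m = 1 case *identical* to univariable IVW, which we treat as
a non-negotiable consistency requirement of the estimator family.  A
per-exposure conditional instrument-strength diagnostic (weighted residual
chi-square of that exposure's effects after projecting out the co-exposures,
scaled by k−m+1) is reported, advisory, against the usual threshold of 10.

## Mediation, pooling, multiplicity

Two-step mediation MR: step 1 is univariable IVW of the mediator on the
exposure's instruments (δ̂); step 2 is the MVMR coefficient of the mediator
with the exposure included (τ̂) — adjusting step 2 for the exposure is the
standard product-of-coefficients formulation.  Indirect effect = δ̂τ̂ with
delta-method SE √(δ̂²σ²_τ + τ̂²σ²_δ); direct = total − indirect; proportion
mediated = indirect/total with a delta-method CI that ignores the
total–indirect covariance (measured coverage ≈ 0.94 at the default study
conditions).  The proportion is suppressed when |total|/SE < 1 (unstable
ratio) or when indirect and total disagree in sign; binary outcomes carry a
non-collapsibility flag since everything lives on the log-OR scale.

Cohort estimates of the same effect are pooled with fixed-effects
inverse-variance weights; between-cohort Q is computed and flagged when
significant but never switches the pooling model.  Outcome-panel
multiplicity uses Bonferroni tiers: p < α/n_outcomes is significant
(0.05/18 = 0.0028 for the default 18-outcome panel), α/n ≤ p < α is
suggestive, otherwise null.

## Synthetic data generator

Summary statistics are generated directly on the observation scale — no
individual-level data — because two-sample MR consumes nothing else and
direct generation makes the ground truth exact.  Traits form a linear
structural model: each trait owns k lead SNPs with effects scaled to a
target explained variance R² (magnitudes U(0.5,1.5), random signs), and
inherits its parents' per-SNP effects times structural coefficients; a
mediator chain M = δX, Y = θ_dir·X + τM therefore has total exposure effect
θ_dir + δτ by construction (tested exactly).  Standard errors follow
1/√(2nf(1−f)) for standardized continuous traits and
1/√(2nf(1−f)φ(1−φ)) on the log-OR scale for binary traits (φ = case
fraction); observed estimates are normal draws at those SEs, with two
outcome cohorts drawn independently.  Pleiotropy α_j ~ N(μ_α, σ_α²) is
planted *relative to the exposure-increasing allele* of the parent exposure
(otherwise random allele orientation would silently convert directional
into balanced pleiotropy), optionally correlated (ρ) with instrument
strength to violate InSIDE.  Outliers add a stated multiple of the outcome
SE to chosen instruments.  Decoy null SNPs give the significance filter
something to reject; block-diagonal LD (shared true effect within a block)
gives clumping something to prune.  All randomness derives from one seed
via `SeedSequence` spawning; identical seeds give byte-identical tables.

What the generator does **not** emulate: realistic LD from reference
panels, exposure–outcome sample overlap, winner's curse in instrument
discovery, liability-scale binary genetics, or allele-frequency differences
between cohorts.  Passing tests therefore demonstrate correctness of the
estimators and pipeline under the stated statistical model, not robustness
to those real-data complications.

The `paper_shape` preset mirrors a consortium-scale study layout: four
correlated metabolic exposures (one binary at n = 898,130 with case
fraction 0.0825 and 286 instruments; three continuous at n = 133,010 /
133,010 / 88,355 with 35 / 18 / 38 instruments), eighteen outcomes (twelve
binary disease traits, six continuous lipid traits) each in two independent
cohorts, and three lipid mediators; per-exposure R² targets (0.35 on the
log-odds scale for the binary exposure, 0.015–0.03 for the continuous ones)
are chosen so instruments clear genome-wide significance with F ≈ 70–170.
True effect sizes are set at the order of magnitude typical for
cardiometabolic MR (log-ORs from 0.001 to 0.19, lipid shifts up to 0.44 SD)
with small balanced pleiotropy (σ_α = 0.003) and mediated components
contributing 5–13% of selected totals.

## Numerical and scale choices

Problem sizes for the Monte-Carlo validation experiments are chosen for a
single desktop CPU: 1000 replicates for type-I error and coverage, 500 for
intercept and mediation recovery, 200 for outlier detection with
n_sim = 1000 PRESSO draws, and 200 bootstrap replicates for median/mode SEs
in full-grid runs (the estimator-level default is 1000).  Grid cells get
independent seeds derived from `SeedSequence((seed, cell_index))`, so
results are independent of execution order and thread count; result rows
are sorted before writing so re-runs are byte-identical.  Ties in clumping
break lexicographically; weighted-median interpolation clamps to the
extreme ratio when one variant holds over half the weight; KDE grids span
the ratio range ±3 bandwidths at 512 points.

## Known limitations

Wald-ratio SEs ignore exposure-side noise (first-order), so very weak
instruments bias estimates toward the null — the F gate exists to flag that
regime rather than correct it.  The mediation proportion's delta-method CI
ignores the covariance between total and indirect estimates from the shared
outcome sample.  The conditional-F diagnostic is an approximation, not the
full weak-instrument test.  MVMR assumes the union instrument set is valid
for all exposures jointly; no MVMR-Egger fallback is provided.
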
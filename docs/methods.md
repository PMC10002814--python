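# Methods

This note documents the models and procedures implemented in `csfstrat`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions that matter for
reproducing a run.

## Biomarker gating

The tTau:Aβ42 ratio across a cognitively normal cohort that mixes
biomarker-negative and biomarker-positive individuals is bimodal. We model
it as a two-component univariate Gaussian mixture, fitted by EM
(`sklearn.mixture.GaussianMixture`; 10 restarts, tolerance 1e-8 on the
log-likelihood, variance floored at 1e-6·var(data), best restart by
log-likelihood). The decision cutoff is the **equal-posterior crossing**
between the two component means — the point where membership in either
component is equally probable, i.e. the Bayes decision boundary of the
fitted mixture. It is located by a sign change on a 2048-point grid
between the means and refined by Brent's method. We chose the
equal-posterior crossing over an equal-density or midpoint rule because it
is the decision-theoretic boundary and respects unequal component weights.

Degenerate fits yield **no cutoff**: a fit is flagged when the component
means are closer than 1 SD of the wider component or the lighter component
weighs under 2%. Single-component data must fail loudly rather than emit a
meaningless threshold.

Fitting may be done on the raw ratio (default) or on log ratio. In the
full pipeline the mixture is fitted on the **cognitively normal subjects
only**: including symptomatic AD cases makes the positive side itself
bimodal (AsymAD around 0.3, AD around 0.65) and the 2-component fit can
then split positives instead of separating negatives from positives.

Gating convention: biomarker-positive iff ratio **strictly greater** than
the cutoff. Cognitively normal ∧ positive → AsymAD; normal ∧ negative →
CN/BM−; impaired ∧ positive → AD; impaired ∧ negative falls outside the
study design and is labeled `Impaired/BM-`. Missing analytes exclude the
subject, with a logged reason.

Youden-index cutoffs (`youden_cutoff`) take candidates at midpoints of
consecutive distinct scores, maximize J = sensitivity + specificity − 1,
and break ties toward higher specificity. Direction is explicit
("greater" or "lesser" = positive) because some external scores are
positive above a threshold (amyloid PET SUVR) and others below
(FDG PET SUVR).

Analyte standardization uses the sample SD (ddof=1); a stored reference
(mean, SD) supports train-only standardization of held-out data.

## Discriminative panel selection

RFE drops **exactly one feature per step**: fit the classifier on the
surviving standardized features, remove the feature with the smallest
absolute coefficient (ties toward the lower column index), refit, stop at
`stop_size` (default 14). One-at-a-time elimination is slower than
block elimination but is exactly reproducible by a step-by-step refit
oracle, which the tests exploit.

The two base classifiers are a linear-kernel SVM with C=1 and L2 logistic
regression with C=1 (lbfgs). Neither is tuned — hyperparameter search
inside selection would leak information. Feature importance is the
absolute coefficient on train-standardized features for both. The final
panel is the intersection of the two 14-peptide selections, kept in input
column order; an empty intersection is allowed but warned about.

The train/test split is stratified per class with the held-out count
`ceil(0.2 · n_class)` (134 per class → 27 + 27 = 54 held out) and a seeded
within-class shuffle. Held-out subjects play no role in standardization,
selection, or training; a property test corrupts the held-out rows and
asserts that no selection output changes.

The permutation null draws B (default 100,000) random panels of the
observed panel's size, uniformly without replacement within a panel
(panels may repeat across draws; the observed panel is not excluded — the
collision probability is negligible), evaluates each with the identical
train/test protocol, and reports empirical p = (1 + #{null ≥ observed}) /
(B + 1) per metric, which is never zero. Caveat: when the cohort signal is
strong, observed metrics sit at their ceiling (recall = 1.0, AUC = 1.0)
and tie with the best null panels; tied nulls count toward p, so
ceiling-valued metrics give conservative (larger) p-values.

## AsymAD stratification

The selected panel (log abundances, standardized) is embedded to 2-D by
t-SNE jointly for reference and query subjects — this method has no
out-of-sample extension, so queries must be embedded together with the
references. Perplexity defaults to 30 capped at (n−1)/3, 1000 iterations,
random initialization (so different seeds genuinely explore different
layouts). Each AsymAD query receives the majority label of its k=5 nearest
reference subjects by Euclidean distance in the embedding; AsymAD cases
never vote, k is required odd so votes cannot tie, and distance ties break
toward the earlier reference row (stable sort).

Because the embedding depends on initialization, embed+vote is repeated
(default 100×) with per-repeat seeds spawned from the master seed. The
fraction of repeats voting AD-like is the assignment probability; the
final label is AD-like above 0.6, Control-like below 0.4, otherwise
`uncertain`. The band (0.4, 0.6) operationalizes "unstable under
re-initialization"; `repeats=1` recovers a single-run assignment.

APOE enrichment between derived subgroups uses a two-sided Fisher exact
test on the genotype × subgroup table over the six ε2/ε3/ε4 genotype
pairs. No exact r×2 routine exists in scipy/statsmodels, so the test
enumerates all tables with the observed margins (p = total probability of
tables no more probable than the observed, the standard two-sided
convention) when the table count — computed first by dynamic
programming — is below 2×10⁶, and otherwise falls back to a seeded Monte
Carlo sample of the multivariate hypergeometric null with the
(1 + x)/(B + 1) estimator.

## JMI sub-grouping panel

Greedy forward selection under the joint-mutual-information criterion:
the first feature maximizes the plug-in I(X;Y); each later step adds the
candidate maximizing Σ_{s∈selected} I(X_cand, X_s; Y), estimated from the
3-way contingency of (bin_cand, bin_s, y). Plug-in estimation with no
bias correction is a documented limitation; it is adequate at the bin
counts and sample sizes used here but biases all scores upward equally.

Continuous features are discretized into 5 equal-frequency bins with
edges computed on training subjects only (no leakage). Features with at
most 5 distinct values are used as categories directly, because quantile
edges can land on data values and merge levels; constant features are
excluded and logged. Ties in the selection score break toward the earlier
column.

Evaluation mirrors the discriminative stage: 20% held-out accuracy of an
L2 logistic classifier (train-only standardization), and stratified
6-fold cross-validated ROC with per-fold AUC by trapezoidal integration
(equivalently the Mann-Whitney U statistic with half-credit ties), mean
AUC, and its standard error across folds.

## Cohort statistics

Median regression (quantile 0.5, `statsmodels.QuantReg`) regresses each
cognitive score on one standardized analyte plus covariates (age, sex,
race, education; categoricals dummy-coded, listwise deletion logged). The
reported β is the outcome change per 1 SD of analyte; more positive β =
stronger positive association. Inference defaults to a seeded
nonparametric bootstrap (B=1000; percentile 95% CI; p from the normal
approximation with the bootstrap SE) because no distributional assumption
on the skewed residuals is warranted; kernel-based asymptotic SEs are
available via `ci_method="asymptotic"`. Sparse scores are dichotomized at
their median (ties to the lower class — deterministic and conservative)
and fitted by maximum-likelihood logistic regression; perfect separation
falls back to an L2-penalized fit and flags the result.

BH FDR uses the step-up procedure at q=0.20 (delegated to statsmodels;
the tests verify it against the step-up definition directly). Kendall
ranking uses tie-corrected τ-b per peptide, stably sorted descending,
with constant peptides excluded. Matched-group tests dispatch to paired
t, Wilcoxon signed-rank (undefined and flagged when all differences are
zero), McNemar-Bowker symmetry (statistic 0, p 1 for symmetric tables),
and the Fisher machinery above.

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes, with
known ground truth:

- **Groups and sizes.** 134 control / 134 AsymAD / 134 AD by default,
  demographically matched by construction (same age, sex, race
  distributions; AD educated slightly lower).
- **CSF analytes.** Per-group log-normals calibrated so medians and IQRs
  match typical Elecsys values for the three groups (e.g. control Aβ42
  median 1412 pg/ml vs AD 540.7; control tTau 167.6 vs AD 343.2). tTau and
  pTau share a latent factor (correlation 0.9). Positive-group draws are
  rejection-sampled to lie strictly above the 0.24 ratio cutoff and
  controls at or below it, so the positive mixture component contains
  every AsymAD/AD subject; with 500+ per group the realized analyte
  medians stay within 10% of their targets despite the truncation.
- **Latent continuum.** Controls sit at u=0, AD at u=1; AsymAD draw u from
  an equal mixture of Beta(2,5) and Beta(5,2), so both subgroups are
  populated with a thinner middle. AsymAD log-peptide centroids
  interpolate linearly between the control and AD centroids at u. The
  true subgroup label is AD-like iff u > 0.5.
- **Peptides.** 75 log-normal peptides (unit log-SD), 8 of which carry a
  2-SD log-scale shift between the control and AD centroids; a
  peptide→protein map assigns 75 peptides to 58 proteins. Optionally two
  pseudo-peptides can be coupled to APOE ε4 allele dose with opposite
  signs (emulating isoform-specific peptides); this is off by default and
  enabled explicitly by the tests that exercise it.
- **APOE.** Genotypes drawn under Hardy-Weinberg at group ε4 allele
  frequencies 0.08 / 0.40 / 0.50 (control / AsymAD / AD). For AsymAD the
  per-subject allele probability is `freq + coupling·(u − 0.5)` (coupling
  0.6 by default), which preserves the group frequency exactly in
  expectation while enriching ε4 along the AD side of the continuum —
  matching the observed ε4 enrichment in AD-like subgroups.
- **Cognition.** Scores are linear in standardized log-analytes with
  right-skewed, median-zero noise (shifted gamma): visual memory loads
  −0.9 SD on tTau, visuospatial judgment −0.35, the global screen −0.25,
  verbal list learning and Aβ42 loadings are null — the tau-linked
  visuospatial pattern the regression stage should recover.
- **Comorbidities.** Bernoulli flags with logistic probabilities in
  standardized Aβ42 (dyslipidemia and diabetes negatively loaded,
  hypertension uncoupled); family history of AD is coupled to ε4 dose.

What the generator does **not** emulate: within-group peptide covariance
(diagonal by default — real SRM panels are correlated within protein
modules), assay-level missingness and batch effects, longitudinal visits,
and imaging. Passing recovery tests therefore demonstrate the pipeline's
correctness and statistical calibration under the assumed structure, not
performance on real cohort heterogeneity.

Matching (`match_groups`) is greedy on the globally smallest
standardized-L1 distance among eligible pairs (exact on categoricals,
within caliper on continuous, each control used once, ties broken by row
order). Greedy matching is deterministic and adequate for constructing
matched test cohorts; it is not optimal assignment.

## Pipeline, seeds, reproducibility

`run_pipeline` executes synth → gate → select → stratify → jmi → stats,
writing every stage output plus `manifest.json` with stage parameters and
seeds. A single master seed fans out to stage seeds via numpy
`SeedSequence` spawning, and stability repeats spawn per-repeat seeds the
same way; no stage touches global random state, so re-running a config
reproduces every output byte-identically. Config validation (panel sizes
vs peptide count, odd k, q in (0,1), split fraction) runs before any
compute. Downstream stages consume the **gated** labels, not the
generator's group column.

## Problem sizes used in tests and the acceptance script

Chosen so a full run completes comfortably on one CPU: permutation-null
calibration uses 200 replicates at B=500 and the planted-panel check
B=1000 (the pipeline default stays at the reference 100,000); stability
stratification is verified at 25 repeats (default 100); bootstrap CI
coverage uses 50 replicates at n=300 with B=199 (default B=1000); the
acceptance script runs B=2000 and 25 repeats. These sizes are reported
alongside each result and do not change any method default.

## Known limitations

- Plug-in MI estimates are upward-biased at small n; JMI rankings are
  robust to this but absolute scores should not be interpreted.
- Ceiling ties make permutation p-values conservative for saturated
  metrics (see above).
- The equal-posterior cutoff depends on the cohort composition used for
  fitting (the positive-component weight enters the boundary); cutoffs
  derived from differently enriched cohorts are not interchangeable.
- t-SNE stratification probabilities quantify sensitivity to embedding
  initialization only, not sampling uncertainty of the cohort.
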
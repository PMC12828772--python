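# Methods

## Deconvolution model

Each bulk sample is modeled as a convex mixture of cell-type-specific
expression profiles. With reference means `R` (signature genes × 7 cell
types, TPM scale), per-gene variability `v`, and a TPM bulk vector `b`, the
per-sample estimate solves

```
min_x  Σ_g w_g (b_g − Σ_c R_gc x_c)²,   w_g = 1/(v_g + 1e-6),
s.t.   x_c ≥ 0,  Σ_c x_c ≤ 1,
```

and reports `1 − Σ_c x_c` as the *uncharacterized* fraction — in prostate
tissue, predominantly malignant and benign epithelium absent from the
reference. The weights down-weight genes whose reference expression is
unstable, which is why the on-disk reference format carries a per-gene
variability column.

Numerics: the problem is a 7-variable convex QP. Active-set non-negative
least squares solves it exactly when the simplex inequality is slack; when
the NNLS total exceeds 1 the equality-constrained problem is solved by
SLSQP (ftol 1e-14) and refined by a KKT solve on the identified active
set, so solutions are exact to solver precision (verified against
exhaustive grid search at step 1e-3 on small systems, and to 1e-6 against
ground truth on noiseless mixtures). Inputs are rescaled to O(1) before
solving; proportions are scale-invariant. Genes absent from the bulk
matrix are dropped; a reference-gene overlap below 80% (configurable) is
an error, not a warning. FPKM/RPKM inputs are renormalized per sample to
TPM first, since the model compares within-sample relative abundances.
An optional per-cell-type mRNA-content scaling vector converts fitted mRNA
fractions into cell fractions (divide by the factor, renormalize); it
defaults to off (all ones).

## Subtype discovery

Compositions are standardized per component across samples (sample SD,
ddof 1); constant components map to zero and are flagged. Standardization
is feature-wise, not per sample: the clustering features and the
per-component enrichment scores that name the clusters both presuppose
component-wise comparability, and the same convention is reused for the
heterogeneity analysis so the two stages share one z-matrix. All 8
components (7 cell types + uncharacterized) are clustering features.

Consensus clustering: for each k in 2..6, draw `n_resamples` subsamples of
⌊0.8·n⌋ samples without replacement, cluster each with PAM (build phase +
best-improvement swap passes, Euclidean distance, lowest-index
tie-breaking for full determinism), and record for every sample pair the
fraction of co-samplings in which it co-clustered. Final labels per k cut
an average-linkage tree of `1 − consensus` at k clusters.

Model selection uses the area under the empirical CDF of off-diagonal
consensus values (computed exactly as `1 − mean(consensus)` for values
supported on [0,1]). The chosen k is the largest whose relative area
increase over k−1 is at least 0.1. Two degenerate cases return the
smallest k with a low-confidence flag: a flat profile, and a candidate
whose consensus matrix is mostly ambiguous (>50% of off-diagonal entries
in (0.1, 0.9)). The ambiguity guard matters because structureless data
dilutes mean consensus roughly like 1/k, which keeps nominal area gains
positive without ever producing the bimodal 0/1 consensus of real
clusters. A `fixed` policy (k = 3, the operative choice for this subtype
model) is available.

Cluster naming: per cluster, the mean z of {CD4, CD8 T cells} scores TCE,
{uncharacterized} scores EPCE, {CAFs, endothelial, macrophages} scores
TASCE; each name goes to its argmax cluster, with a greedy margin-ordered
fallback (and a logged warning) if two criteria point at one cluster.

## Classifier

Plain LDA: class means, pooled within-class covariance (divisor N − 3),
priors defaulting to empirical frequencies. The discriminant
`δ_c(x) = xᵀΣ⁻¹μ_c − ½μ_cᵀΣ⁻¹μ_c + log π_c` is exact for the
shared-covariance Gaussian model, and posteriors are its softmax. Because
the 8 features sum to one, the pooled covariance is singular; a ridge of
`1e-8 · trace/8` is added and recorded in the model for audit. Features
are raw proportions rather than z-scores: per-cohort standardization would
make cross-cohort prediction depend on each cohort's own statistics,
ill-defined for the train-on-one / validate-elsewhere design. Models
serialize to versioned JSON at full float precision.

## Multifocal heterogeneity

All C(n,2) sample pairs are classified intrafocal / interfocal /
interpatient from the sample map and scored by cosine similarity of their
z-scored composition rows (clamped to [−1,1] against floating-point
overshoot). The three pairwise comparisons use the two-sided Wilcoxon
rank-sum test (normal approximation with tie and continuity corrections),
reported unadjusted. Note these pairs are not independent — each sample
appears in many pairs — so the nominal test is anti-conservative; see
"Generator calibration" below for the consequences. Subtype concordance
reports, per patient and per focus with ≥2 samples, whether all samples
carry one subtype label.

## Outcome analysis

Cox models use Efron tie handling and Newton–Raphson maximization of the
partial likelihood (via lifelines), Wald 95% CIs and p-values, and
Harrell's concordance from the fitted linear predictor. Categorical
covariates are dummy-coded against declared reference levels (subtype TCE,
Gleason low, pT T2). Complete-case analysis drops subjects with missing
covariates, with a logged count. A covariate level with zero events has a
monotone partial likelihood and no finite MLE for its contrast; such terms
are flagged `non_identifiable` on the fit (boundary estimates and CIs are
still reported, as R's `coxph` does) and simulation studies exclude
flagged replicates. Coefficients above |20| on identifiable terms raise a
complete-separation error.

The proportional-hazards check correlates scaled Schoenfeld residuals with
the rank of event time (Grambsch–Therneau, per term); the global p-value
sums the per-term chi-squares with df = number of terms, an approximation
that treats terms as independent. Kaplan–Meier curves carry a per-point
truncation flag where the at-risk count falls below 5; the flag is for
rendering only and never affects the log-rank test, which is the k-group
chi-square on the full data.

The pipeline skips the survival stage when a cohort has fewer than 10
events (as with small multifocal cohorts, whose scarce relapses cannot
support the multivariable model).

## Synthetic-cohort generator

The generator provides ground truth for every stage. Per patient: a
subtype from the prior (default uniform over TCE/EPCE/TASCE) and a
composition from a subtype-specific Dirichlet over 8 components (7 cell
types + epithelial). Focus- and sample-level compositions derive by
additive Gaussian noise in centered-log-ratio space followed by softmax —
this keeps vectors positive and sum-one while giving tunable nested
variance (`sd_patient`, `sd_focus`, `sd_sample`, all in CLR units). Bulk
expression is the reference matrix augmented with an epithelial column
times the proportion vector, with per-gene multiplicative log-normal noise
(`noise_sd`, default 0.1), then TPM-renormalized.

The synthetic reference is block-structured: each cell type owns 30
signature genes (high own-mean 200–1000, cross-type leak 0–20, columns
TPM-scaled), plus 90 background genes expressed by none of the 7 types.
The epithelial profile is supported only on the background genes, making
it exactly orthogonal to the reference block, so the uncharacterized
fraction recovers the epithelial share exactly in the noiseless limit.
Real epithelium expresses immune-signature genes at low levels; this
idealization is what makes machine-precision recovery tests possible and
is the main respect in which passing tests overstate accuracy on real
tissue (alongside log-normal noise standing in for count noise, batch and
FFPE effects).

BCR times are exponential with rate `baseline_hazard × HR[subtype]`
(HR: TCE 1, EPCE 5.3, TASCE 10.9 — the univariable effect sizes of the
subtype model), censored independently at Uniform(0, 120 months). The
baseline hazard is solved analytically (Brent) so the expected event
fraction is 52/405 ≈ 12.8%, the cohort condition of the 405-patient
survival arm. Gleason and pT categories come from subtype-conditional
multinomials that enrich TASCE for high grade / advanced stage and TCE for
low grade / organ-confined disease. All randomness flows through one
seeded generator; a config fully determines the cohort.

### Generator calibration

Defaults were fixed by a design-time calibration study (before freezing):

* **Single-sample defaults** (`SimulationConfig()`): Dirichlet
  concentrations of total 200 per subtype, with mean compositions
  separated by ~2–4 within-subtype SDs in the planted directions (TCE
  ~22% T cells; EPCE ~85% epithelial; TASCE ~37% stroma), `sd_focus`
  0.15, `sd_sample` 0.08. Under these conditions consensus clustering at
  n=300 recovers the three subtypes with ARI 0.95–1.0 and the delta-area
  rule selects k=3. No quantitative between-subtype effect sizes are
  published; the calibration targets the qualitative orderings (enrichment
  directions, grade/stage trends, survival separation) only.
* **Multifocal defaults** (`simulate_multifocal_defaults()`): 23 patients,
  2–3 foci, 1–2 samples per focus (~86 samples). All subtypes share one
  pooled, highly concentrated Dirichlet and `sd_patient` is 0, so patient
  identity carries no compositional signal, while `sd_focus` (0.5)
  exceeds `sd_sample` (0.4). This is the regime the multifocal finding
  describes — similarity is much higher within a focus, with no detectable
  interfocal-vs-interpatient difference. It is also essentially forced:
  because pair similarities share samples, the rank-sum comparison of
  ~100 interfocal against ~3000 interpatient pairs is anti-conservative
  (measured rejection ≈35% under an exchangeable null at large
  `sd_focus`), and even a patient-level CLR jitter of 0.05 is "detected"
  through the induced pair correlation. With the chosen defaults the
  intrafocal contrast is significant in ~100% of seeds and the
  interfocal-interpatient comparison stays non-significant in ~88%.

## Design choices and limitations

* PAM is implemented in-repo (no installed k-medoids); Cox/KM/log-rank/
  Schoenfeld/concordance come from lifelines; rank-sum and chi-square
  tests from scipy. Tests check the in-repo implementations against
  independent oracles (grid search, exhaustive enumeration, brute-force
  Bayes rule, hand-coded partial likelihood and score statistic, sklearn's
  LDA).
* Whether the published classifier was trained on raw or z-scored
  proportions is not stated; raw is the default here (documented switch
  would be trivial, see "Classifier" for the rationale). Whether final
  cohort labels come from the consensus partition or a full-data PAM at
  k=3 is likewise unstated; the consensus partition is used.
* Gleason "a+b" strings map to three grades as: total ≥ 8 high, 4+3
  intermediate, all else low.
* The generator emulates mixture structure, not real TCGA gene-level
  distributions: no counts, no batch effects, no correlated gene modules
  beyond the cell-type blocks. Quantities that depend on the real cohorts
  (published hazard-ratio point estimates, concordance indices 0.677–0.76,
  tumor-purity correlations) are design anchors for the generator, not
  reproduced measurements.
* Problem sizes in tests and the acceptance script (300-sample subtyping
  cohorts, 50-seed/50-replicate studies, 250 consensus resamples) are the
  package's default desk-scale study conditions; all are configurable
  upward.
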
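# tmesubtypes

Cell-type-composition subtyping of bulk prostate-cancer RNA-seq.

Bulk tumor tissue is a mixture of malignant and benign epithelium, immune
cells and stroma. This package estimates, for each bulk RNA-seq sample, the
proportions of seven reference cell types (B cells, CD4+ and CD8+ T cells,
NK cells, macrophages, endothelial cells, cancer-associated fibroblasts)
plus an *uncharacterized* remainder (predominantly epithelium), and carries
that composition through a complete prognostic analysis:

1. **Deconvolution** — per sample, solve the constrained weighted least
   squares problem

   minimize Σ<sub>g</sub> w<sub>g</sub> (b<sub>g</sub> − Σ<sub>c</sub> R<sub>gc</sub> x<sub>c</sub>)²  subject to x<sub>c</sub> ≥ 0, Σ<sub>c</sub> x<sub>c</sub> ≤ 1,

   where *b* is the bulk TPM profile over signature genes, *R* the
   reference profile, and w<sub>g</sub> = 1/(variability<sub>g</sub> + ε);
   the slack 1 − Σ x<sub>c</sub> is the uncharacterized fraction.
2. **Subtype discovery** — z-score each composition component across
   samples, run resampling consensus clustering with PAM (partitioning
   around medoids) over k = 2..6, choose k from the consensus-CDF area
   profile, and name the three clusters **TCE** (T-cells enriched),
   **EPCE** (epithelial-cells enriched) and **TASCE**
   (tumor-associated-stromal-cells enriched) by their enriched components.
3. **Classification** — linear discriminant analysis on the 8 raw
   proportions (pooled covariance with a recorded ridge for the simplex
   degeneracy), serialized to JSON for cross-cohort prediction.
4. **Multifocal heterogeneity** — cosine similarity of z-scored
   compositions for every sample pair, classified intrafocal / interfocal /
   interpatient, compared with Wilcoxon rank-sum tests; subtype concordance
   per patient and per focus.
5. **Outcome analysis** — Kaplan–Meier and log-rank, univariable and
   multivariable Cox proportional-hazards models for time to biochemical
   recurrence (BCR) with subtype / Gleason-grade / pT-stage covariates
   (reference levels TCE / low / T2), Harrell's concordance index, and the
   Grambsch–Therneau proportional-hazards check.

A synthetic-cohort generator with full ground truth (planted subtypes,
nested patient/focus/sample composition variance, exponential BCR times
with subtype hazard ratios 5.3 and 10.9, subtype-correlated Gleason and pT
categories) backs every stage with recovery tests; see `docs/methods.md`
for the model and its calibration.

## Worked example

Discover subtypes on a simulated 300-patient cohort
(`examples/02_discover_subtypes.py`):

```python
import tmesubtypes as tms

reference = tms.generate_reference(seed=1)
cfg = tms.SimulationConfig(n_patients=300, seed=7)
expression, _, _, truth = tms.simulate_cohort(cfg, reference)

composition = tms.deconvolve_cohort(expression, reference)
z = tms.zscore(composition)
result = tms.consensus_cluster(z, k_range=(2, 6), n_resamples=250, seed=11)
k = tms.select_k(result)
naming = tms.assign_subtype_names(result.labels[3], z)
```

prints

```
chosen number of clusters: 3
ARI vs planted subtypes at k=3: 0.980
subtype sizes: {'TCE': 105, 'EPCE': 104, 'TASCE': 91}
```

— the consensus-CDF area profile supports exactly three clusters, the
partition agrees with the planted subtypes (adjusted Rand index 0.98), and
the enrichment table maps each cluster to its name. Continuing into the
survival arm (`examples/05_survival_analysis.py`, 405 patients, ~13% BCR
events):

```
log-rank chi2 = 44.13 (df 2), p = 2.61e-10

univariable hazard ratios vs TCE (planted: EPCE 5.3, TASCE 10.9):
subtype_EPCE    5.858   (1.311 - 26.174)   p=0.021
subtype_TASCE  20.669   (4.970 - 85.956)   p<0.001

concordance: gleason 0.571 -> gleason + subtype 0.767
```

— the three subtypes separate strongly in time-to-event, the fitted hazard
ratios bracket the planted effects (single-replicate estimates are noisy at
~50 events; the acceptance script averages 50 replicates), and adding the
subtype to a Gleason-only Cox model raises the concordance index.

The other examples cover deconvolution accuracy
(`01_simulate_and_deconvolve.py`), cross-cohort LDA classification
(`03_classify_new_cohort.py`) and multifocal heterogeneity
(`04_multifocal_heterogeneity.py`).

## Command line

The same stages are available as a thin CLI:

```
tmesub simulate --seed 5 --out cohort/
tmesub deconvolve --expression cohort/expression.tsv --reference cohort/reference.tsv --out composition.tsv
tmesub cluster --composition composition.tsv --k-range 2:6 --resamples 1000 --seed 11 --out clusters/
tmesub train / predict / heterogeneity / survival / associate ...
tmesub run --config pipeline.yaml --out results/
```

`tmesub run` executes everything from one YAML config and writes a
manifest with SHA-256 checksums; reruns with the same config and seed are
byte-identical.

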
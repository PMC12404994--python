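# ndproteo

Cross-disease plasma-proteomics analysis for neurodegenerative disease
(ND) cohorts. The package re-implements, as a tested and reusable Python
library, the analysis chain used to compare plasma proteomes of
Alzheimer's disease (AD), Parkinson's disease (PD) and frontotemporal
dementia (FTD) against cognitively normal controls on aptamer-based
(SomaScan-style) panels pooled from many contributor sites:

* **QC & harmonization** — log10 transform of relative fluorescence units
  (RFU), per-aptamer IQR-fence outlier masking within each processing
  group (pooled EDTA vs citrate site), two-pass call-rate filtering
  (65% / 85%), removal of non-human or unannotated aptamers, bootstrap
  imputation, group-wise z-scoring, and proteomic principal components.
* **Differential abundance** — per-aptamer OLS of
  `protein ~ status + age + sex + PC1 + PC2` with Benjamini–Hochberg FDR,
  plus tertile logistic odds ratios summarized by a symmetric mean OR
  (ORs < 1 inverted before averaging).
* **Cross-disease mapping** — overlap partitions of significant aptamers,
  pairwise effect-size correlation (r²) with a 95% prediction band and
  outlier flagging, and directional-concordance summaries.
* **Site sensitivity analyses** — per-site fits pooled by random-effects
  meta-analysis with REML estimation of the between-site variance τ²,
  joint models with site as a fixed or random intercept, and concordance
  reports between model variants.
* **Enrichment** — hypergeometric over-representation against a
  user-supplied GMT database; cell-type specificity labeling (a gene is
  specific to its top cell type when that expression is ≥ 1.5× every
  other cell type) with hypergeometric or Fisher's-exact enrichment.
* **Boolean regulatory networks** — STRING-style interaction tables
  filtered at combined score ≥ 0.7 over FDR-significant proteins
  (one lowest-FDR aptamer per protein), Booleanized states (1 =
  increased, 0 = decreased), genetic-algorithm reconstruction of edge
  orientation/sign under an inhibitor-dominant update rule, and
  perturbation scores that rank upstream regulators by how many
  downstream states flip when the regulator is inverted.
* **Biomarker panels** — r² > 0.8 correlation pruning, 50-iteration LASSO
  stability selection (penalty by 10-fold CV), top-10 panels,
  100-iteration class-balanced evaluation with ROC/AUC and Youden-cutoff
  metrics, cross-disease specificity testing, and leave-one-site-out
  cross-validation with site-wise z-scoring, train-only imputation and
  DeLong CIs.

Real consortium data of this kind are access-controlled, so the package
ships a first-class **synthetic cohort generator** (`ndproteo.cohort`)
that emulates the statistical structure the pipeline assumes — multi-site
offsets, citrate/EDTA processing groups, planted per-disease effects with
controllable cross-disease correlation, covariate slopes, MCAR
missingness, outlier spikes, and ground-truth regulatory networks — and
returns the ground truth alongside, so every stage can be validated
end-to-end.

## Worked example

```python
import ndproteo as nd

spec = nd.CohortSpec(
    n_per_group={"control": 300, "AD": 150, "PD": 100},
    n_sites=8, n_aptamers=800, frac_signal=0.08, effect_scale=0.5,
    site_offset_sd=0.15,
    shared_block_spec={("AD", "PD"): {"frac_shared": 0.5,
                                      "r2_target": 0.44}},
    missing_rate=0.03, outlier_rate=0.003, seed=42)
matrix, metadata, annotation, truth = nd.generate_cohort(spec)

z, pcs, report = nd.run_qc(matrix, annotation, nd.QCParams(seed=42))
print("QC:", report.masked_outlier_count, "outliers masked;",
      "final dims", report.final_dims)

tables = {}
for disease in ("AD", "PD"):
    tab = nd.fit_associations(z, metadata.loc[z.sample_ids],
                              ["age", "sex", "PC1", "PC2"], disease,
                              covariate_table=pcs)
    tables[disease] = tab
    print(f"{disease}: {(tab.q < 0.05).sum()} aptamers FDR-significant")

comp = nd.effect_size_correlation(tables["AD"], tables["PD"],
                                  selection_rule="union_significant")
print(f"AD-PD effect-size r^2 = {comp.r2:.2f} "
      f"({len(comp.outside_band)} aptamers outside the 95% band)")
overlap = nd.overlap_sets(tables)
shared = overlap["counts"].get(frozenset({"AD", "PD"}), 0)
print(f"{shared} of {overlap['union_size']} significant aptamers shared")
```

prints

```
QC: 4693 outliers masked; final dims (550, 800)
AD: 39 aptamers FDR-significant
PD: 29 aptamers FDR-significant
AD-PD effect-size r^2 = 0.11 (1 aptamers outside the 95% band)
10 of 58 significant aptamers shared
```

Reading the output: QC masked ~1% of measurements as IQR outliers and
kept all 550 samples and 800 aptamers; each disease contrast recovers a
few dozen of its planted signal aptamers at FDR < 0.05; the pairwise
effect-size r² over the union of significant aptamers is 0.11 — lower
than the 0.44 planted within the *shared* block because half of each
disease's signal is disease-specific by construction, which dilutes the
union-level correlation exactly as disease-specific biology does in real
cohorts.

The same stages are scriptable from a shell:

```bash
ndproteo simulate --config cohort.yaml --out cohort/ --seed 42
ndproteo qc --in cohort/ --out qc/ --seed 42
ndproteo assoc --in cohort/ --qc-dir qc/ --contrast AD --out assoc_AD.tsv
ndproteo run-all --out run/ --seed 42        # the full pipeline
```

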
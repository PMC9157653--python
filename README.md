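# solgs

Genomic selection (GS) of morphometric and colorimetric fruit traits in
Solanaceous crop panels: a reusable, tested pipeline for predicting the
genetic merit of unseen accessions from genome-wide SNP dosages.

The package is aimed at plant-breeding and quantitative-genetics work on
panels of a cultivated crop (tomato, pepper, eggplant) accompanied by small
groups of divergent wild relatives. It covers the full analysis chain:

- **`genotypes`** — VCF/dosage I/O, missingness and minor-allele-frequency
  filters, modal imputation, LD pruning at r² ≥ 0.999, greedy LD-based
  tag-SNP selection with importance-ranked nested subsets, and PCA for
  population structure.
- **`phenotypes`** — trial-level linear mixed models
  `y_ij = μ + g_i + t_j + e_ij` fitted by EM-REML; variance components,
  broad-sense heritability `H² = σ²_g / (σ²_g + σ²_t + σ²_e)`, and
  per-accession genetic values `μ̂ + BLUP(g_i)` used as GS responses.
- **`gs_core`** — single-trait ridge-regression BLUP (`y = 1b + Zu + e`,
  `u ~ N(0, σ²_u I)`): spectral REML for the ridge ratio
  `λ = σ²_e/σ²_u`, marker effects via the kernel identity
  `û = Z_c'(Z_c Z_c' + λI)⁻¹(y − b̂1)`, and GBLUP-equivalent prediction.
- **`gs_multi`** — multivariate kernel mixed model
  (`cov(g) = Σ_g ⊗ K`, `cov(e) = Σ_e ⊗ I`) fitted by EM-REML on error
  contrasts, with Rv-coefficient evaluation of multi-trait predictions.
- **`gs_class`** — random-forest and RBF-SVC classification of ordinal
  descriptor traits with SMOTE class balancing and 15 × 15 hyperparameter
  grids selected by inner cross-validated accuracy.
- **`evaluate`** — repeated 5-fold × 30-repetition cross-validation (150
  sets), Pearson/Spearman/top-30%/top-15% and accuracy/AUC metrics,
  rank-quantile mapping of regression predictions onto descriptor classes,
  cultivated→wild transfer scenarios, and paired t-tests between models.
- **`simdata`** — a synthetic-data generator (structured genotypes with
  calibrated LD, Balding–Nichols wild-group differentiation, and
  heritability-controlled polygenic traits with trial/replicate structure)
  used throughout the test suite; see `docs/methods.md`.

## Worked example

Simulate a tomato-like panel, run QC, fit the trial mixed model and assess
genomic predictability in repeated cross-validation:

```python
import numpy as np
from solgs import simdata, genotypes as gt, phenotypes, evaluate as ev

spec = simdata.PopulationSpec(n_snps=3000, seed=7)
G = simdata.simulate_genotypes(spec)          # 180 accessions (34 wild)
G = gt.filter_missingness(G, 0.5)
G = gt.impute_missing(G)
G = gt.filter_maf(G, 0.05)
G = gt.prune_redundant(G, 0.999)              # 2609 SNPs survive QC

tbl, truth = simdata.simulate_trait(
    G, simdata.TraitSpec(n_qtl=200, h2=0.8, seed=8), trait_name="fruit_area")
s = phenotypes.fit_trial_lmm(phenotypes.trial_means(tbl, "fruit_area"),
                             trait="fruit_area")
print(f"var_g={s.var_g:.3f} var_t={s.var_t:.3f} var_e={s.var_e:.3f} "
      f"H2={s.h2:.3f}")

cult = G.take_accessions(np.flatnonzero(~G.meta["is_wild"].to_numpy()))
y = s.genetic_value.loc[list(cult.accession_ids)].to_numpy()
scheme = ev.make_cv_folds(cult.accession_ids, 5, 30, seed=9)
report = ev.run_cv_regression(cult.dosage.astype(float), y, scheme,
                              trait="fruit_area")
print(report.summary().round(3))
```

Output:

```
var_g=0.806 var_t=0.084 var_e=0.019 H2=0.887
              mean     sd
pearson      0.686  0.093
spearman     0.668  0.098
top30_match  0.646  0.109
top15_match  0.569  0.168
```

The variance components say most phenotypic variance on the replicate-mean
scale is genetic (`H² ≈ 0.89`, the trait was simulated at single-observation
h² = 0.8 with 8 replicates per trial). The cross-validation summary is the
predictability of rrBLUP over 150 held-out sets: a mean Pearson correlation
of 0.69 between predicted and measured genetic values, and 65% / 57% of the
top-30% / top-15% accessions correctly recovered — the numbers a breeder
would use to decide whether marker-based selection is worth it for this
trait.

The same stack is scriptable from the shell (`solgs simulate`, `solgs qc`,
`solgs tags`, `solgs blup`, `solgs gs-single`, `solgs evaluate`,
`solgs scenarios`, or `solgs run-all --config pipeline.yaml`).

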
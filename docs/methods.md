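# Methods

`solgs` implements a genomic-selection (GS) analysis stack for panels of a
cultivated crop plus small, divergent wild relatives: genotype quality
control and tag-SNP selection, trial-level BLUP phenotypes, single- and
multi-trait ridge-regression BLUP prediction, classification of ordinal
descriptor traits, and a repeated cross-validation / population-transfer
evaluation framework. A synthetic-data module generates panels with the
relevant structure so the entire stack can be exercised and validated end to
end. This note records the models, the parameters that matter, and the
design choices made where the design was genuinely open.

## Phenotype model and heritability

Continuous traits are observed as replicates within trials. Replicates are
averaged per (accession, trial) cell and the cell means are fitted with the
two-random-effect linear mixed model

    y_ij = mu + g_i + t_j + e_ij,

mu fixed, genotype g ~ N(0, sigma_g^2) and trial t ~ N(0, sigma_t^2)
independent. Variance components are estimated by EM-REML on Henderson's
mixed-model equations (relative tolerance 1e-8, at most 500 iterations;
components floored at 1e-10 of the phenotypic variance; the restricted
likelihood is non-decreasing across iterations and can be monitored with
`phenotypes.restricted_loglik`). Unbalanced tables are handled natively; no
cells are dropped. The GS response ("genetic value") is mu_hat + BLUP(g_i).

Heritability is reported as sigma_g^2 over the sum of all three fitted
components. Whether the trial component belongs in the denominator is a
convention choice; the flag `include_trial_in_h2=False` switches to
sigma_g^2 / (sigma_g^2 + sigma_e^2). Note the estimates live on the
replicate-mean scale: averaging r replicates divides the residual component
by r, so this broad-sense figure exceeds the single-observation
heritability whenever r > 1.

Ordinal descriptor traits (scored into 3–10 categories) bypass the Gaussian
model; their per-accession summary is the modal label across records, ties
resolved to the lower category.

## Single-trait rrBLUP

The core prediction model is y = 1b + Zu + e with independent marker
effects u ~ N(0, sigma_u^2 I) — ridge-regression BLUP. Markers are centered
by training-set means and not variance-scaled (the common-effect-variance
assumption refers to the dosage scale). The fixed design is the intercept
only. The variance ratio delta = sigma_e^2/sigma_u^2 is estimated by
restricted maximum likelihood in the kernel form: the marker kernel
Zc Zc' is projected onto error contrasts (Helmert basis orthogonal to the
intercept) and eigendecomposed once; the profiled restricted likelihood is
then a scalar function of delta, maximized by bounded search over
log delta in [log 1e-6, log 1e6] (absolute tolerance 1e-12, interior optima
polished by a gradient root-find so the estimate is invariant to kernel
rescaling at machine precision). Optima at the search boundary are reported
with a warning as boundary fits. Marker effects follow from the kernel
identity u_hat = Zc'(Zc Zc' + delta I)^-1 (y - b_hat 1), the dual of the
dense ridge solve; the equivalence of the two forms, and of the
kinship-form GBLUP predictions, is asserted by tests. Genomic heritability
is reported as sigma_u^2 c / (sigma_u^2 c + sigma_e^2) with c the mean
diagonal of the training kernel.

## Multi-trait model

For a group of t traits the kernel-parameterized multivariate mixed model
is vec(Y) = (I kron 1)B + g + e with cov(g) = Sigma_g kron K and
cov(e) = Sigma_e kron I, K the genomic relationship matrix. Estimation is
EM-REML on error contrasts: after projecting out the intercept and rotating
by the eigenvectors of the projected kernel, rows are independent t-variate
Gaussians with covariance d_i Sigma_g + Sigma_e; the E-step conditions each
row in closed form and the M-step averages expected cross-products
(convergence when the largest relative covariance change drops below 1e-6,
at most 500 iterations; near-singular estimates are ridge-stabilized by
1e-8 trace/t). EM approaches such optima slowly; fits regularly stop at the
iteration cap with relative changes around 1e-5, which is far below any
downstream tolerance, and the cap is reported by warning. With t = 1 the
model delegates to the exact univariate spectral REML, so the single-trait
collapse reproduces rrBLUP predictions to ~1e-8.

Prediction of unseen accessions uses the conditional-mean identity
G_test = K_cross K_train^+ G_blup applied per trait, with K_cross built on
training-mean-centered markers. Multi-trait prediction matrices are
compared with observed ones by the Rv coefficient
trace(XX'YY') / sqrt(trace((XX')^2) trace((YY')^2)). The seven trait-group
presets (four pairs: fruit size, width/height, external shape indices,
pericarp; three triples: RGB color, CIELab color, height profile) are in
`gs_multi.TRAIT_GROUP_PRESETS`; arbitrary groups are accepted.

## Classification of descriptor traits

Ordinal descriptors are predicted as nominal classes from marker dosages by
either a random forest (1000 trees, floor(sqrt(p)) split candidates) or an
RBF-kernel SVC whose cost and kernel width are chosen from 15 x 15 grids by
inner cross-validated accuracy. The grids are unspecified upstream
conventions; defaults are 15 log-spaced costs in [1e-2, 1e3] and 15
log-spaced widths around the median-heuristic kernel width, both
configurable. Class imbalance is addressed by SMOTE (interpolation between
a minority sample and one of its k = 5 nearest same-class neighbors;
singleton classes fall back to duplication with a warning), applied
strictly inside training folds. Class scores are row-stochastic: vote
fractions for the forest, softmax-normalized one-vs-rest margins for the
SVC (rank-preserving per class, so AUC is unaffected); predicted labels are
always the score argmax. Marker input defaults to the 25% tag-SNP subset.

## Evaluation framework

Predictability is assessed by repeated k-fold cross-validation, default
5 folds x 30 repetitions = 150 sets, with seeded per-repetition
permutations and round-robin fold assignment (fold sizes differ by at most
one). Regression metrics per set: Pearson and Spearman correlation and the
matched rate of the top 30%/15% accessions (|top-s predicted intersect
top-s observed| / s, s = ceil(fraction n), ranking ties broken by accession
order). Classification metrics: accuracy and ROC AUC (binary rank-based;
multiclass macro-averaged one-vs-rest, a reduction the upstream convention
leaves unstated). Correlations of constant vectors are recorded as missing
and excluded from summaries with a logged count rather than zero-filled.
Regression predictions are made comparable with classification by
rank-quantile mapping onto the descriptor's class proportions. Paired
two-sided t-tests compare per-set metrics between models; raw p-values are
emitted without multiple-testing correction.

Everything fitted within a set — marker centering, REML, SMOTE,
hyperparameter grids — sees training folds only; an instrumentation hook
(`fold_callback`) lets tests assert this.

Transfer scenarios: `baseline_transfer` trains on all cultivated and tests
on all wild accessions (one split); `wild_augment` adds n_wild wild
accessions to training (at least one per wild species when stratified) and
tests on the remaining wilds; `wild_balanced` trains on equal cultivated
and wild counts. Draw-based scenarios redraw independently per set (the
alternative, reusing one draw across folds, is ambiguous upstream;
independent redraws give honest between-draw variance).

## Synthetic data

The generator emulates a tGBS-style panel: 146 cultivated accessions plus
seven small divergent wild species groups (34 accessions; sizes avoid
singleton species so stratified transfer scenarios keep every species
represented in both training and test), 10^4 SNPs on 12 chromosomes by
default.

Genotypes. Ancestral allele frequencies vary smoothly along each chromosome
(markers in strong LD necessarily carry similar frequencies; independent
frequencies would cap attainable r2 far below one through the binary
max-correlation bound). Wild-group frequencies follow the Balding–Nichols
construction — Beta marginals around the ancestral frequency with
dispersion set by `fst_wild` — driven by a chromosome-smooth latent uniform
so group deviations are coherent along chromosomes; the cultivated group
uses ancestral frequencies directly, reproducing the "cultivated core plus
scattered wilds" PCA geometry. Haplotypes are thresholded latent AR(1)
Gaussian processes; the AR coefficient is calibrated through the arcsine
(tetrachoric) relation so that `ld_rho` is the target adjacent-SNP dosage
r2 for common variants (the scale tagging operates on), decaying
geometrically with marker distance. Each wild group couples a random site
subset (probability `ld_phase_divergence`, default 0.5) to its latent chain
with flipped sign: allele frequencies, Fst and within-group LD are
untouched, but local LD phase differs between species, which is what makes
cultivated-trained marker effects transfer poorly to wilds — without it,
transfer is nearly lossless and the population-transfer contrast cannot be
reproduced. Per-SNP missing-call rates are drawn from a right-skewed Beta
(alpha = 0.4, mean `missing_rate`, default 0.1): most SNPs are nearly
complete while a small tail exceeds the 50%-missingness QC threshold, as in
real GBS data.

Phenotypes. A trait samples `n_qtl` causal SNPs with standard-normal
effects; the genetic score is standardized and scaled by sqrt(h2), and
trial/residual draws are rescaled to their exact target variances
(partitioned by `trial_var_frac`), so the realized variance composition
matches the request. At h2 = 0 the returned truth keeps the unit-variance
latent genetic score (the phenotype itself carries no genetic signal), so
null-association checks remain well defined. Multi-trait simulation draws
per-locus effect vectors with a requested genetic correlation matrix over
shared causal loci; a 1x1 matrix reduces exactly to the single-trait path.
Trait architecture (QTL count, effect distribution) is a free parameter of
the generator, not an estimate of any real crop.

Categorical descriptors are derived from continuous values by rank
quantiles with floor/largest-remainder class counts; tied values share the
lowest label in the tie group, so a constant vector lands in the first
class, and the mapping is invariant to strictly increasing transforms.

What the generator does not emulate: coalescent genealogies and
recombination maps, selection and domestication sweeps, dominance and
epistasis, genotype-by-environment interaction, and LD-aware imputation
errors. Passing tests therefore validate the estimators and the evaluation
machinery under a controlled, stylized population model — not GS
performance on any particular real crop.

## Known limitations and numerical notes

- Modal imputation (the stand-in for haplotype-based imputation) attenuates
  between-marker r2 on imputed entries. On the default panel with 10% mean
  missingness the tag-SNP fraction at r2 >= 0.8 is roughly 65%, versus
  roughly 25% on complete data; panels imputed with an LD-aware method
  would tag far more aggressively. The 0.8 tagging threshold itself is a
  configurable default (the upstream threshold is unstated).
- Tag-SNP selection is pairwise greedy maximum coverage inside a
  100-SNP positional window (full pairwise r2 is quadratic and unnecessary
  under local LD); multi-marker tagging rules are out of scope. Ranked tags
  interleave per-chromosome selection orders so any prefix is genome-wide
  representative, and subsets over fractions are nested by construction.
- LD pruning at r2 >= 0.999 removes near-duplicates left-to-right within
  the same window.
- The null (h2 = 0) cross-validated predictability concentrates near zero
  only when the kinship spectrum is not dominated by a few components;
  panels with very strong LD and few effective segments show realization
  noise of ±0.1–0.2 in the fold-mean correlation for a single trait draw.
  Validation of the null therefore uses a moderate-LD panel (ld_rho = 0.5,
  300 accessions, 2000 SNPs).
- Analyses in tests and in the acceptance script run at reduced problem
  sizes (2,000–6,000 SNPs, 150–300 accessions) chosen so the full stack,
  including 150-set cross-validations and 1000-tree forests, completes in
  minutes; all qualitative contrasts are stable at these sizes.
- In transfer analyses the causal loci are treated as untyped (trait
  simulated on one half of the sites, markers are the other half), as in
  real GBS panels where causal variants are tagged through LD only;
  transfer conditions use interspecific divergence (fst_wild = 0.7).
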
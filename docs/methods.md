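# Methods

This note records the statistical models behind `cwgcna`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions that matter for reproducing results.

## Co-expression network and modules

Features (genes, methylation loci compressed to genes, miRNAs) are
standardized per row and correlated with Pearson's r. The adjacency is the
soft-thresholded correlation, `a_ij = |r_ij|^beta` (unsigned, the default) or
`((1+r_ij)/2)^beta` (signed). `beta` is chosen as the smallest integer for
which the degree distribution approximates scale-free topology: node
connectivities `k_i = sum_j a_ij` are binned into 10 equal-width bins on
`log10 k`, and the R^2 of the regression of `log10 p(k)` on `log10 k` must
reach `r2_cut` (default 0.8). A fit with a positive slope, or with fewer than
3 non-empty bins (degenerate degree distributions, e.g. duplicated blocks),
reports R^2 = 0 so that NaNs never propagate. When no candidate power
qualifies the argmax-R^2 power is used with a warning.

The topological overlap matrix blends direct adjacency with shared
neighbourhoods:

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu * a_uj,  TOM_ii = 1.

Features are clustered by average-linkage hierarchical clustering on
`1 - TOM` and the tree is cut at a fixed absolute height (default 0.9, the
classical static-cut convention). A quantile-of-merge-heights cut was
considered and rejected: on planted two-block data the lower quantiles of
the merge-height distribution sit *below* the height at which blocks
coalesce, so such a cut fragments true modules into unassigned features.
Clusters smaller than `min_size` (default 30) become ME0; survivors are
renamed ME1..MEk by decreasing size with ties broken by the
lexicographically smallest member, making labels independent of feature
input order. Note that the appropriate cut height grows with the fraction of
noise features (they dilate TOM denominators); the 2000-feature pipeline
example uses 0.99.

The module eigengene is the first right singular vector of the module's
standardized feature submatrix — equivalently PC1 across samples — scaled to
unit variance (sd with one delta degree of freedom) and sign-aligned to
correlate positively with the module's mean standardized profile.
`variance_explained = sigma_1^2 / sum_k sigma_k^2`.

## Confounder screening (type-III ANOVA)

For each of the `top_n` (default 10 000) most variable features one linear
model with *all* phenotype variables as predictors is fitted. Categorical
predictors are sum-to-zero coded — type-III (marginal) sums of squares are
only meaningful under effects coding. Each variable's SS is the SSR increase
when its columns are dropped from the full model; MSS, F and p are averaged
over features, giving a dataset-level ranking of which phenotype variables
(group, gestational week, fetal sex, ...) explain variance and therefore
need adjustment downstream. Aliased (collinear) variable pairs are reported
by name and refuse to fit.

## Moderated differential testing

Module eigengenes, and features within each differential module, are tested
with per-unit OLS on the design `[intercept, group, confounders]` plus
empirical-Bayes variance moderation: residual variances `s_g^2` with d
degrees of freedom are assumed to follow a scaled inverse-chi-square prior
`(s_0^2, d_0)`, estimated by matching the first two moments of `log s^2`
(the trigamma inversion solved by Newton iteration). The moderated variance
is `(d_0 s_0^2 + d s^2) / (d_0 + d)` and the moderated t has `d_0 + d`
degrees of freedom. When the observed `log s^2` dispersion is at or below
the chi-square sampling floor, `d_0 = infinity` (fully pooled variance,
normal reference distribution). The implementation reproduces Bioconductor
limma's eBayes to ~1e-10 on shared fixtures (tested through Rscript).
Benjamini-Hochberg correction is applied across modules for the eigengene
test and within each module for the feature-level test; the within-module
family matches the per-module reporting of the downstream mediation screen.

## Two-direction mediation with IPW

For every group-differential feature M of a differential module, two
product-method mediation models are fitted:

* forward, module -> feature -> phenotype: exposure E = eigengene,
  mediator = M, outcome Y = group;
* reverse, phenotype -> feature -> module: E = group, Y = eigengene.

Path a is the weighted regression `M ~ E`; path b is the coefficient of M in
the weighted regression `Y ~ M + E` (weighted logistic when Y is the binary
group); the indirect effect is `a*b`. Measured confounders enter via
stabilized inverse-probability weights on the exposure: a logistic
propensity for the binary group, a Gaussian generalized propensity (linear
mean, homoscedastic) for the continuous eigengene; weights are truncated at
the 1st/99th percentiles. Significance comes from a nonparametric bootstrap
(default 500 resamples for single tests; weights re-estimated inside every
resample) with percentile CIs and the add-one two-sided sign-crossing
p-value `2*min(r_le+1, r_ge+1)/(B+1)`. A bootstrap p can therefore never be
smaller than `2/(B+1)`: within a module screen BH-corrected across ~F
features, B must exceed roughly `40*F` for a lone true positive to reach
p_adj < 0.05, so the module screen defaults to B = 1000.

Labels: a feature significant (BH within direction) only forward is a
*driver*, only reverse a *passenger*, both *ambiguous*, neither *none*.

Two screen-level defaults differ from the single-test primitive, both forced
by the composition of the eigengene from the tested features themselves:

* the reverse-direction *outcome* eigengene is recomputed without the tested
  feature (leave-one-out). Otherwise the feature's own loading guarantees a
  mediator-outcome association and every upstream feature is labelled
  ambiguous. The forward-direction *exposure* eigengene keeps all members:
  there the mediator's contribution legitimately belongs to the module
  summary, and excluding it turns the eigengene into an errors-in-variables
  proxy whose attenuation leaks the mediator's factor content into the
  forward b-path, faking forward signal for downstream features.
* the screen is doubly robust (confounders also enter the path models as
  covariates). Exposure IPW alone cannot remove mediator-outcome
  confounding: a confounder loading on module members sits inside the
  eigengene, and conditioning on the group in the reverse b-path opens a
  collider path to the mediator. This was measured as a systematic reverse
  bias (z ~ -1.7) under IPW-only adjustment.

The single-test primitive keeps IPW-only adjustment as its default so the
effect of weighting can be studied in isolation (the confounding calibration
study contrasts `use_ipw` on/off); logistic-outcome indirect effects are on
the `a * b_logit` product scale and are not transformed to risk differences.

## Network-aware gene-set annotation

Each within-module gene pair (edge; weight = TOM by default, adjacency
optional; complete within-module graph at `min_weight = 0`) inherits the
*intersection* of its two genes' term sets. A term's observed score is the
sum of its edges' weights. The shuffle test permutes the weight vector over
all module edges (term assignments fixed) 1000 times by default; the
empirical upper-tail p uses the add-one correction (so p >= 1/(n+1) and the
total edge weight is conserved by construction). The hypergeometric variant
counts module edges carrying the term against a background edge population
(default: the union of all modules' within-module edges — a configurable
convention). Gene-level hypergeometric over-representation is provided for
comparison with node-only enrichment. BH across terms in all three.

## Multi-omics clustering

Omics are feature-standardized, then folded into one samples x components
matrix. The CCA route computes, per omic pair, the SVD of the
cross-covariance of the centered blocks (computed in sample space via thin
SVDs, so feature counts far beyond n stay cheap), i.e. diagonally
regularized CCA / PLS-SVD, and reports the variate pairs ordered by
empirical correlation. Fully whitened CCA was implemented first and
rejected: with p >= n both blocks' whitened scores span the same
(n-1)-dimensional sample space, every canonical correlation equals 1 and
the directions are arbitrary — the planted shared structure was
unrecoverable (ARI ~ 0). The fold is left to right over the user-supplied
omic order (non-commutative; the order is part of the analysis definition);
a single omic degenerates to PCA scores. Merged columns are standardized,
which deliberately equalizes component scales; with the conventional
`n_cc = 30` most columns are noise when n is small, so for ~100-200 samples
`n_cc` of ~10 concentrates signal (the clustering examples use 10).

k-means (25 restarts, seeded) is run per candidate k; the chosen k is the
2-of-3 vote of max Silhouette, max Calinski-Harabasz and min Davies-Bouldin,
with Silhouette breaking three-way disagreement; a k yielding empty or
singleton clusters is retried up to 5 times and then marked invalid. The
WGCNA route replaces CCA by per-omic module eigengenes, concatenated and
standardized.

## Imbalance-aware ensemble classification

Per omic: one-way ANOVA screen against the class labels (p < 0.05,
deliberately unadjusted — a permissive pre-filter), then base training sets
by mode: (1) bagging-SMOTE — 10 sets, each class bootstrapped at its own
size and minority classes topped up to the majority size with SMOTE (k = 5
minority neighbours, uniform interpolation on the segment, applied after
the bootstrap draw and never to evaluation data); (2) 10 plain bootstraps;
(3) the original data once. Elastic-net logistic regression (mixing 0.5,
penalty strength by internal 3-fold CV over {0.05, 0.5, 5}) selects
features per base set; features selected in >= 50% of base sets form the
recurrent set (mode 3: the single fit's selection; an empty recurrent set
falls back to the 50 smallest screen p-values with a warning). One base
learner per base set — linear-kernel SVM with probability outputs, or
multinomial logistic regression — is trained on the recurrent features.
Omic-level probabilities average over base learners; multi-omic predictions
average omic-level probability vectors (soft voting at both levels) and take
the argmax. Prediction aligns features by name and is deterministic given
the fitted model.

## Synthetic data

Block-correlated expression uses the factor construction
`x = sqrt(rho) f + sqrt(1-rho) eps` with a block factor `f ~ N(0,1)`, giving
exact target within-block correlation rho.

The mediation scenario plants a structurally identifiable graph (defaults:
n = 300 samples; 1 driver, 20 passengers, 30 null module features; one
standard-normal confounder):

* driver: `M_d = 0.8 u + 0.6 eps` on its own latent u; the group is
  `Bern(expit(1.5 M_d + 0.8 C))`;
* module factor: `f = delta G + eta`, `delta = 2` (the module's group
  separation, chosen to represent a clearly disease-coupled module);
* passengers: `lambda f + noise` with `lambda = shift/delta = 0.3`, giving
  unit variance and a 0.6-sd group difference per passenger;
* nulls: confounder-loaded noise (`0.3 C + noise`) — associated with the
  group only through C, which the differential stage removes by adjustment.

Under this graph "driver" and "passenger" correspond to exact conditional
independencies (`M_d` independent of f given G; passengers independent of G
given f), not to power accidents. An earlier design in which the driver also
loaded on the module factor was rejected: the reverse b-path
(eigengene ~ driver | group) is then structurally nonzero and every driver
is necessarily ambiguous. What the generators do *not* emulate: bounded beta
values and their heteroscedasticity (logit-normal tails), count noise for
RNA/miRNA, batch structure, correlated confounders, or modules with mixed
effect signs — so passing recovery tests demonstrates correctness of the
inferential machinery under the stated model, not robustness to real-data
pathologies.

Multi-omic clusters shift a subset of features per omic by cluster-specific
means drawn `N(0, (sep/sqrt 2)^2)` over unit noise; imbalanced classes shift
10 of 150 informative features by 0.5 sd between classes (400 vs 40
samples), an overlap regime where the Bayes error is substantial and
majority-vote collapse is the failure mode the bagging-SMOTE mode is meant
to fix.

## Numerical conventions

* Standardization uses sample sd (ddof = 1) throughout.
* Written tables carry a `# cwgcna v<version> seed=<seed>` header and fix
  floats to 10 significant digits, so identical runs are byte-identical.
* Logistic fits use Newton-Raphson with eta clipped at +-30; coefficients
  beyond 25 in absolute value raise a separation error (propensity models)
  or mark the resample as failed (bootstrap); a screen result is flagged
  unstable when >20% of resamples fail.
* BH adjustment is the standard step-up with monotonicity enforcement.
* k-means uses 25 restarts per candidate k with seeds drawn from the
  user-provided seed.

## Problem sizes used by the shipped checks

Simulation-based checks run at the sizes stated in their docstrings —
mediation calibration at 500 null replicates (n = 300, 300 bootstrap
resamples), confounding contrast at 200 replicates, recovery at 20 seeds,
the determinism run at 2000 features x 120 samples — chosen so the whole
suite completes on a single CPU in well under half an hour while keeping
Monte-Carlo error far below the asserted margins.

## Known limitations

* Static tree cut only; dynamic hybrid cutting is not implemented, so very
  large noise fractions require raising the cut height.
* Mediation treats one mediator at a time; exposure-mediator interactions,
  joint multi-mediator models and unmeasured-confounding sensitivity
  analyses are out of scope.
* The logistic-outcome indirect effect is a coefficient product, not a
  risk-difference decomposition.
* CCA merging is the diagonally regularized (PLS) limit; a partially
  whitened variant between the two extremes is not exposed.
* probes-to-genes compression averages all mapped probes equally; no
  promoter/body weighting.
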
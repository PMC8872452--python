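# Methods

## Model and procedure

`rvprior` addresses gene-based rare-variant association scans: `m` gene-level
hypotheses with p-values `p_1..p_m`, each carrying a covariate `X_i` that is
independent of `p_i` under the null but informative of the prior probability
that gene `i` is truly associated. The covariate is built in two supervised
stages and consumed in a third, weighted multiple-testing stage.

### Stage 1 — training labels

Input is a candidate table: genes grouped by GWAS locus, each with a
posterior probability of being that locus' risk gene (produced upstream by
an integrative prioritization tool; `rvprior` consumes the posteriors, it
does not compute them). Per locus, the argmax-posterior gene is a positive
training instance; genes whose posteriors fall strictly below the median
posterior over **all** candidate entries are negatives, minus any gene that
is positive somewhere. Choices where the rule is underdetermined:

* ties at a locus maximum go to the lexicographically smallest gene ID, so
  the labeling is deterministic and input-order invariant;
* the median is taken over all candidate entries, positives included; with
  an even count it is the mean of the two central values;
* genes exactly at the median stay unlabeled;
* a gene occurring in several loci is labeled from its best showing: it is
  positive if it tops any locus, and negative only if all its entries fall
  below the median.

### Stage 2 — genome-wide risk scores

Per feature source, a genes × features numeric matrix is reduced to a score
per gene by a repeat-downsampled random forest:

* each of `n_repeats` (default 100) repeats downsamples negatives, without
  replacement, to the number of positives — the raw label set is heavily
  imbalanced because each locus contributes one positive and several
  negatives;
* within a repeat the balanced set is split into `n_cv_folds` (default 3)
  stratified folds; the number of features tried per split
  (`sqrt`, 1/3 or 1/2 of the feature count) is chosen by mean held-out AUC,
  and the winning setting is refit on the whole balanced set;
* the refit forest (default 3,000 trees) scores every gene in the matrix as
  a class probability; the per-source score is the mean over repeats.
  Held-out AUCs are reported per repeat; training genes are scored by the
  refit model like any other gene, and the repeat averaging attenuates the
  resulting optimism. Reported performance always comes from held-out folds
  only.
* missing feature values are imputed with per-feature medians learned on the
  training genes only; gene IDs are matched as exact strings after
  upper-casing and whitespace stripping (no identifier-mapping service);
* seeding: a master seed spawns one independent child stream per repeat, so
  repeats are reproducible and order-independent.

Single-cell sources are first reduced to one column per cell type/state by
per-gene averaging over each type's cells. Per-source genome-wide scores
are min-max normalized — a constant score vector maps to all 0.5, the
uninformative midpoint, so a degenerate source neither dominates nor
vanishes — and averaged per gene over the sources that cover it, giving the
ensemble score in [0, 1]. Genes covered by no source get no ensemble score
and are flagged.

### Stage 3 — cross-weighted hypothesis weighting

Plain BH rejects `H_(i)` for the largest `k*` with
`p_(k) ≤ k·α/m`. The weighted procedure replaces `p_i` by
`p_i / Ŵ(X_i^{−l})` and applies one common BH pass:

1. **Strata.** Hypotheses are quantile-binned on the covariate into
   `n_bins` strata of near-equal size (ties broken by stable rank; sizes
   differ by ≤ 1). `auto` chooses `max(1, min(10, ⌊m/1500⌋))`: about 1,500
   hypotheses per stratum keep per-stratum weight estimates stable at
   genome scale (≈19k genes → 10 strata). A constant covariate, or `m` too
   small for `n_bins × n_folds`, collapses to a single stratum, which makes
   the procedure exactly BH.
2. **Folds.** Within each stratum, hypotheses are randomly split into
   `n_folds` (default 5) folds with a seeded generator.
3. **Weight learning.** For fold `l`, one weight per stratum is learned
   from the other folds' p-values only: candidate raw masses per stratum
   from `{0, 0.25, 0.5, 1, 2, 4}` are rescaled to the budget
   `Σ_g n_g w_g = Σ_g n_g` and scored by the number of weighted-BH
   rejections of the training p-values at level α. Exact ties go to the
   vector closest to uniform in squared distance. The search is exhaustive
   for ≤ 5 strata and coordinate ascent with 3 random restarts above that.
   An optional total-variation bound `Σ_g |w_{g+1} − w_g| ≤ λ` can exclude
   rough weight vectors; it is off by default. The transparent grid keeps
   the learned rule auditable against an exhaustive oracle, at some cost in
   resolution compared to continuous optimizers.
4. **Budget and decision.** The learned vector is rescaled so the mean
   weight over the held-out fold's hypotheses is exactly 1 — the rescaling
   uses the fold's stratum counts only (covariate information), never its
   p-values, so the weight applied to hypothesis `i` is a function of the
   other folds' data and the covariates alone. Weighted p-values (weight 0
   → +∞; p = 0 clipped to the smallest positive double) then enter a single
   BH pass at α, giving a common threshold across folds. Rows with missing
   p-values are dropped with a logged count.

Diagnostics: stratified p-value histograms (hypotheses split at the
covariate's 33%/67% quantiles; an informative covariate shows a growing
spike of near-zero p-values from the low to the high group) and a
shuffled-covariate control (IHW re-run on permuted covariates should reject
about as many hypotheses as BH — weighting on noise must neither gain nor
lose power).

For association tables published as BH q-values, the inverse transform
sorts q ascending, repairs monotonicity by a running maximum, sets
`p_(i) = q_(i)·i/m` and unsorts. BH-adjusting the result reproduces the
monotone q exactly in exact arithmetic (`min_{j≥i} q_(j) = q_(i)`); in
floating point the round trip is exact to ~1 ulp, and tests assert it to
1e-12.

### Enrichment

Top-`N` genes by ensemble rank (default N = 1000) are tested against each
gene set by a one-sided (greater) Fisher exact test — the upper
hypergeometric tail of the 2×2 table top/rest × in-set/out-of-set — with
Bonferroni correction over the number of sets tested. The universe defaults
to all genes with an ensemble score; gene sets are intersected with the
universe before counting. The reported odds ratio is the sample odds ratio
`ad/bc` (∞ when `bc = 0` with `a > 0`; 0 when `a = 0`); the conditional
MLE is available in verbose mode since published tables rarely state which
convention they use.

## Synthetic data generator

The generator emulates the statistical structure of the three real inputs,
making every stage testable offline.

* **Loci**: each of `n_loci` (default 40) loci holds one designated risk
  gene with posterior ~ Beta(8, 2) and `genes_per_locus − 1` (default 7)
  non-risk candidates ~ Beta(2, 8); `n_background_genes` (default 4,680,
  for 5,000 genes total) carry no locus. The designated risk gene is
  usually, not always, the locus argmax — realistic label noise.
* **Propensity**: a continuous per-gene risk propensity in [0, 1] drives
  the p-value model — Beta(8, 2) for risk genes, Uniform(0, 1) otherwise.
  The uniform choice makes the non-null proportion genuinely span its range
  across the genome, so a covariate correlated with the propensity is
  informative of the prior without determining it.
* **Features**: per source, i.i.d. standard normals; a random half of each
  source's features is shifted by `feature_effect_size` (default 2.0 SD)
  for risk genes; optionally one source gets zero shift as an uninformative
  control.
* **P-values**: two-groups model. Gene `i` is non-null with probability
  `clip(expit(b0 + b1·propensity_i), 0.001, 0.999)` with defaults
  `b0 = logit(0.02)`, `b1 = logit(0.20) − logit(0.02)` — π1 rises from 2%
  at propensity 0 to 20% at propensity 1. Null p ~ Uniform(0, 1); non-null
  p ~ Beta(a, 1) with `a = 0.25`, whose closed-form CDF `P(p<t) = t^a`
  gives exact calibration checks.

What the generator does **not** emulate: linkage disequilibrium and 2 Mb
locus geometry (loci are disjoint gene groups), genotypes and burden-test
mechanics (p-values are drawn from the mixture directly), correlated
features within or across sources, and covariate-dependent alternative
strength (the Beta shape is shared). Passing tests therefore demonstrate
the statistical properties of the procedures under a faithful two-groups
abstraction, not performance on any particular real cohort.

## Numerical choices and problem sizes

* BH, the weighted pass, stratification and weight learning are implemented
  directly (vectorized step-up counts over candidate grids, chunked to
  bound memory); random forests, CV splitting, AUC and imputation use
  scikit-learn; the hypergeometric tail uses scipy.
* Determinism: every stochastic step (downsampling, CV splits, fold
  assignment, shuffles, simulation) draws from seeded generators derived
  from a master seed; identical configs give bit-identical outputs.
* Reference problem sizes used by the test suite and the acceptance script:
  m = 5,000 genes, 100–200 two-groups replicates, forests of 150 trees with
  10–50 repeats. The library defaults (3,000 trees, 100 repeats) match the
  production recommendation; the smaller sizes keep the suite minute-scale
  and do not change any generator parameter (effect sizes, π1 range, Beta
  shapes, m).
* Measured behaviour at these conditions (all recomputed by
  `scripts/acceptance.py`): empirical FDR of IHW ≤ α at α ∈ {0.05, 0.1};
  mean rejection gain over BH of ~2–5% across α ∈ {0.05..0.3} with the
  oracle-informative covariate; shuffled covariates power-neutral within
  10% of the BH count. The per-replicate probability that IHW strictly
  beats BH is ≈ 0.6 here: with a π1 gradient of 2%→20% the systematic gain
  (a few rejections) is small relative to replicate noise, and experiments
  with fixed near-oracle weights show this is a property of the conditions
  (the strict-win probability stays ≤ ~0.85 even without weight-estimation
  noise), not of the estimator.

## Known limitations

* The weight grid is coarse by design (auditability over resolution);
  continuous-optimization weighting can be somewhat more powerful.
* The ensemble is an unweighted average of sources; no source reliability
  weighting is attempted.
* Scores are treated as covariates, not calibrated probabilities.
* With very sparse strata the procedure deliberately falls back to plain
  BH rather than learn weights from a handful of p-values.
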
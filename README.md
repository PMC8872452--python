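# rvprior

Prior-informed FDR control for gene-based rare-variant association studies
(RVAS).

Gene-based RVAS tests are underpowered: ultra-rare variants are, by
definition, observed in few carriers, and a genome-wide scan pays a multiple
testing burden of ~20,000 hypotheses. The Benjamini–Hochberg (BH) procedure
treats every gene exchangeably, which is nearly optimal only when all genes
are equally likely to be associated. They are not: GWAS loci, expression
programs and gene-set annotations carry prior information about which genes
plausibly carry risk. `rvprior` turns that prior information into a
per-gene covariate and uses it to reweight the FDR budget, via independent
hypothesis weighting (IHW), without losing type-I error control.

The framework has three stages:

1. **Training labels.** Candidate genes near GWAS-significant loci arrive
   with posterior probabilities from an upstream gene-prioritization tool.
   The top-posterior gene of each locus becomes a positive instance
   (high-confidence risk gene, HRG); genes with posteriors strictly below
   the median over all candidates become negatives (local background genes,
   LBG).
2. **Genome-wide risk scores.** Per feature source (bulk developmental
   expression, reconstituted gene-set memberships, promoter-usage profiles,
   cell-type-averaged single-nucleus expression, …), a random-forest
   classifier is trained on the labels. Because one HRG faces several LBGs,
   each of `n_repeats` repeats downsamples the negatives to a balanced set,
   tunes the forest by 3-fold cross-validation, refits and scores every
   gene; scores are averaged over repeats. Per-source scores are min-max
   normalized and averaged into an **ensemble score** in [0, 1].
3. **Hypothesis weighting.** With p-values `p_1..p_m` and covariates
   `X_1..X_m` (the ensemble scores), plain BH rejects `H_i` when
   `p_i ≤ t̂`. IHW instead rejects when

   ```
   p_i ≤ t̂ · Ŵ(X_i^{−l}),   i ∈ I_l ,
   ```

   i.e. a single BH pass over weighted p-values `p_i / Ŵ(X_i^{−l})`.
   Hypotheses are binned into covariate strata and split into `k` folds
   within each stratum; the weights applied to fold `l` are learned — by
   grid search maximizing the number of weighted-BH discoveries, under the
   budget that weights average to 1 — from the other `k−1` folds only
   (cross-weighting), so the weight applied to a hypothesis never sees its
   own p-value and FDR control is preserved.

The package also provides one-sided Fisher exact enrichment of top-ranked
genes against GMT gene sets (Bonferroni-corrected), a q-value → p-value
inverse-BH transform for inputs published as FDR q-values, stratified
p-value histograms as a covariate-informativeness diagnostic, a
shuffled-covariate control, and a synthetic-data generator that reproduces
the statistical structure of all three inputs so the whole pipeline is
testable offline.

## Worked example

Simulate a dataset (5,000 genes: 40 GWAS-like loci of 8 candidates each,
plus background genes; four feature sources; two-groups p-values whose
non-null proportion rises from 2% to 20% with the true risk propensity),
then adjust the p-values with an informative covariate:

```bash
rvprior simulate --outdir data --seed 11
rvprior adjust data/pvalues.tsv --covariates data/covariate.tsv \
        --alpha 0.1 --seed 1 --out adjusted.tsv
```

which prints

```
m=5000: IHW rejects 96, BH rejects 94 at alpha=0.1
```

— at FDR level 0.1 the covariate-weighted procedure recovers two
associations that plain BH misses on this dataset. `adjusted.tsv` records,
per gene, the stratum, fold, applied weight, weighted and BH-adjusted
p-value and the rejection flag.

The full pipeline (label → train → score → ensemble → adjust → enrich) runs
from one YAML config and writes a manifest plus a rejection-count summary in
the layout `method × α`:

```bash
rvprior run config.yaml
```

```
method                  0.05   0.1   0.2   0.3
IHW-SRC1                  32    53    83   112
IHW-SRC2                  31    52    80   117
IHW-ensemble              39    60    76   104
IHW-shuffled ensemble     26    56    71    98
BH                        33    60    80    99
```

(2 sources, 3,000 genes, seed 7). Single-run differences at this scale are
dominated by replicate noise; the systematic behaviour — FDR control, the
average power gain of the informative covariate, and the neutrality of a
shuffled covariate — is quantified over replicates by the acceptance script
below. Per-repeat cross-validated AUCs of each source model are written to
`auc_report.tsv` (here 0.996 and 1.000: the synthetic feature shift of 2 SD
makes risk genes nearly separable).

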
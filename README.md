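# rarecausal

Gene-based association tests tell you *that* a gene harbors trait-associated
rare variants; they do not tell you *which* of its dozens or hundreds of
variants are the causal ones.  `rarecausal` implements two complementary
statistical approaches for pinpointing rare causal variants in a sequenced
region and estimating their effects, for statistical geneticists analysing
case-control (or dichotomized quantitative) sequencing studies:

1. **Backward elimination on groupwise score tests.**  Starting from a set of
   variants, the variant whose deletion most improves the groupwise Burden or
   SKAT p-value is removed, until no deletion helps.  Applied to 2000 random
   subsets of k = 10 variants, each variant's *return count* — the fraction
   of subsets containing it in which it survived — separates into a
   low-count "non-interesting" and a high-count "interesting" group,
   identified by a two-component nonparametric mixture (top-20% quantile rule
   where the mixture shows no separation, as is typical for synonymous
   variants).
2. **A two-stage hierarchical model.**  The first stage is the logistic
   disease model `logit P(y_i = 1) = alpha_0 + x_i'alpha + g_i'beta`; the
   second stage ties the per-variant log odds ratios to functional
   annotations (non-synonymous indicator, PolyPhen-2-like scores, GERP-like
   conservation, any number of them): `beta = Z gamma + b`,
   `b ~ N(0, tau^2 I)`.  The variance component gets a grid posterior from a
   Laplace-approximated marginal likelihood (half-normal prior on tau); fixed
   and random effects are then estimated by ridge-penalized (penalized
   quasi-likelihood) logistic regression at the posterior-mean `tau^2`.
   Sparse variants — singletons and doubletons, the majority in any
   sequencing study — borrow strength from their annotations, while variants
   with many carriers are driven by their own case/control counts.

The combined workflow runs the gene-level Burden test as a gate, selects
"interesting" variants by return counts, and reports hierarchical-model
effect estimates and standard errors for them.  A built-in simulator
(haplotype pool with a rare-variant-dominated site-frequency spectrum,
MAF-dependent odds-ratio disease models, prevalence-calibrated phenotypes,
Bayes-rule annotation labels) generates cohorts with known causal structure
for benchmarking; see `docs/methods.md` for the model details and all
defaults.

## Worked example

Simulate one cohort (2000 individuals, 10 kb region, disease model M1 with
20% causal rare variants, NS:S ratio 1.4) and run the full pipeline:

```python
import rarecausal as rc

cfg = rc.RunConfig(
    output_dir="demo_run",
    seed=5,
    simulate={"disease_model": "M1", "causal_fraction": 0.2,
              "ns_s_ratio": 1.4, "n_cases": 1000, "n_controls": 1000},
    hm_annotation_columns=["B2"],
)
out = rc.run_pipeline(cfg)
print(open(out / "gene_test.json").read())
```

```
{
 "config_hash": "7c530a9db539",
 "test": "burden",
 "Q": 2704.0,
 "pvalue": 0.01447856069217279,
 "n_variants": 53,
 "eigenvalues": [452.26199999999994]
}
```

The gene-level Burden p-value (here 0.014, computed from the single-
eigenvalue chi-square null of the score statistic Q over the 53 rare
variants) clears the 0.05 gate, so the pipeline continues: backward
elimination with 2000 resamples per stratum, mixture classification of
return counts, and the hierarchical fit.  The report `demo_run/results.tsv`
has one row per rare variant, sorted by descending log odds ratio, mirroring
the layout used for real-data variant tables (counts in cases/controls,
return count, effect, SE, annotations):

```
variant_id    pos     count_cases  count_controls  return_count  log_or  stderr  functional_class  B2  selected
1:501541:A:C  501541            4               0      0.859788  0.597407  0.206923  nonsynonymous   1         1
1:507723:A:C  507723          101              55      0.998665  0.593929  0.140431  nonsynonymous   1         1
1:504716:A:C  504716            5               1      0.893168  0.585634  0.205053  nonsynonymous   1         1
1:503409:A:C  503409           22              13      0.883495  0.548071  0.185494  nonsynonymous   1         1
...
```

Note the hierarchical shrinkage at work: the 4-carrier variant at the top
has nearly the same estimated effect as the 156-carrier variant below it —
its sparse but case-exclusive counts are reinforced by its probably-damaging
annotation — while its standard error is appropriately larger.
`demo_run/evaluation.json` compares the ranking with the simulation truth:

```
{"n_causal_observed": 10, "median_rank_all": 5.0,
 "median_rank_selected": 4.0, "top10_selected": 7}
```

Of the 10 causal variants observed among the rare variants of this cohort,
7 sit in the top 10 of the selected-set ranking.  The same stages are
scriptable from
the shell (`rarecausal simulate | assoc | select | classify | fit | evaluate
| run`); every output carries a hash of the analysis configuration, and a
fixed seed reproduces every file byte for byte.

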
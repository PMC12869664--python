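# clonerisk

Longitudinal tumor-subclone tracking, recurrence signatures, bulk
deconvolution and survival risk stratification for paired
diagnosis–relapse single-cell cohorts.

## The problem

In pediatric AML, relapse is driven by tumor subclones that survive
therapy and expand. Given paired diagnosis/relapse scRNA-seq profiles,
normal-donor references, bulk RNA-seq cohorts with clinical follow-up, and
standard covariates (measurable residual disease, cytogenetic risk),
`clonerisk` implements the inference chain from raw counts to risk strata:

1. **Longitudinal classification** — cluster each patient's cells (Louvain
   on a kNN graph over principal components, resolution 2.5) and label each
   cluster by the fraction of each timepoint's QC-passing cells it holds,
   at threshold θ = 10%:
   *expanded* (n_dx > 0, f_rel > θ, f_dx ≤ θ), *diminished*
   (f_dx > θ, f_rel ≤ θ), *stable* (both > θ), *relapsed* (n_dx = 0,
   f_rel > θ), else *other*. Diminished clusters whose expression program
   tracks a relapse-emergent cluster are flagged *transforming*; patients
   are Group A/B by presence/absence of expanded subclones.
2. **Recurrence signature** — Wilcoxon rank-sum DE of every
   expanded/relapsed/stable cluster against the patient's pooled diminished
   clusters (≥25%-expressed filter, BH-adjusted p < 0.05, positive effect);
   per-gene tallies of recurrent upregulation across all comparisons;
   signature = genes above an Otsu-style cutoff that splits the bimodal
   tally distribution. Hypergeometric enrichment and a rank-z gene-set
   score are provided for downstream use.
3. **Merging and deconvolution** — cluster centroids correlating at
   r > 0.986 merge (single-linkage components; clusters with < 50 cells
   are disqualified) into a gene × subclone signature matrix **S**; a bulk
   profile **b** is decomposed by exact simplex-constrained least squares

       min ‖W^(1/2)(Sπ − b)‖²   s.t.  π ≥ 0,  Σπ = 1,

   solved by an active-set method (machine precision on noiseless
   mixtures), with optional variance/dampened weighting, plus a diagonally
   weighted NNLS similarity score for comparing external subclones to the
   reference set.
4. **Risk stratification** — univariate Cox screening of every subclone
   abundance against OS *and* EFS with Bonferroni correction (adjusted
   p < 0.01 on both; FLT3-ITD–positive patients excluded); T = summed
   abundance of the selected subclones; median split of T combined with
   binary MRD (unknown counted as positive) and cytogenetic risk into
   eight strata; Kaplan–Meier/log-rank tests, multivariate Cox with
   MRD-negative / normal-cytogenetics reference levels, and a
   likelihood-ratio test for nested-model improvement.

A first-class synthetic-data generator (`clonerisk.simulate`) emulates the
study design — negative-binomial counts with log-normal library sizes,
planted subclone dynamics and a shared resistance program, bulk mixtures of
known composition, and exponential proportional-hazards outcomes — so the
whole chain is testable end to end without any data download.

## Worked example

`examples/05_risk_stratification.py` runs the default synthetic study
(8 patients × ~1700 cells, 800 bulk samples) end to end:

```
screened 62 merged subclones; selected (adj p<0.01 on OS and EFS):
  ['M001', 'M010', 'M016', 'M025', 'M034']
T = total abundance of selected subclones; median split -> log-rank p = 1.33e-12

multivariate Cox (binary T / MRD / cytogenetics):
             coef      hr  hr_ci_low  hr_ci_high       p
T_bin      0.7144  2.0430     1.6651      2.5068  0.0000
mrd_bin    0.4167  1.5169     1.2398      1.8559  0.0001
cyto_bin   0.6566  1.9282     1.5704      2.3674  0.0000

adding T to MRD+cytogenetics: LRT chi2=48.3, p=3.60e-12
```

Five subclones pass the double-endpoint screen — they are exactly the
planted expanded/transforming populations — and their total abundance T
remains a strong independent predictor (HR ≈ 2.0 for the high-T half)
after controlling for MRD and cytogenetics. The other examples each
demonstrate one stage (simulation, clustering/classification, signature
derivation, deconvolution) on small inputs.

A thin CLI mirrors the chain on an on-disk study:

```bash
clonerisk simulate --out study/ --seed 1
clonerisk classify --study study/
clonerisk deconvolve --study study/
clonerisk risk --study study/
```

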
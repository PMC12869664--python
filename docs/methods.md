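# Methods

## Synthetic study model

The generator produces the data structure the analysis assumes, with
planted ground truth for every downstream stage.

**Counts.** A cell of subclone *k* has gene-*g* counts
NB(mean = ℓ_c · μ_g · 2^{L_{kg}} / Z_k, inverse-dispersion θ), where
μ_g is a log-normal baseline (meanlog 0, sdlog 1), ℓ_c a log-normal
library size (median 2500, sdlog 0.35), L the subclone log2-fold-change
matrix, and Z_k normalizes each subclone's relative profile to sum 1.
θ defaults to 2 (strong overdispersion; θ→∞ recovers Poisson, which the
tests exploit as a moment oracle). Each subclone owns 60 disjoint marker
genes with log2FC ~ U(1, 3); disjointness makes planted programs
identifiable and is configurable.

**Dynamics.** Each of 8 patients carries six tumor subclones with fixed
(diagnosis, relapse) composition: expanded (0.06, 0.34), stable
(0.24, 0.27), diminished (0.36, 0.02), transforming (0.27, 0.03),
relapsed (0, 0.29), other (0.07, 0.05) — every fraction at least 0.03 from
the 10% classification threshold, so labels are recoverable at realistic
cell counts (700 per timepoint; multinomial sampling leaves crossing
probabilities below 1e-5). Two normal cell types (300 cells/patient)
exercise the normal-exclusion rules. The relapsed subclone's program is a
mix of the transforming subclone's program (weight r = 0.8) and an
orthogonal own program, planting the "transforming" truth as program
correlation; log1p compression attenuates 0.8 to ≈ 0.68 on residual
centroids, and the pipeline flags at 0.5, far above the ≈ −0.2 seen for
non-transforming diminished clusters. At a designed correlation of 0.9
the pair co-clusters at any usable resolution — the transcriptional
continuity that motivates trajectory methods — so 0.8 is the default.

**Resistance program.** 150 genes (log2FC ~ U(1, 2), baselines drawn
mid-to-high so the 25%-expressed filter keeps them) are added to every
patient's expanded subclone. They recur in each of the 8 expanded-cluster
comparisons, while cross-patient marker collisions produce tallies of 1–3,
yielding the bimodal tally distribution the cutoff selector targets.
The 3000-gene universe keeps the collision tail light (collisions scale as
markers²/genes).

**Bulk and outcomes.** 800 diagnostic bulk samples are Dirichlet mixtures
over all patients' subclones and normal types (role-specific
concentrations; relapse-emergent subclones nearly absent at diagnosis),
with per-gene log-normal noise (σ = 0.25) by default; `exact` and
`cell_resample` modes exist for calibration tests. OS and EFS times are
independent exponentials sharing one linear predictor,
λ = λ₀·exp(β_T·T + β_mrd·MRD + β_cyto·cyto), censored by a shared
U(0, horizon) follow-up. In the full study the predictor is log(1.5) per
standard deviation of each risk (expanded or transforming) subclone's
abundance, so every planted risk subclone carries HR 1.5/SD — the effect
size the screening benchmarks quote. MRD (35% positive, 3% missing) and
cytogenetic risk (30% high) enter with HR 2.0 and 2.5; 5% of patients are
FLT3-ITD–positive and excluded from screening.

**Not emulated:** doublets, ambient RNA, batch effects beyond library
size, platform differences between signature and bulk, competing risks,
and informative censoring. Passing tests therefore demonstrate the
correctness of the inference chain under its own assumptions, not
robustness to these artifacts.

## Analysis choices

**QC and normalization.** Cells need ≥ 200 detected genes, genes ≥ 3
cells (community defaults); expression is log1p(count/total × 10⁴).

**Clustering.** PCA (50 components) → kNN graph (k = 20, symmetrized) →
Louvain (igraph multilevel) at resolution 2.5, seeded through igraph's
RNG for determinism. Joint clustering of the concatenated per-patient
matrices replaces anchor-based integration; batch correction is
deliberately omitted since integration happens within patient plus
normals.

**Classification.** Fractions are relative to each timepoint's total
QC-passing tumor cells (normal-donor cells excluded from denominators);
inequalities at θ = 0.10 are strict; "present at diagnosis" is n_dx > 0;
majority-normal clusters are forced to *other*. This is the only reading
under which the four named categories are mutually exclusive and
exhaustive over clusters exceeding θ. The transforming flag uses Pearson
correlation of residual centroids (cluster centroid minus the patient's
mean centroid — removing the shared baseline component that otherwise
dominates all centroid correlations) against every relapse-emergent
cluster (labels *relapsed* or *expanded*: under the strict n_dx = 0 rule a
couple of stray diagnosis cells turn a relapse cluster "expanded", so
restricting to *relapsed* would make the flag unreachable).

**Differential expression and the signature.** Two-sided Wilcoxon
rank-sum per gene; the 25% expression filter applies in at least one of
the two groups; effects are differences of mean log-normalized
expression; BH adjustment spans the tested genes within each comparison
(not across comparisons); "upregulated" requires adjusted p < 0.05 and
positive effect. The reference pool per comparison is all diminished
clusters of the same patient, pooled. The recurrence cutoff minimizes
intra-class variance over the integer tally histogram (Otsu criterion,
smallest value of the upper class; manual override logged) — a
data-driven formalization of "split the bimodal distribution" that does
not hard-code any particular count. Enrichment is one-sided
hypergeometric with BH across sets; the gene-set score is the mean over
set genes of per-gene z-scored ranks across samples (invariant to
monotone per-gene transforms) — both deliberately simple stand-ins for
enrichr/GSVA-class tools.

**Merging and deconvolution.** High-similarity groups are
single-linkage connected components over r > 0.986 edges (similarity is
not transitive, so linkage is a genuine design choice; group diameters
are logged to expose chaining),
computed after dropping clusters under 50 cells. Merged centroids are
cell-count-weighted means on the log scale and exported as expm1 to the
linear scale, so mixing is linear. Bulk and signature are both
normalized to counts-per-10⁴ before solving (making the solution
invariant to bulk rescaling); the solver is an exact active-set method on
the simplex-constrained (optionally weighted) least-squares problem with
a scale-aware KKT check and an SLSQP fallback for the rare cycling case.
`variance` weighting uses W_g = 1/(1+b_g); `dampened` iteratively
reweights by the model fit with weights capped at the 98th percentile.
The subclone-similarity score is NNLS with diagonal weights
1/(1 + mean reference expression), reported normalized to sum 1.

**Risk model.** Subclone screening uses an in-house Newton fit of the
univariate Cox partial likelihood (Breslow ties) — validated against
lifelines and against direct likelihood maximization — because the
operating-characteristic simulations fit thousands of models; all
multivariate fits, Kaplan–Meier curves and log-rank tests go through
lifelines. Bonferroni is applied within each endpoint across the screened
subclones (denominator configurable, default the number screened);
selection requires both endpoints. Median-split ties go to low risk
(conservative, logged). Missing MRD is grouped with MRD-positive. The
nested-model comparison is a likelihood-ratio test (2·Δ log partial
likelihood vs χ²), the standard choice for nested Cox models.

## Numerical notes

Simplex solver tolerances: drop at π < −1e-12, re-add at gradient
violation 1e-9·(1+|μ|) after normalizing the system by ‖b‖; KKT residual
reported on every estimate. Zero-variance centroids yield NA
correlations with a warning rather than an error. Cluster ids are
relabeled contiguously by decreasing size with a stable tie-break.
Annotation ties break toward the first reference column and are logged.

## Problem sizes

Default study: 8 patients × (700 + 700 + 300) cells × 3000 genes,
800 bulk samples; the full chain runs in well under a minute on one core.
Benchmarks use 2000 genes × 8 subclones for deconvolution (20 noiseless
mixtures; 50 pseudobulks of 500 cells), 20 seeds for classification and
cutoff-separation checks, and 50/20 replicates at n = 800 with 90
subclones for the screening null and power. These sizes are the package's
own study conditions; the mechanisms, not any cohort-specific counts, are
what transfers to real data.

## Limitations

Cluster-level (not genotype-based) clone definition; the transforming
flag is a correlation surrogate for trajectory inference; deconvolution
assumes the signature spans the bulk transcriptome (no unknown-content
term); the screening HRs are per unit abundance and depend on abundance
scale; exponential outcomes satisfy proportional hazards by construction,
so the Cox diagnostics are not stress-tested here.
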
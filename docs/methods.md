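# Methods

## Statistical model

Counts are normalized to log2 counts per million,
`log2((count + 0.5) / (libsize * factor + 1) * 1e6)`, with TMM normalization
factors (trimmed mean of M-values: reference = library whose upper-quartile
CPM is closest to the mean upper quartile; 30% two-sided trim on M, 5% on A;
precision-weighted mean of surviving M values; factors rescaled to geometric
mean 1).  Genes with mean log2CPM below zero are removed before modeling.

Per gene, a linear model is fitted to the log2CPM values with observation
precision weights.  The design is treatment-coded with wild type and the
unstimulated condition as reference levels, so the coefficients are log2
fold changes: a stimulation main effect (stimulated vs unstimulated in wild
type), one mutant main effect per genotype (mutant vs wild type,
unstimulated) and one interaction per genotype.  Precision weights follow
the voom recipe: per-gene residual standard deviations from an unweighted
fit, a lowess trend (span 0.5) of sqrt(sd) against mean log2 count, and
per-observation weights equal to the trend prediction at the fitted log2
count raised to −4.  The trend is clamped below at sd 0.05 to keep weights
finite on small, nearly noise-free simulations.

The experiment identifier (batch) enters either as fixed dummy columns or as
a one-variance-component random intercept.  The random-intercept model is
fitted by maximum likelihood with the variance ratio λ = σ²_batch/σ²_resid
profiled out: for fixed λ the GLS coefficients and the ML residual variance
are closed-form, and λ is maximized by bounded scalar search on log10 λ in
[−8, 3] (tolerance 1e-8), with the λ→0 boundary checked explicitly.  Wald
t statistics use the residual degrees of freedom of the fixed part (n − p);
no Satterthwaite correction and no empirical-Bayes variance moderation are
applied — this is a deliberate plain-WLS/ML contract, so p values are exact
under normality rather than moderated.  If the batch factor is confounded
with the design (adding its dummies does not increase the design rank by
n_batches − 1), the fit falls back to fixed mode with a logged warning.

P values are Benjamini–Hochberg adjusted across all genuine comparisons;
intercept and batch-dummy rows are nuisance terms and are left unadjusted.

## Interaction signatures

Genes with adjusted interaction p below α (default 0.05) are partitioned by
two dominance indicators, D_s = (|β_int| > r·|β_stim|) and
D_m = (|β_int| > r·|β_mut|) with dominance ratio r = 2:

* D_s ∧ D_m → **de_novo** — the interaction dominates both main effects;
* ¬D_s ∧ ¬D_m → **minor** — significant but dominated;
* D_m only → the mutant modifies the stimulation response:
  **mut_enhances_stim** if sign(β_int) = sign(β_stim), else
  **mut_reverts_stim**;
* D_s only → stimulation modifies the mutant effect:
  **stim_enhances_mut** if sign(β_int) = sign(β_mut), else
  **stim_reverts_mut**.

"Twofold greater" is read as a strict inequality, so exact equality falls to
the not-greater branch and the partition is deterministic at boundaries.
When a compared main effect is exactly zero, dominance holds for any
non-zero interaction, so the sign branches never see sign(0); the
pathological all-zero triple with a significant p is labeled minor.  The
classification is scale-equivariant (multiplying all three coefficients by
c > 0 leaves the label unchanged) and exhaustive enumeration over sign ×
magnitude grids confirms exactly five assignable groups plus minor, one
label per input.

Prevalence denominators are all interaction-significant genes (minor genes
included).  Reversion shares divide the group-3 (group-5) count by the
number of genes with a significant stimulation (mutant) main effect at the
same α on adjusted p — adjusted rather than raw, because the pipeline
declares significance on padj throughout.

## Sample QC

Stage one applies strict below-threshold filters per sample: RNA — reads
< 1e6, alignment rate < 0.5, exome rate < 0.3; ATAC-style region tables —
reads < 5e6, peaks < 1e3, alignment rate < 0.5, FRiP < 0.025.  Boundary
values pass.  Stage two computes each sample's mean Spearman correlation
with its biological replicates on the filtered log2CPM matrix — the same
matrix the models see, which makes the correlations comparable across
assays and library depths.  The exclusion
cutoff is the mean cross-pair Spearman correlation between two clearly
distinct reference groups (e.g. wild-type macrophages vs wild-type CD8 T
cells); for cultured samples a fixed 0.5 is used instead.  Samples below the
cutoff are excluded unless a group would drop below three samples, in which
case the three-sample subset with the highest mean pairwise correlation is
kept (exhaustive over triples, ties broken by lexicographic sample id);
groups of three or fewer are kept whole, and singleton groups pass with a
logged warning.

## Gene modules and contrast similarity

Genes passing padj < 0.05 and |log2FC| > 2 in at least one coefficient form
a genes × coefficients log2FC matrix (missing entries imputed as zero:
absence of evidence of effect keeps the matrix complete).  A symmetrized
union kNN graph (k = 15, Euclidean, distance ties broken by row order) is
clustered with walktrap (4-step random walks, cut at maximum modularity) via
igraph; community detection is a deterministic function of the graph and
never depends on any 2-D layout, which is provided only for visualization
(UMAP when installed, otherwise the first two principal components).
Contrast similarity maps use classical (Torgerson) MDS on distances
1 − Spearman ρ between contrast log2FC profiles; the embedding is defined up
to rotation and reflection.

## Enrichment statistics

The ranking metric is −log10(p)·sign(log2FC) with zero p clamped to the
smallest positive float; ties are broken by |log2FC| then gene id.  Fisher's
exact test uses the sum-of-smaller-probability two-sided convention and the
sample odds ratio.  Preranked enrichment uses the weighted running sum (hits
add |stat|^exponent normalized to 1, misses subtract 1/(N − N_hit)); the p
value comes from gene-label permutations (sample-level permutation is
impossible from ranked statistics alone) with a +1 pseudo-count and the
signed-tail convention, and NES divides the ES by the mean |null ES| of
matching sign.  CERNO is −2Σln(r_i/N) against χ² with 2·|set| df.  The
sampling overlap test draws same-size queries uniformly from the universe;
NES is defined as observed/mean(null) — the minimal definition consistent
with a "normalized enrichment score", chosen because no formal definition
accompanies the figure-level usage — and the two-sided p doubles the smaller
tail with a +1 pseudo-count, capped at 1.

## Synthetic data generator

The generator emulates the study structure: genotypes × cell types ×
conditions × replicates, with batches assigned round-robin over replicate
indices.  Counts are gamma-Poisson (negative binomial, variance μ + φμ²)
around means `lib · 2^(base + celltype + x'β + batch) / normalizer`, where
the normalizer makes each sample's relative abundances sum to one —
so planting effects induces the same mild composition shifts TMM exists to
correct.  Defaults: baseline log2 abundance N(3, 2); gene dispersions
log-normal with median 0.1; library sizes log-normal, mean 5e6, CV 0.2;
per-gene cell-type offsets N(0, 2) so distinct cell types are genuinely
distinct (this is what makes the cross-cell-type QC cutoff meaningful);
batch offsets N(0, batch_sd) shared across genes by default, with a
per-gene-per-batch switch — note that gene-shared offsets cancel under CPM
normalization, so studies of batch absorption should use the per-gene
variant.  Four replicates per cell and two batches by default, matching the
3–6 replicate range of the emulated design.

Archetype genes draw |β_int| uniformly from [1, 3] log2 units; main effects
are sized to respect or violate the twofold dominance rules with a margin of
at least 0.1 so the planted labels are unambiguous, and the classifier
applied to the planted coefficients reproduces the planted label for 100% of
planted genes by construction.  Null genes have all coefficients zero.
Outlier injection either permutes a sample's counts across genes
(`shuffle_genes`, preserving the count distribution while destroying
replicate correlation) or re-simulates the sample around a donor profile
from a different cell type (`swap_profile`).

What the generator does **not** emulate: gene–gene correlation, length or GC
bias, varying library complexity, dropout, or real effect-size
distributions (the emulated study does not publish them).  Benchmarks on
this generator therefore demonstrate correctness of the statistical
machinery under its stated model, not performance on real data.

## Benchmark problem sizes and expected outcomes

The self-validation battery (`mutstim.validation`, driven by
`scripts/acceptance.py` and the acceptance tests) uses problem sizes chosen
to estimate each quantity precisely while keeping the full battery around a
minute: 2000 null genes for calibration; 50 seeds × 300 genes with 60
planted mutant effects for effect recovery; 20 seeds × 800 genes for label
recovery; 20 seeds × 300 genes for module recovery; 50 seeds × 2000 genes
for QC.  The resampling uniformity checks run at transcriptome scale
(universe 10000, query 1000, reference 5000): the two-sided sampling p is
discrete, and only when the null overlap distribution is wide (sd ≈ 15 here)
does it behave as continuously uniform under a Kolmogorov–Smirnov check.

Two recovery numbers deserve context.  At the reference conditions —
negative-binomial dispersion φ = 0.1 and 4 replicates per cell — the
per-sample log2 noise floor is sd = sqrt(ψ₁(1/φ))/ln 2 ≈ 0.47, so the best
unbiased 4-vs-4 contrast has standard error 0.33 and mean absolute error
sqrt(2/π)·0.33 ≈ 0.26 log2 units; the interaction coefficient has standard
error 0.47, so interactions near |β_int| = 1 sit close to the detection
boundary of a 5% FDR and dominance comparisons near the twofold boundary are
noise-limited.  The measured values — MAE ≈ 0.26–0.27, overall label
recovery ≈ 0.55–0.56 with ≈ 0.84 correct among genes passing the
significance gate — sit at these information-theoretic limits; they reflect
the experiment's signal-to-noise, not estimator defects (the same pipeline
at dispersion 0.01 recovers effects with MAE < 0.1 and labels at > 0.9).
Confidence-interval coverage (0.95), null false-positive rate (within the
binomial 99% band of 0.05), module ARI (1.0) and QC sensitivity/false
exclusion (1.0 / 0.0) confirm calibration and structure recovery.

## Known limitations

* Mixed-model Wald tests use residual df of the fixed part; Satterthwaite
  df and shrinkage moderation are out of scope, so small-sample mixed-model
  p values are slightly anti-conservative when the batch variance is large
  and the design unbalanced.
* TMM assumes most genes unchanged; with ≳15% strongly asymmetric
  differential genes plus heavy per-gene batch noise, residual composition
  offsets of ~0.1–0.3 log2 can remain (they cancel in contrasts against
  null-gene baselines).
* The exact number and identity of gene modules on real data depend on k
  and the walktrap step count; defaults (k = 15, t = 4) follow the common
  defaults of the tools this pipeline mirrors and are exposed as
  configuration.
* ATAC-style data are supported only as pre-counted region × sample
  matrices run through the same engine; no peak calling or fragment model.
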
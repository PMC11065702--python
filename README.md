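# mutstim

Interaction-aware differential expression for multi-genotype immune
transcriptomes.

## The problem

Bulk RNA-seq studies of immune cells from panels of mutant mouse genotypes
(e.g. knockouts of JAK-STAT pathway members) under resting and stimulated
conditions ask two intertwined questions: which genes does each mutation
affect at baseline, and how does each mutation reshape the response to a
stimulus such as interferon-β?  The second question is a statistical
interaction: for each gene, a two-factor linear model

```
log2 expression ~ stim + mut + stim:mut  (+ experiment batch)
```

yields a stimulation main effect β_stim (stimulated vs unstimulated in wild
type), a mutant main effect β_mut (mutant vs wild type, unstimulated), and
an interaction β_int that quantifies how the mutation changes the
stimulation response.  `mutstim` implements the full pipeline around that
model for scientists analyzing such designs:

* **qc** — hard per-sample metric thresholds (read depth, alignment rate,
  exome rate / FRiP, peak count) plus replicate-correlation outlier removal
  with a data-driven cutoff and a keep-top-3 rescue rule;
* **diffexpr** — TMM normalization factors, log2CPM, low-expression
  filtering, voom-style precision weights, and per-gene weighted linear
  models with the batch either as fixed dummies or as a maximum-likelihood
  random intercept; Benjamini–Hochberg FDR control;
* **signatures** — the five-group interaction classifier: genes with a
  significant β_int are partitioned by magnitude dominance
  (|β_int| > 2·|β_main|) and relative sign into *de novo*,
  *mutant-enhances-stimulation*, *mutant-reverts-stimulation*,
  *stimulation-enhances-mutant* and *stimulation-reverts-mutant* (plus
  *minor* when neither main effect is dominated), with prevalence and
  reversion-share summaries;
* **modules** — effect-profile gene modules: strongly differential genes
  (padj < 0.05, |log2FC| > 2) form a log2FC matrix, clustered by walktrap
  random-walk communities on a symmetrized kNN graph; plus a classical-MDS
  similarity map of contrasts from Spearman distances;
* **enrichment** — two-sided Fisher's exact tests, preranked running-sum
  enrichment with a permutation null, the CERNO rank test, and a
  random-sampling overlap test with a normalized enrichment score, all on
  the signed −log10(p) ranking metric;
* **simulate** — a negative-binomial generator that reproduces the study
  structure (genotypes × cell types × conditions × replicates × batches)
  and plants genes in the five signature archetypes, so every stage is
  testable against known ground truth.

## Worked example

```python
import mutstim as ms
import pandas as pd

# simulate a 2-genotype x 2-condition study, 4 replicates, planted archetypes
cfg = ms.SimulationConfig(n_genes=1000, seed=42)
design, truth, counts = ms.simulate_dataset(cfg)

# normalize, weight, fit the interaction model with a batch random intercept
factors = ms.tmm_factors(counts)
norm = ms.log2_cpm(counts, factors)
keep = ms.filter_low_expression(norm)
norm = ms.NormalizedMatrix(norm.values.loc[keep], norm.lib_size, norm.factors)
X = ms.make_design(design, condition="condition", interaction=True)
weights = ms.mean_variance_weights(norm, X)
fit = ms.fit_linear_models(ms.ModelSpec(norm.values, X, weights,
                                        design["experiment_id"], "random_intercept"))

# classify interaction signatures
lfc = fit.pivot(index="gene", columns="coefficient", values="log2FC")
padj = fit.pivot(index="gene", columns="coefficient", values="padj")
table = pd.DataFrame({"beta_stim": lfc["stim"], "beta_mut": lfc["mut_MUT"],
                      "beta_int": lfc["int_MUT"], "padj_stim": padj["stim"],
                      "padj_mut": padj["mut_MUT"], "padj_int": padj["int_MUT"]})
labels = ms.classify_signatures(table)
print(labels.value_counts())
share, n = ms.reversion_shares(labels, table, "mutant_reverts_stim")
print(f"mutant reverts stimulation: {share:.1f}% of {n} genes")
```

This prints (by construction of the planted truth, 40 genes per archetype):

```
unassigned           848
de_novo               48
mut_reverts_stim      26
stim_reverts_mut      26
stim_enhances_mut     24
mut_enhances_stim     17
minor                 11
mutant reverts stimulation: 32.1% of 81 genes
```

152 genes have a significant interaction at 5% FDR; the five archetypes are
recovered in roughly their planted proportions (genes with weaker planted
interactions fall below the significance gate and stay `unassigned`).  The
reversion share is the percentage of stimulation-responsive wild-type genes
whose response the mutant cancels — here 32.1% of 81 such genes.

The same stages are available as a CLI for shell pipelines:

```
mutstim --outdir out --seed 1 simulate
mutstim --outdir out fit --counts out/counts.tsv --samples out/samples.csv \
        --condition-col condition --interaction
mutstim --outdir out classify --fit out/fit.tsv --mutant MUT
```

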
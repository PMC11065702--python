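import numpy as np
import pandas as pd
import pytest

import mutstim as ms


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated study: 2 genotypes x 1 cell type x 2 conditions x 4
    replicates with all five signature archetypes planted."""
    cfg = ms.SimulationConfig(n_genes=400, seed=7)
    design, truth, counts = ms.simulate_dataset(cfg)
    return cfg, design, truth, counts


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """Interaction-model fit of the small dataset (fixed batch mode)."""
    cfg, design, truth, counts = small_dataset
    factors = ms.tmm_factors(counts)
    norm = ms.log2_cpm(counts, factors)
    mask = ms.filter_low_expression(norm)
    norm = ms.NormalizedMatrix(norm.values.loc[mask], norm.lib_size, norm.factors)
    X = ms.make_design(design, condition="condition", interaction=True)
    weights = ms.mean_variance_weights(norm, X)
    fit = ms.fit_linear_models(ms.ModelSpec(norm.values, X, weights, None, "fixed"))
    return truth, fit


def interaction_table(fit, mutant="MUT"):
    """Pivot a long fit table to the per-gene interaction coefficient view."""
    lfc = fit.pivot(index="gene", columns="coefficient", values="log2FC")
    padj = fit.pivot(index="gene", columns="coefficient", values="padj")
    return pd.DataFrame(
        {
            "beta_stim": lfc["stim"],
            "beta_mut": lfc[f"mut_{mutant}"],
            "beta_int": lfc[f"int_{mutant}"],
            "padj_stim": padj["stim"],
            "padj_mut": padj[f"mut_{mutant}"],
            "padj_int": padj[f"int_{mutant}"],
        }
    )
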
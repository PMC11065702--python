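"""Synthetic multi-genotype immune transcriptome generator.

Emulates the structure of a bulk RNA-seq study of immune cells from several
mutant mouse genotypes and cell types, under an unstimulated baseline and one
or more stimulation/culture conditions, with replicates nested in experiment
batches.  Counts follow a negative-binomial model

    count ~ NB(mean = lib * 2^(base + celltype + x'beta + batch) / normalizer,
               dispersion = phi)

with variance mu + phi * mu^2 and gene-wise dispersions drawn log-normally.
A configurable fraction of genes is planted in each of the five interaction
signature archetypes (plus ``minor``); the remainder are null.  The planted
coefficients respect the classifier's magnitude-dominance and sign rules with
a safety margin, so the classifier applied to the truth reproduces the
planted labels exactly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signatures import (
    DE_NOVO,
    MINOR,
    MUT_ENHANCES_STIM,
    MUT_REVERTS_STIM,
    SIGNATURE_GROUPS,
    STIM_ENHANCES_MUT,
    STIM_REVERTS_MUT,
    UNASSIGNED,
)

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    The first genotype is the wild-type reference; the first condition is the
    unstimulated baseline.  ``archetype_fractions`` maps signature labels to
    the fraction of genes planted in that archetype (the remainder are null
    genes with all coefficients zero).
    """

    n_genes: int = 2000
    genotypes: list[str] = field(default_factory=lambda: ["WT", "MUT"])
    cell_types: list[str] = field(default_factory=lambda: ["Tcell"])
    conditions: list[str] = field(default_factory=lambda: ["unstim", "IFNb"])
    n_replicates: int = 4
    n_batches: int = 2
    batch_sd: float = 0.0
    batch_per_gene: bool = False
    celltype_sd: float = 2.0
    dispersion_meanlog: float = float(np.log(0.1))
    dispersion_sdlog: float = 0.0
    lib_size_mean: float = 5e6
    lib_size_cv: float = 0.2
    archetype_fractions: dict[str, float] = field(
        default_factory=lambda: {g: 0.04 for g in SIGNATURE_GROUPS}
    )
    effect_magnitude_low: float = 1.0
    effect_magnitude_high: float = 3.0
    dominance_margin: float = 0.1
    base_meanlog2: float = 3.0
    base_sdlog2: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("genotypes", "cell_types", "conditions"):
            if not getattr(self, name):
                raise ValueError(f"factor list {name!r} must be non-empty")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        bad = set(self.archetype_fractions) - set(SIGNATURE_GROUPS) - {MINOR}
        if bad:
            raise ValueError(f"unknown archetype labels: {sorted(bad)}")
        total = sum(self.archetype_fractions.values())
        if total > 1 + 1e-12:
            raise ValueError(f"archetype fractions sum to {total} > 1")
        if not 0 < self.effect_magnitude_low <= self.effect_magnitude_high:
            raise ValueError("effect magnitude bounds must satisfy 0 < low <= high")


def simulate_design(config: SimulationConfig) -> pd.DataFrame:
    """Build the sample sheet: one row per sample, replicates in every
    genotype x cell type x condition cell, batches assigned round-robin over
    replicate indices.  Deterministic given the config."""
    config.validate()
    rows = []
    for ct in config.cell_types:
        for g in config.genotypes:
            for cond in config.conditions:
                for r in range(config.n_replicates):
                    batch = r % config.n_batches
                    rows.append(
                        {
                            "sample_id": f"{ct}_{g}_{cond}_r{r + 1}",
                            "genotype": g,
                            "cell_type": ct,
                            "condition": cond,
                            "experiment_id": f"batch{batch + 1}",
                        }
                    )
    design = pd.DataFrame(rows).set_index("sample_id")
    logger.info("simulated design with %d samples", len(design))
    return design


def _plant_coefficients(
    label: str, rng: np.random.Generator, low: float, high: float, margin: float
) -> tuple[float, float, float]:
    """Draw (beta_stim, beta_mut, beta_int) satisfying the archetype's
    dominance and sign relations with a safety margin away from the 2x
    boundaries."""
    b = rng.uniform(low, high)
    s = rng.choice([-1.0, 1.0])
    beta_int = s * b
    big = rng.uniform(b / 2 + margin, b)  # dominated-by-main magnitude
    small = rng.uniform(0.0, max(b / 2 - margin, 0.0))  # dominated-by-interaction
    other_sign = rng.choice([-1.0, 1.0])
    if label == DE_NOVO:
        return 0.0, 0.0, beta_int
    if label == MUT_ENHANCES_STIM:
        return s * big, other_sign * small, beta_int
    if label == MUT_REVERTS_STIM:
        return -s * big, other_sign * small, beta_int
    if label == STIM_ENHANCES_MUT:
        return other_sign * small, s * big, beta_int
    if label == STIM_REVERTS_MUT:
        return other_sign * small, -s * big, beta_int
    if label == MINOR:
        sign2 = rng.choice([-1.0, 1.0])
        return other_sign * rng.uniform(b / 2 + margin, b), sign2 * rng.uniform(
            b / 2 + margin, b
        ), beta_int
    raise ValueError(f"unknown archetype: {label!r}")


def simulate_effects(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the per-gene truth table.

    Returns a frame indexed by gene with columns ``base`` (baseline log2
    mean), ``dispersion``, ``beta_stim``, ``beta_mut``, ``beta_int`` (log2
    units, shared across mutant genotypes) and ``label`` (planted archetype,
    ``unassigned`` for null genes).
    """
    config.validate()
    n = config.n_genes
    genes = [f"gene{i + 1:05d}" for i in range(n)]
    base = rng.normal(config.base_meanlog2, config.base_sdlog2, size=n)
    dispersion = rng.lognormal(config.dispersion_meanlog, config.dispersion_sdlog, size=n)

    labels = np.array([UNASSIGNED] * n, dtype=object)
    beta = np.zeros((n, 3))
    pos = 0
    for arch, frac in config.archetype_fractions.items():
        k = int(round(frac * n))
        for i in range(pos, pos + k):
            beta[i] = _plant_coefficients(
                arch,
                rng,
                config.effect_magnitude_low,
                config.effect_magnitude_high,
                config.dominance_margin,
            )
            labels[i] = arch
        pos += k
    truth = pd.DataFrame(
        {
            "base": base,
            "dispersion": dispersion,
            "beta_stim": beta[:, 0],
            "beta_mut": beta[:, 1],
            "beta_int": beta[:, 2],
            "label": labels,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    logger.info(
        "planted %d effect genes of %d (%s)",
        int((labels != UNASSIGNED).sum()),
        n,
        {k: v for k, v in pd.Series(labels).value_counts().items() if k != UNASSIGNED},
    )
    return truth


def simulate_counts(
    design: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw the negative-binomial count matrix (genes x samples).

    Sample means are library size times the gene's relative abundance
    ``2^(base + celltype offset + x'beta + batch offset)`` renormalized to
    sum to 1 within each sample; counts are gamma-Poisson draws with
    variance ``mu + phi mu^2`` (Poisson in the ``phi -> 0`` limit).
    """
    config.validate()
    n_genes = len(truth)
    n_samples = len(design)

    # per-gene cell-type offsets make distinct cell types genuinely distinct
    ct_levels = list(config.cell_types)
    ct_offsets = {ct_levels[0]: np.zeros(n_genes)}
    for ct in ct_levels[1:]:
        ct_offsets[ct] = rng.normal(0.0, config.celltype_sd, size=n_genes)

    batches = sorted(design["experiment_id"].unique())
    if config.batch_per_gene:
        batch_offsets = {b: rng.normal(0.0, config.batch_sd, size=n_genes) for b in batches}
    else:
        batch_offsets = {
            b: np.full(n_genes, rng.normal(0.0, config.batch_sd)) for b in batches
        }

    lib_sigma = np.sqrt(np.log1p(config.lib_size_cv**2))
    lib_mu = np.log(config.lib_size_mean) - lib_sigma**2 / 2
    lib_sizes = rng.lognormal(lib_mu, lib_sigma, size=n_samples)

    base = truth["base"].to_numpy()
    beta = truth[["beta_stim", "beta_mut", "beta_int"]].to_numpy()
    phi = truth["dispersion"].to_numpy()
    baseline_cond = config.conditions[0]
    ref_genotype = config.genotypes[0]

    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    for j, (sid, row) in enumerate(design.iterrows()):
        stim = 0.0 if row["condition"] == baseline_cond else 1.0
        mut = 0.0 if row["genotype"] == ref_genotype else 1.0
        log2_expr = (
            base
            + ct_offsets[row["cell_type"]]
            + beta @ np.array([stim, mut, stim * mut])
            + batch_offsets[row["experiment_id"]]
        )
        rel = np.exp2(log2_expr)
        mu = lib_sizes[j] * rel / rel.sum()
        # gamma-Poisson mixture: shape 1/phi, scale phi*mu gives var mu + phi*mu^2;
        # the phi -> 0 limit is plain Poisson
        lam = mu.copy()
        nb = phi >= 1e-12
        if nb.any():
            lam[nb] = rng.gamma(1.0 / phi[nb], phi[nb] * mu[nb])
        counts[:, j] = rng.poisson(lam)
    matrix = pd.DataFrame(counts, index=truth.index, columns=design.index)
    logger.info("simulated counts: %d genes x %d samples", n_genes, n_samples)
    return matrix


def inject_outliers(
    counts: pd.DataFrame,
    sample_ids,
    mode: str,
    rng: np.random.Generator,
    design: pd.DataFrame | None = None,
    truth: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Corrupt selected samples so they become replicate-correlation outliers.

    ``shuffle_genes`` permutes the sample's counts across genes, destroying
    its correlation with replicates while preserving the count distribution.
    ``swap_profile`` replaces the sample with a fresh negative-binomial draw
    around the profile of a donor sample from a different cell type (needs
    ``design`` and ``truth``).

    Returns the modified matrix and the list of flagged sample ids.
    """
    sample_ids = list(sample_ids)
    unknown = [s for s in sample_ids if s not in counts.columns]
    if unknown:
        raise KeyError(f"unknown sample id(s): {unknown}")
    out = counts.copy()
    for sid in sample_ids:
        if mode == "shuffle_genes":
            out[sid] = rng.permutation(out[sid].to_numpy())
        elif mode == "swap_profile":
            if design is None or truth is None:
                raise ValueError("swap_profile requires design and truth tables")
            ct = design.loc[sid, "cell_type"]
            donors = design.index[(design["cell_type"] != ct)]
            if len(donors) == 0:
                raise ValueError("swap_profile needs a sample from a different cell type")
            donor = donors[rng.integers(len(donors))]
            mu = np.maximum(counts[donor].to_numpy().astype(float), 0.1)
            phi = truth["dispersion"].to_numpy()
            lam = mu.copy()
            nb = phi >= 1e-12
            if nb.any():
                lam[nb] = rng.gamma(1.0 / phi[nb], phi[nb] * mu[nb])
            out[sid] = rng.poisson(lam)
        else:
            raise ValueError(f"unknown mode: {mode!r}")
    return out, sample_ids


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: design, truth and counts from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    design = simulate_design(config)
    truth = simulate_effects(config, rng)
    counts = simulate_counts(design, truth, config, rng)
    return design, truth, counts


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a plain mapping (e.g. YAML),
    rejecting unknown keys."""
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    bad = set(d) - known
    if bad:
        raise ValueError(f"unknown simulation config keys: {sorted(bad)}")
    return SimulationConfig(**d)
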
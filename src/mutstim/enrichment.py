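"""Gene-set enrichment statistics.

Four complementary tests: a two-sided Fisher's exact test for overlap of a
query set with an annotation set within a universe; preranked enrichment
with the weighted Kolmogorov-Smirnov running-sum statistic and a gene-label
permutation null; the CERNO rank test (-2 sum of log relative ranks, chi2
with 2 * set size degrees of freedom); and a random-sampling overlap test
whose normalized enrichment score is the observed overlap over the mean
overlap of uniform draws.  The standard ranking metric is the signed
-log10 p of differential expression.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)


def rank_metric(fit: pd.DataFrame) -> pd.DataFrame:
    """Rank genes by signed significance: ``-log10(p) * sign(log2FC)``.

    ``fit`` needs columns ``gene``, ``p`` and ``log2FC`` (one row per gene).
    Zero p values are clamped to the smallest positive float before the log.
    The result is sorted descending; ties are broken by absolute log2FC then
    gene id, so the order is deterministic.
    """
    for col in ("gene", "p", "log2FC"):
        if col not in fit.columns:
            raise ValueError(f"fit table lacks column {col!r}")
    if fit[["p", "log2FC"]].isna().any().any():
        raise ValueError("missing p or log2FC values in the fit table")
    if fit["gene"].duplicated().any():
        raise ValueError("duplicate genes in the fit table")
    p = np.maximum(fit["p"].to_numpy(dtype=float), np.finfo(float).tiny)
    stat = -np.log10(p) * np.sign(fit["log2FC"].to_numpy(dtype=float))
    out = pd.DataFrame(
        {"gene": fit["gene"].to_numpy(), "stat": stat, "abs_lfc": fit["log2FC"].abs()}
    )
    out = out.sort_values(
        ["stat", "abs_lfc", "gene"], ascending=[False, False, True], kind="stable"
    )
    return out[["gene", "stat"]].reset_index(drop=True)


def fisher_enrichment(query, annotation, universe) -> dict:
    """Two-sided Fisher's exact test of query/annotation overlap.

    The 2x2 table counts universe genes by membership in the query and the
    annotation; the two-sided p sums hypergeometric probabilities of tables
    at most as probable as the observed one; the odds ratio is the sample
    estimate ``(a d) / (b c)``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query) & universe
    annotation = set(annotation) & universe
    a = len(query & annotation)
    b = len(query - annotation)
    c = len(annotation - query)
    d = len(universe) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return {
        "overlap": a,
        "set_size": len(annotation),
        "query_size": len(query),
        "universe_size": len(universe),
        "odds_ratio": float(odds),
        "p": float(p),
    }


def fisher_enrichment_table(query, collection, universe) -> pd.DataFrame:
    """Fisher's exact test of one query against every set in a collection,
    with BH adjustment across sets."""
    rows = {
        name: fisher_enrichment(query, genes, universe)
        for name, genes in collection.items()
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "set_name"
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out


def _running_sum_es(stats_ordered: np.ndarray, hit: np.ndarray, exponent: float) -> float:
    """Enrichment score: signed maximum deviation of the weighted running sum."""
    n = len(stats_ordered)
    n_hit = int(hit.sum())
    weights = np.abs(stats_ordered) ** exponent
    hit_total = weights[hit].sum()
    if hit_total == 0:
        # all hit statistics are zero: fall back to equal hit increments
        increments = np.where(hit, 1.0 / n_hit, -1.0 / (n - n_hit))
    else:
        increments = np.where(hit, weights / hit_total, -1.0 / (n - n_hit))
    running = np.cumsum(increments)
    return float(running[np.argmax(np.abs(running))])


def preranked_es(
    ranked: pd.DataFrame,
    geneset,
    exponent: float = 1.0,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Preranked enrichment with a weighted running-sum statistic.

    Walking down the ranked list, set members add ``|stat|^exponent``
    (normalized to sum 1 over members) and non-members subtract
    ``1/(N - N_hit)``; the enrichment score (ES) is the signed maximum
    deviation.  The p value comes from gene-label permutations with the
    signed-tail convention and a +1 pseudo-count; NES divides the ES by the
    mean absolute null ES of matching sign.
    """
    if rng is None:
        rng = np.random.default_rng()
    genes = ranked["gene"].to_numpy()
    statv = ranked["stat"].to_numpy(dtype=float)
    hit = np.isin(genes, list(set(geneset)))
    n_hit = int(hit.sum())
    if n_hit == 0 or n_hit == len(genes):
        raise ValueError("gene set must cover some but not all of the ranked list")
    es = _running_sum_es(statv, hit, exponent)

    null = np.empty(n_perm)
    for b in range(n_perm):
        perm_hit = np.zeros(len(genes), dtype=bool)
        perm_hit[rng.choice(len(genes), size=n_hit, replace=False)] = True
        null[b] = _running_sum_es(statv, perm_hit, exponent)
    same_sign = null * np.sign(es) >= 0 if es != 0 else np.ones(n_perm, dtype=bool)
    n_extreme = int(np.sum(np.abs(null[same_sign]) >= abs(es)))
    p = (n_extreme + 1) / (int(same_sign.sum()) + 1)
    denom = np.mean(np.abs(null[same_sign])) if same_sign.any() else np.nan
    nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
    return {
        "ES": es,
        "NES": float(nes),
        "p": float(min(p, 1.0)),
        "overlap": n_hit,
        "set_size": len(set(geneset)),
        "universe_size": len(genes),
    }


def cerno_test(ranked: pd.DataFrame, geneset) -> dict:
    """CERNO rank test: ``-2 sum(ln(r_i / N))`` over set-member ranks,
    chi-squared with ``2 * |set|`` degrees of freedom (upper tail)."""
    genes = list(ranked["gene"])
    members = set(geneset) & set(genes)
    if not members:
        raise ValueError("no gene-set member present in the ranked list")
    N = len(genes)
    ranks = np.array([i + 1 for i, g in enumerate(genes) if g in members], dtype=float)
    statistic = float(-2.0 * np.sum(np.log(ranks / N)))
    p = float(stats.chi2.sf(statistic, df=2 * len(ranks)))
    return {
        "cerno": statistic,
        "df": 2 * len(ranks),
        "p": p,
        "overlap": len(ranks),
        "set_size": len(set(geneset)),
        "universe_size": N,
    }


def cerno_table(ranked: pd.DataFrame, collection) -> pd.DataFrame:
    """CERNO test for every set in a collection, BH-adjusted across sets."""
    rows = {}
    for name, genes in collection.items():
        try:
            rows[name] = cerno_test(ranked, genes)
        except ValueError:
            logger.warning("gene set %r has no member in the ranked list; skipped", name)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "set_name"
    if len(out):
        out["padj"] = bh_adjust(out["p"].to_numpy())
    return out


def sampling_overlap_test(
    query,
    reference,
    universe,
    n_draws: int = 10000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Random-sampling overlap test with a normalized enrichment score.

    The observed overlap of query and reference is compared with overlaps of
    ``n_draws`` uniform same-size draws from the universe.  NES is observed
    over mean null overlap; the two-sided p doubles the smaller tail
    probability (with a +1 pseudo-count), capped at 1.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    if rng is None:
        rng = np.random.default_rng()
    universe = sorted(set(universe))
    query = set(query) & set(universe)
    reference = set(reference) & set(universe)
    if len(query) > len(universe):
        raise ValueError("query larger than universe")
    observed = len(query & reference)

    ref_mask = np.fromiter((g in reference for g in universe), bool, len(universe))
    n_u, n_q = len(universe), len(query)
    # each row of a permuted index matrix is one uniform draw of n_q genes
    perm = rng.permuted(np.tile(np.arange(n_u), (n_draws, 1)), axis=1)[:, :n_q]
    null = ref_mask[perm].sum(axis=1).astype(np.int64)
    mean_null = float(null.mean())
    nes = observed / mean_null if mean_null > 0 else np.nan
    upper = (int(np.sum(null >= observed)) + 1) / (n_draws + 1)
    lower = (int(np.sum(null <= observed)) + 1) / (n_draws + 1)
    p = min(1.0, 2.0 * min(upper, lower))
    return {
        "overlap": observed,
        "NES": float(nes),
        "p": float(p),
        "query_size": n_q,
        "set_size": len(reference),
        "universe_size": n_u,
        "mean_null_overlap": mean_null,
    }
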
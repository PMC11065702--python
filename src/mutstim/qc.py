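"""Two-stage sample quality control.

Stage one applies hard per-sample metric thresholds (read depth, alignment
rate, exome rate for RNA; depth, peak count, alignment rate and FRiP for
ATAC), all strict "below threshold fails" comparisons.  Stage two removes
replicate-correlation outliers: each sample's mean Spearman correlation with
its biological replicates is compared against a data-driven cutoff — the
average cross-pair correlation between two clearly distinct reference groups
(e.g. wild-type macrophages vs wild-type CD8 T cells), or a fixed 0.5 for
cultured samples.  When fewer than three replicates of a group survive, the
three samples with the highest mutual correlations are kept instead.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RNA_METRICS = ("total_reads", "alignment_rate", "exome_rate")
ATAC_METRICS = ("total_reads", "alignment_rate", "frip", "n_peaks")


def metric_filter(
    metrics: pd.DataFrame, assay: str, thresholds: dict | None = None
) -> pd.DataFrame:
    """Apply hard QC thresholds per sample.

    Parameters
    ----------
    metrics
        Per-sample table with columns ``total_reads``, ``alignment_rate``
        and ``exome_rate`` (RNA) or ``total_reads``, ``alignment_rate``,
        ``frip`` and ``n_peaks`` (ATAC).
    assay
        ``"rna"`` or ``"atac"``.
    thresholds
        Optional overrides of the default cutoffs (keys ``min_reads``,
        ``min_alignment_rate``, ``min_exome_rate`` / ``min_peaks``,
        ``min_frip``).

    Returns
    -------
    pandas.DataFrame
        Per sample: ``passed`` flag and a ``fail_reasons`` string (empty if
        passing).  A sample fails iff a metric is strictly below its cutoff.
    """
    from .io import DEFAULT_CONFIG

    assay = assay.lower()
    if assay not in ("rna", "atac"):
        raise ValueError(f"assay must be 'rna' or 'atac', got {assay!r}")
    thr = dict(DEFAULT_CONFIG["qc"][assay])
    if thresholds:
        thr.update(thresholds)

    required = RNA_METRICS if assay == "rna" else ATAC_METRICS
    for col in required:
        if col not in metrics.columns:
            raise ValueError(f"metrics table lacks column {col!r} required for {assay}")
        missing = metrics.index[metrics[col].isna()]
        if len(missing):
            raise ValueError(f"missing metric {col!r} for sample {missing[0]!r}")

    checks = [("total_reads", thr["min_reads"]), ("alignment_rate", thr["min_alignment_rate"])]
    if assay == "rna":
        checks.append(("exome_rate", thr["min_exome_rate"]))
    else:
        checks += [("n_peaks", thr["min_peaks"]), ("frip", thr["min_frip"])]

    reasons = pd.Series("", index=metrics.index, dtype=object)
    for col, cut in checks:
        fail = metrics[col] < cut  # strict "below" fails; equality passes
        reasons[fail] += f"{col}<{cut};"
    out = pd.DataFrame({"passed": reasons == "", "fail_reasons": reasons})
    logger.info("metric filter (%s): %d/%d samples pass", assay, out["passed"].sum(), len(out))
    return out


def pairwise_spearman(expr: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Spearman correlation matrix of an expression matrix
    (genes x samples)."""
    if expr.shape[1] < 2:
        return pd.DataFrame(
            np.ones((expr.shape[1], expr.shape[1])), index=expr.columns, columns=expr.columns
        )
    rho = stats.spearmanr(expr.to_numpy(), axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-sample case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    return pd.DataFrame(rho, index=expr.columns, columns=expr.columns)


def replicate_correlations(expr: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Mean Spearman correlation of each sample with its replicates.

    ``groups`` maps sample id -> replicate group (same genotype, cell type
    and condition).  Samples in singleton groups get ``NaN`` (nothing to
    correlate against) with a logged warning; downstream they pass by
    convention.
    """
    groups = groups.loc[expr.columns]
    means = pd.Series(np.nan, index=expr.columns, name="mean_replicate_correlation")
    for key, members in groups.groupby(groups).groups.items():
        members = list(members)
        if len(members) < 2:
            logger.warning("replicate group %r has a single sample; skipping", key)
            continue
        rho = pairwise_spearman(expr[members]).to_numpy()
        np.fill_diagonal(rho, np.nan)
        means[members] = np.nanmean(rho, axis=1)
    return means


def derive_correlation_cutoff(
    expr: pd.DataFrame,
    group_a,
    group_b,
    cultured: bool = False,
    cultured_cutoff: float = 0.5,
) -> float:
    """Data-driven outlier cutoff: mean Spearman correlation over all cross
    pairs between two reference sample groups (two clearly distinct cell
    types).  In cultured mode a fixed threshold (0.5 by default) is returned
    regardless of the data."""
    if cultured:
        return float(cultured_cutoff)
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both reference groups must be non-empty")
    rho = pairwise_spearman(expr[group_a + group_b])
    cross = rho.loc[group_a, group_b].to_numpy()
    return float(cross.mean())


def remove_outliers(
    correlations: pd.Series,
    cutoff: float,
    groups: pd.Series,
    pairwise: pd.DataFrame,
) -> pd.DataFrame:
    """Exclude replicate-correlation outliers, with the keep-top-3 rescue.

    Samples whose mean replicate correlation falls below ``cutoff`` are
    excluded.  If that leaves fewer than three samples in a group, the
    three-sample subset with the highest mean pairwise correlation is kept
    instead (exhaustive over triples; ties broken by lexicographic sample
    id).  Groups of three or fewer samples are kept whole.

    Parameters
    ----------
    correlations
        Per-sample mean replicate correlation (:func:`replicate_correlations`).
    cutoff
        Exclusion threshold (:func:`derive_correlation_cutoff`).
    groups
        Sample -> replicate group mapping.
    pairwise
        Sample x sample Spearman matrix (:func:`pairwise_spearman`), needed
        for the triple rescue.

    Returns
    -------
    pandas.DataFrame
        Per sample: ``mean_replicate_correlation``, ``cutoff``, ``group``
        and ``decision`` in {kept, excluded, rescued}.
    """
    decisions = pd.Series("kept", index=correlations.index, dtype=object)
    for key, members in groups.loc[correlations.index].groupby(
        groups.loc[correlations.index]
    ).groups.items():
        members = sorted(members)
        if len(members) <= 3:
            continue  # kept whole
        corr = correlations[members]
        surviving = [s for s in members if not (corr[s] < cutoff)]  # NaN passes
        if len(surviving) >= 3:
            for s in members:
                if s not in surviving:
                    decisions[s] = "excluded"
            continue
        # rescue: best triple by mean pairwise correlation; combinations of the
        # sorted member list come out lexicographically, and strict > keeps the
        # first (lexicographically smallest) triple on ties
        best, best_score = None, -np.inf
        for triple in combinations(members, 3):
            score = float(
                np.mean([pairwise.loc[a, b] for a, b in combinations(triple, 2)])
            )
            if score > best_score:
                best, best_score = triple, score
        for s in members:
            decisions[s] = "rescued" if s in best else "excluded"
        logger.info("group %r: fewer than 3 above cutoff, rescued %s", key, best)
    report = pd.DataFrame(
        {
            "mean_replicate_correlation": correlations,
            "cutoff": cutoff,
            "group": groups.loc[correlations.index],
            "decision": decisions,
        }
    )
    n_exc = int((decisions == "excluded").sum())
    logger.info("outlier removal: %d of %d samples excluded", n_exc, len(decisions))
    return report
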
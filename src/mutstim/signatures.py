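"""Two-factor interaction signatures: the five-group classification of genes.

For each gene (and each mutant genotype) the interaction model yields three
log2 fold-change coefficients:

* ``beta_stim`` — stimulation main effect (stimulated vs unstimulated, in
  wild-type cells),
* ``beta_mut``  — mutant main effect (mutant vs wild type, in unstimulated
  cells),
* ``beta_int``  — interaction: how the mutant changes the stimulation
  response (equivalently, how stimulation changes the mutant effect).

Genes whose interaction term is significant are partitioned by comparing the
magnitude of the interaction against each main effect (dominance factor 2 by
default) and by the relative signs:

====================  =========================================================
label                 meaning
====================  =========================================================
de_novo               interaction dominates both main effects (group 1)
mut_enhances_stim     mutant amplifies the stimulation effect (group 2)
mut_reverts_stim      mutant opposes/reverts the stimulation effect (group 3)
stim_enhances_mut     stimulation amplifies the mutant effect (group 4)
stim_reverts_mut      stimulation opposes/reverts the mutant effect (group 5)
minor                 significant but dominated by both main effects
unassigned            interaction not significant
====================  =========================================================
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DE_NOVO = "de_novo"
MUT_ENHANCES_STIM = "mut_enhances_stim"
MUT_REVERTS_STIM = "mut_reverts_stim"
STIM_ENHANCES_MUT = "stim_enhances_mut"
STIM_REVERTS_MUT = "stim_reverts_mut"
MINOR = "minor"
UNASSIGNED = "unassigned"

#: The five assignable signature groups, in their conventional order.
SIGNATURE_GROUPS = (
    DE_NOVO,
    MUT_ENHANCES_STIM,
    MUT_REVERTS_STIM,
    STIM_ENHANCES_MUT,
    STIM_REVERTS_MUT,
)

#: All labels the classifier can emit.
ALL_LABELS = SIGNATURE_GROUPS + (MINOR, UNASSIGNED)


def classify_triple(
    beta_stim: float,
    beta_mut: float,
    beta_int: float,
    significant: bool,
    ratio: float = 2.0,
) -> str:
    """Classify a single (beta_stim, beta_mut, beta_int) coefficient triple.

    Parameters
    ----------
    beta_stim, beta_mut, beta_int
        Log2 fold-change coefficients of the interaction model.
    significant
        Whether the interaction term passed the significance cutoff; if not,
        the gene is ``unassigned``.
    ratio
        Dominance factor: the interaction dominates a main effect when
        ``|beta_int| > ratio * |beta_main|`` (strict inequality).

    Returns
    -------
    str
        One of :data:`ALL_LABELS`.
    """
    if not significant:
        return UNASSIGNED
    a_int = abs(beta_int)
    dom_stim = a_int > ratio * abs(beta_stim)
    dom_mut = a_int > ratio * abs(beta_mut)
    if dom_stim and dom_mut:
        # beta_int == 0 can only reach here with both mains 0 too; that
        # degenerate triple carries no direction and is treated as minor.
        if a_int == 0:
            return MINOR
        return DE_NOVO
    if not dom_stim and not dom_mut:
        return MINOR
    if dom_mut:
        # interaction modifies the stimulation effect
        return MUT_ENHANCES_STIM if np.sign(beta_int) == np.sign(beta_stim) else MUT_REVERTS_STIM
    # dom_stim only: interaction modifies the mutant effect
    return STIM_ENHANCES_MUT if np.sign(beta_int) == np.sign(beta_mut) else STIM_REVERTS_MUT


def classify_signatures(
    fit: pd.DataFrame,
    alpha: float = 0.05,
    ratio: float = 2.0,
) -> pd.Series:
    """Assign one signature label per row of an interaction fit table.

    Parameters
    ----------
    fit
        One row per (gene, mutant) with columns ``beta_stim``, ``beta_mut``,
        ``beta_int`` and ``padj_int`` (BH-adjusted p of the interaction term).
    alpha
        Significance level applied to ``padj_int``; rows at or above it are
        ``unassigned``.
    ratio
        Dominance factor, see :func:`classify_triple`.

    Returns
    -------
    pandas.Series
        Label per row, aligned with ``fit.index``.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if ratio <= 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    required = ["beta_stim", "beta_mut", "beta_int", "padj_int"]
    missing = [c for c in required if c not in fit.columns]
    if missing:
        raise ValueError(f"fit table is missing columns: {missing}")
    bad = fit[required].isna().any(axis=1)
    if bad.any():
        genes = fit.index[bad].tolist()[:5]
        raise ValueError(f"missing coefficient for gene(s): {genes}")
    labels = [
        classify_triple(s, m, i, p < alpha, ratio=ratio)
        for s, m, i, p in zip(
            fit["beta_stim"], fit["beta_mut"], fit["beta_int"], fit["padj_int"]
        )
    ]
    return pd.Series(labels, index=fit.index, name="label")


def signature_prevalence(labels: pd.Series, by: pd.Series | None = None) -> pd.DataFrame:
    """Fraction of each signature group among interaction-significant genes.

    The denominator is the number of interaction-significant genes, i.e. all
    labels except ``unassigned`` — the ``minor`` genes count toward the
    denominator but form their own column.

    Parameters
    ----------
    labels
        Output of :func:`classify_signatures`.
    by
        Optional grouping (e.g. mutant genotype), aligned with ``labels``.
        Without it a single row ``all`` is returned.

    Returns
    -------
    pandas.DataFrame
        One row per group with columns for the five signatures plus
        ``minor``, a ``n_significant`` denominator column, and fractions
        summing to 1 where the denominator is positive (all-zero row with
        ``n_significant`` 0 otherwise).
    """
    if by is None:
        by = pd.Series("all", index=labels.index)
    cols = list(SIGNATURE_GROUPS) + [MINOR]
    rows = {}
    for key, sub in labels.groupby(by):
        sig = sub[sub != UNASSIGNED]
        n = len(sig)
        counts = sig.value_counts()
        if n == 0:
            rows[key] = {c: 0.0 for c in cols} | {"n_significant": 0}
        else:
            rows[key] = {c: counts.get(c, 0) / n for c in cols} | {"n_significant": n}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = by.name or "group"
    return out[cols + ["n_significant"]]


def reversion_shares(
    labels: pd.Series,
    fit: pd.DataFrame,
    mode: str,
    alpha: float = 0.05,
) -> tuple[float, int]:
    """Share of genes whose effect in one factor is reverted by the other.

    ``mutant_reverts_stim``: percentage of genes with a significant
    stimulation effect in wild type (``padj_stim < alpha``) that are labeled
    ``mut_reverts_stim``.  ``stim_reverts_mut``: percentage of genes with a
    significant mutant effect in unstimulated cells (``padj_mut < alpha``)
    that are labeled ``stim_reverts_mut``.

    Returns
    -------
    (share, n)
        Percentage (0–100) and the denominator it refers to.  The share is
        ``nan`` when the denominator is zero.
    """
    if mode == "mutant_reverts_stim":
        denom_mask = fit["padj_stim"] < alpha
        target = MUT_REVERTS_STIM
    elif mode == "stim_reverts_mut":
        denom_mask = fit["padj_mut"] < alpha
        target = STIM_REVERTS_MUT
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    n = int(denom_mask.sum())
    if n == 0:
        return float("nan"), 0
    count = int((labels.loc[fit.index[denom_mask]] == target).sum())
    return 100.0 * count / n, n


def geneset_mean_lfc(fit: pd.DataFrame, genes, coefficient: str) -> tuple[float, int]:
    """Mean log2FC of one coefficient across a gene set.

    Set members absent from the fit are dropped; the count of members
    actually used is returned alongside the mean.
    """
    present = fit.index.intersection(pd.Index(genes))
    if len(present) == 0:
        raise ValueError("no gene-set member present in the fit table")
    values = fit.loc[present, coefficient]
    return float(values.mean()), int(len(present))
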
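"""Normalization and per-gene linear modeling of RNA-seq counts.

The engine follows the standard bulk RNA-seq workflow: trimmed-mean-of-
M-values (TMM) normalization factors, log2 counts-per-million with small
offsets, removal of lowly expressed genes (mean log2CPM below zero),
precision weights from a lowess fit of the mean-variance trend (voom-style),
and per-gene weighted linear models.  Batches (experiment identifiers) enter
either as fixed dummy coefficients or as a one-variance-component random
intercept fitted by maximum likelihood with a profiled variance ratio.
P values are Benjamini-Hochberg adjusted.

No empirical-Bayes moderation of variances is applied: this is a plain
WLS/ML engine with two-sided t/Wald tests on residual degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> pd.Series:
    """Trimmed mean of M-values normalization factors.

    The reference sample is the library whose upper-quartile CPM is closest
    to the mean upper quartile.  For each sample, M (log2 CPM ratio vs the
    reference) and A (mean log2 CPM) are computed over genes expressed in
    both libraries; the most extreme 30% of M on each side and 5% of A are
    trimmed; the factor is 2 to the precision-weighted mean of the surviving
    M values.  Factors are rescaled to geometric mean 1.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"all-zero librar{'y' if len(bad) == 1 else 'ies'}: {bad}")
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")

    cpm = counts.to_numpy(dtype=float) / lib.to_numpy()
    uq = np.array([np.quantile(cpm[:, j][cpm[:, j] > 0] if (cpm[:, j] > 0).any() else cpm[:, j], 0.75) for j in range(cpm.shape[1])])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))

    N = lib.to_numpy()
    c_ref = counts.to_numpy(dtype=float)[:, ref_idx]
    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            continue
        c = counts.to_numpy(dtype=float)[:, j]
        ok = (c > 0) & (c_ref > 0)
        if ok.sum() == 0:
            continue
        p, pr = c[ok] / N[j], c_ref[ok] / N[ref_idx]
        M = np.log2(p / pr)
        A = 0.5 * np.log2(p * pr)
        n = len(M)
        loM, hiM = int(np.floor(n * logratio_trim)), n - int(np.floor(n * logratio_trim))
        loA, hiA = int(np.floor(n * abundance_trim)), n - int(np.floor(n * abundance_trim))
        rank_M = stats.rankdata(M, method="ordinal") - 1
        rank_A = stats.rankdata(A, method="ordinal") - 1
        keep = (rank_M >= loM) & (rank_M < hiM) & (rank_A >= loA) & (rank_A < hiA)
        if keep.sum() == 0:
            continue
        # inverse asymptotic variance of M as precision weight
        v = (N[j] - c[ok]) / (N[j] * c[ok]) + (N[ref_idx] - c_ref[ok]) / (
            N[ref_idx] * c_ref[ok]
        )
        f = np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep])
        factors[j] = 2.0**f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="norm_factor")


@dataclass
class NormalizedMatrix:
    """log2CPM values plus the library sizes and normalization factors that
    produced them."""

    values: pd.DataFrame
    lib_size: pd.Series
    factors: pd.Series

    @property
    def effective_lib(self) -> pd.Series:
        return self.lib_size * self.factors


def log2_cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> NormalizedMatrix:
    """log2 counts per million: ``log2((count + 0.5) / (lib*factor + 1) * 1e6)``.

    The half-count and one-read offsets avoid log-of-zero and match the
    common voom convention.
    """
    lib = counts.sum(axis=0).astype(float)
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns, name="norm_factor")
    eff = (lib * factors).to_numpy()
    values = np.log2((counts.to_numpy(dtype=float) + 0.5) / (eff + 1.0) * 1e6)
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=counts.index, columns=counts.columns),
        lib_size=lib,
        factors=factors,
    )


def filter_low_expression(norm: NormalizedMatrix | pd.DataFrame) -> pd.Series:
    """Keep genes whose mean log2CPM across samples is at least zero."""
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    if values.shape[0] == 0:
        return pd.Series(dtype=bool)
    return values.mean(axis=1) >= 0


# ---------------------------------------------------------------------------
# precision weights (mean-variance trend)
# ---------------------------------------------------------------------------

def mean_variance_weights(
    norm: NormalizedMatrix,
    design: pd.DataFrame | np.ndarray,
    span: float = 0.5,
    sd_floor: float = 0.05,
) -> pd.DataFrame:
    """Observation-level precision weights from the mean-variance trend.

    Per gene an unweighted least-squares fit against ``design`` yields the
    residual standard deviation; a lowess smoother of sqrt(sd) against mean
    log2 count captures the mean-variance trend; each observation's weight
    is the predicted trend value at its fitted log2 count raised to the
    power -4.  The trend is clamped below at ``sd_floor`` for stability.
    """
    y = norm.values.to_numpy()
    X = np.asarray(design, dtype=float)
    n_genes, n_samples = y.shape
    if X.shape[0] != n_samples:
        raise ValueError("design rows must match number of samples")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if n_samples - rank < 1:
        raise ValueError("no residual degrees of freedom for the variance trend")
    if n_genes < 2:
        logger.warning("fewer than 2 genes: returning unit weights")
        return pd.DataFrame(1.0, index=norm.values.index, columns=norm.values.columns)

    pinv = np.linalg.pinv(X)
    beta = y @ pinv.T                      # genes x p
    fitted = beta @ X.T                    # genes x samples
    resid = y - fitted
    sigma = np.sqrt(np.sum(resid**2, axis=1) / (n_samples - rank))

    log2lib = np.log2(norm.effective_lib.to_numpy() + 1.0)
    sx = y.mean(axis=1) + log2lib.mean() - np.log2(1e6)   # mean log2 count
    sy = np.sqrt(np.maximum(sigma, 0.0))  # sqrt of residual sd; pred^-4 = 1/variance

    trend = lowess(sy, sx, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], np.sqrt(sd_floor))

    fitted_count = fitted + log2lib[None, :] - np.log2(1e6)
    pred = np.interp(fitted_count, tx, ty)
    weights = pred**-4.0
    return pd.DataFrame(weights, index=norm.values.index, columns=norm.values.columns)


# ---------------------------------------------------------------------------
# model specification and fitting
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Per-gene linear model specification.

    ``response`` is a genes x samples matrix (log2CPM), ``design`` the
    samples x coefficients fixed-effect matrix (including an intercept),
    ``weights`` optional observation precision weights, ``batch`` an
    optional experiment-identifier factor handled per ``batch_mode``
    (``"fixed"`` dummy columns or ``"random_intercept"`` with a profiled
    variance ratio, fitted by maximum likelihood)."""

    response: pd.DataFrame
    design: pd.DataFrame
    weights: pd.DataFrame | None = None
    batch: pd.Series | None = None
    batch_mode: str = "fixed"


def make_design(
    samples: pd.DataFrame,
    genotype: str = "genotype",
    condition: str | None = None,
    ref_genotype: str | None = None,
    ref_condition: str | None = None,
    interaction: bool = False,
) -> pd.DataFrame:
    """Build a treatment-coded design matrix from a sample sheet.

    With ``condition`` and ``interaction`` the columns are ``intercept``,
    ``stim`` (non-baseline condition), ``mut_<genotype>`` per non-reference
    genotype and ``int_<genotype>`` interaction terms — the two-factor
    interaction model.  Without ``condition``, just intercept plus one
    mutant dummy per non-reference genotype (the homeostatic model).
    """
    geno = samples[genotype].astype(str)
    levels = list(dict.fromkeys(geno))
    ref_g = ref_genotype if ref_genotype is not None else levels[0]
    if ref_g not in levels:
        raise ValueError(f"reference genotype {ref_g!r} not present")
    X = pd.DataFrame({"intercept": 1.0}, index=samples.index)
    stim = None
    if condition is not None:
        cond = samples[condition].astype(str)
        clevels = list(dict.fromkeys(cond))
        ref_c = ref_condition if ref_condition is not None else clevels[0]
        if ref_c not in clevels:
            raise ValueError(f"reference condition {ref_c!r} not present")
        stim = (cond != ref_c).astype(float)
        X["stim"] = stim
    for g in levels:
        if g == ref_g:
            continue
        dummy = (geno == g).astype(float)
        X[f"mut_{g}"] = dummy
        if interaction:
            if stim is None:
                raise ValueError("interaction requires a condition factor")
            X[f"int_{g}"] = dummy * stim
    return X


def _batch_dummies(batch: pd.Series) -> pd.DataFrame:
    levels = list(dict.fromkeys(batch.astype(str)))
    return pd.DataFrame(
        {f"batch_{b}": (batch.astype(str) == b).astype(float) for b in levels[1:]},
        index=batch.index,
    )


def _check_aliasing(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns greedily
        aliased, kept = [], []
        for j in range(X.shape[1]):
            trial = X[:, kept + [j]]
            if np.linalg.matrix_rank(trial) > len(kept):
                kept.append(j)
            else:
                aliased.append(names[j])
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")


def _wls_gene(y, X, w):
    """Weighted least squares for one gene: returns beta, se, df."""
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    df = X.shape[0] - X.shape[1]
    s2 = float(resid @ resid) / df
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(s2 * np.diag(XtX_inv))
    return beta, se, df


def _ml_random_intercept(y, X, w, Z, tol=1e-8):
    """One-variance-component random-intercept fit by maximum likelihood.

    The variance ratio lambda = var(batch)/var(resid) is profiled out:
    for fixed lambda the covariance is V0 = diag(1/w) + lambda Z Z', GLS
    gives beta and the ML residual variance in closed form, and lambda is
    maximized by bounded scalar search on the log scale (plus the lambda=0
    boundary).  Returns beta, se, df, converged.
    """
    n, p = X.shape
    Winv = np.diag(1.0 / w)
    ZZt = Z @ Z.T

    def profile_negll(log10_lam):
        lam = 10.0**log10_lam
        V0 = Winv + lam * ZZt
        try:
            L = np.linalg.cholesky(V0)
        except np.linalg.LinAlgError:
            return np.inf, None
        Xs = solve_triangular(L, X, lower=True)
        ys = solve_triangular(L, y, lower=True)
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        r = ys - Xs @ beta
        rss = float(r @ r)
        sigma2 = rss / n
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        nll = 0.5 * (n * np.log(sigma2) + logdet)
        return nll, (beta, sigma2, Xs)

    res = optimize.minimize_scalar(
        lambda t: profile_negll(t)[0],
        bounds=(-8.0, 3.0),
        method="bounded",
        options={"xatol": tol},
    )
    candidates = [res.x, -12.0]  # -12 ~ lambda -> 0 boundary
    best = min(candidates, key=lambda t: profile_negll(t)[0])
    nll, payload = profile_negll(best)
    if payload is None:
        return None
    beta, sigma2, Xs = payload
    XtX_inv = np.linalg.inv(Xs.T @ Xs)
    se = np.sqrt(sigma2 * n / (n - p) * np.diag(XtX_inv))
    df = n - p
    return beta, se, df, bool(res.success)


def fit_linear_models(spec: ModelSpec) -> pd.DataFrame:
    """Fit the per-gene linear models and test every coefficient.

    Returns a long-format table with one row per (gene, coefficient):
    ``log2FC``, ``SE``, ``df``, ``p`` (two-sided t/Wald), ``padj``
    (Benjamini-Hochberg across the whole table) and ``converged``.
    """
    y_all = spec.response.to_numpy(dtype=float)
    genes = spec.response.index
    samples = spec.response.columns
    X = spec.design.loc[samples].to_numpy(dtype=float)
    coef_names = list(spec.design.columns)

    mode = spec.batch_mode
    Z = None
    if spec.batch is not None and mode == "fixed":
        B = _batch_dummies(spec.batch.loc[samples])
        if not B.empty:
            Xb = np.hstack([X, B.to_numpy(dtype=float)])
            if np.linalg.matrix_rank(Xb) < np.linalg.matrix_rank(X) + B.shape[1]:
                logger.warning("batch factor aliased with the design; dropping batch term")
            else:
                X = Xb
                coef_names = coef_names + list(B.columns)
    elif spec.batch is not None and mode == "random_intercept":
        batch = spec.batch.loc[samples].astype(str)
        levels = list(dict.fromkeys(batch))
        Z = np.stack([(batch == b).to_numpy(dtype=float) for b in levels], axis=1)
        # confounded batch cannot be separated from the contrasts: fall back
        if np.linalg.matrix_rank(np.hstack([X, Z])) < np.linalg.matrix_rank(X) + len(levels) - 1:
            logger.warning(
                "batch factor confounded with the design; falling back to fixed mode"
            )
            Z = None
            mode = "fixed"
    elif mode not in ("fixed", "random_intercept"):
        raise ValueError(f"unknown batch_mode: {mode!r}")

    _check_aliasing(X, coef_names)

    W = (
        spec.weights.loc[genes, samples].to_numpy(dtype=float)
        if spec.weights is not None
        else np.ones_like(y_all)
    )

    rows = []
    p_fixed = X.shape[1]
    for i, gene in enumerate(genes):
        y, w = y_all[i], W[i]
        converged = True
        if Z is not None:
            result = _ml_random_intercept(y, X, w, Z)
            if result is None:
                beta, se, df = _wls_gene(y, X, w)
                converged = False
            else:
                beta, se, df, converged = result
        else:
            beta, se, df = _wls_gene(y, X, w)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), df)
        for j, name in enumerate(coef_names[:len(beta)]):
            rows.append((gene, name, beta[j], se[j], df, p[j], converged))

    out = pd.DataFrame(
        rows, columns=["gene", "coefficient", "log2FC", "SE", "df", "p", "converged"]
    )
    # BH across all genuine comparisons; intercept and batch nuisance rows are
    # not hypotheses of interest and stay unadjusted
    is_test = ~out["coefficient"].isin(["intercept"]) & ~out["coefficient"].str.startswith("batch_")
    out["padj"] = np.nan
    out.loc[is_test, "padj"] = bh_adjust(out.loc[is_test, "p"].to_numpy())
    logger.info(
        "fitted %d genes x %d coefficients (%s batch mode)",
        len(genes), p_fixed, mode if spec.batch is not None else "no",
    )
    return out


def pivot_fit(fit: pd.DataFrame, value: str = "log2FC") -> pd.DataFrame:
    """Wide view of a long fit table: genes x coefficients for one column."""
    return fit.pivot(index="gene", columns="coefficient", values=value)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order.

    ``padj_(i) = min_{j >= i} p_(j) * m / j`` over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out
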
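"""Negative-binomial differential expression for count tables.

A compact NB-GLM stack: median-of-ratios size factors, the cross-assay
normalization rule (T>C and non-T>C counts are always modelled with offsets
computed from *total* reads), method-of-moments dispersion with trend
shrinkage, a vectorized IRLS Wald test, BH adjustment and DEG calling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError, ValidationError

READ_CLASSES = ("total", "tc", "non_tc")

DEFAULT_ALPHA = 0.05
DEFAULT_LFC_THRESHOLD = 1.5
DEFAULT_MIN_FILTER_MEAN = 5.0
DISPERSION_FLOOR = 1e-8


@dataclass
class CountMatrix:
    """Genes x samples integer counts with sample metadata.

    ``meta`` is indexed by sample id with columns condition/assay/replicate.
    ``size_factors``, when set, are the per-sample normalization factors to be
    used as GLM offsets; for read_class 'tc'/'non_tc' they must come from the
    paired total matrix (see :func:`apply_cross_normalization`).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    read_class: str = "total"
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.read_class not in READ_CLASSES:
            raise ValidationError(f"unknown read_class {self.read_class!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.meta.index)
        if missing:
            raise ValidationError(f"samples missing from metadata: {sorted(missing)}")
        for col in ("condition",):
            if col not in self.meta.columns:
                raise ValidationError(f"metadata missing column {col!r}")
        if self.size_factors is not None:
            missing = set(self.counts.columns) - set(self.size_factors.index)
            if missing:
                raise ValidationError(f"size factor missing for samples: {sorted(missing)}")

    @property
    def samples(self):
        return list(self.counts.columns)

    @property
    def genes(self):
        return list(self.counts.index)


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios size factors, rescaled to geometric mean 1.

    The per-gene reference is the geometric mean across samples over genes
    with all-positive counts; if no such gene exists, genes positive in at
    least half the samples are used instead (with a warning).
    """
    mat = counts.to_numpy(dtype=float)
    if mat.size == 0:
        raise ValidationError("empty count matrix")
    if mat.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns, name="size_factor")
    all_pos = (mat > 0).all(axis=1)
    if all_pos.any():
        sub = mat[all_pos]
        log_ref = np.log(sub).mean(axis=1)
        log_ratios = np.log(sub) - log_ref[:, None]
        log_sf = np.median(log_ratios, axis=0)
    else:
        warnings.warn("no gene has positive counts in all samples; "
                      "falling back to a positive-subset reference", stacklevel=2)
        mostly_pos = (mat > 0).sum(axis=1) >= mat.shape[1] / 2
        if not mostly_pos.any():
            raise EstimationError("counts too sparse for size-factor estimation")
        sub = mat[mostly_pos]
        with np.errstate(divide="ignore"):
            logs = np.where(sub > 0, np.log(sub), np.nan)
        log_ref = np.nanmean(logs, axis=1)
        log_sf = np.nanmedian(logs - log_ref[:, None], axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def apply_cross_normalization(cm: CountMatrix, factors: pd.Series) -> CountMatrix:
    """Attach size factors computed on total reads to a tc/non-tc matrix.

    The labeled-read counts are never used to derive their own factors: a
    global change in the labeled fraction would otherwise be normalized away.
    """
    missing = set(cm.counts.columns) - set(factors.index)
    if missing:
        raise ValidationError(f"size factor missing for samples: {sorted(missing)}")
    return CountMatrix(counts=cm.counts, meta=cm.meta, read_class=cm.read_class,
                       size_factors=factors.loc[cm.counts.columns].copy())


def cpm(counts: pd.DataFrame, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million over (normalized) library sizes."""
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    lib = library_sizes.loc[counts.columns]
    if (lib <= 0).any():
        raise ValidationError("library sizes must be positive")
    return counts * 1e6 / lib


def _group_labels(cm: CountMatrix, by=("condition",)):
    cols = [c for c in by if c in cm.meta.columns]
    meta = cm.meta.loc[cm.counts.columns]
    return meta[cols].astype(str).agg("|".join, axis=1)


def estimate_dispersion(cm: CountMatrix, factors: pd.Series | None = None,
                        group_by=("condition", "assay"),
                        prior_df: float = 12.0) -> pd.Series:
    """Per-gene NB dispersion: method of moments shrunk toward a mean trend.

    Normalized counts are pooled within condition(xassay) groups to get a
    per-gene moments estimate ``(s2 - mu) / mu^2``; a parametric trend
    ``a/mu + b`` is fitted across genes and each gene's estimate is averaged
    with the trend with weight ``df / (df + prior_df)``.  With fewer than two
    replicates in every group, a global trend-only estimate is returned with a
    warning.
    """
    if factors is None:
        factors = cm.size_factors if cm.size_factors is not None \
            else size_factors_median_of_ratios(cm.counts)
    norm = cm.counts.to_numpy(dtype=float) / factors.loc[cm.counts.columns].to_numpy()
    groups = _group_labels(cm, by=group_by)
    labels = groups.unique()

    n_genes = norm.shape[0]
    sse = np.zeros(n_genes)
    df = 0
    base_mean = norm.mean(axis=1)
    for lab in labels:
        idx = np.flatnonzero((groups == lab).to_numpy())
        if idx.size < 2:
            continue
        sub = norm[:, idx]
        sse += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += idx.size - 1

    if df < 1:
        warnings.warn("no replicated group; using a single global dispersion",
                      stacklevel=2)
        mu = max(base_mean.mean(), 1e-8)
        s2 = float(((norm - base_mean[:, None]) ** 2).mean())
        alpha = max((s2 - mu) / mu**2, DISPERSION_FLOOR)
        return pd.Series(np.full(n_genes, alpha), index=cm.counts.index, name="dispersion")

    s2 = sse / df
    mu = np.maximum(base_mean, 1e-8)
    raw = (s2 - mu) / mu**2

    # parametric trend a/mu + b, least squares over informative genes
    ok = (base_mean >= 1.0) & np.isfinite(raw)
    a, b = 0.0, 0.0
    if ok.sum() >= 10:
        X = np.column_stack([1.0 / mu[ok], np.ones(ok.sum())])
        coef, *_ = np.linalg.lstsq(X, raw[ok], rcond=None)
        a, b = max(coef[0], 0.0), max(coef[1], 0.0)
    trend = np.maximum(a / mu + b, DISPERSION_FLOOR)
    if not (a > 0 or b > 0):
        trend = np.maximum(np.full(n_genes, np.nanmedian(np.maximum(raw, 0.0))),
                           DISPERSION_FLOOR)

    w = df / (df + prior_df)
    shrunk = w * np.maximum(raw, 0.0) + (1 - w) * trend
    shrunk = np.maximum(shrunk, DISPERSION_FLOOR)
    return pd.Series(shrunk, index=cm.counts.index, name="dispersion")


# ---------------------------------------------------------------------------
# NB GLM via vectorized IRLS
# ---------------------------------------------------------------------------

def nb_irls(y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: np.ndarray,
            max_iter: int = 100, tol: float = 1e-10):
    """Fit per-gene NB log-link GLMs, vectorized over genes.

    Parameters: ``y`` (G, S) counts, ``X`` (S, P) design, ``offset`` (S,) or
    (G, S) log-scale offsets, ``alpha`` (G,) dispersions.  Returns
    ``(beta, cov, converged)`` with ``beta`` (G, P), ``cov`` (G, P, P) the
    inverse expected Fisher information, and a convergence mask.
    """
    y = np.asarray(y, dtype=float)
    G, S = y.shape
    P = X.shape[1]
    offset = np.broadcast_to(np.asarray(offset, dtype=float), (G, S))
    alpha = np.asarray(alpha, dtype=float)

    mu0 = np.maximum((y / np.exp(offset)).mean(axis=1), 1e-4)
    beta = np.zeros((G, P))
    beta[:, 0] = np.log(mu0)
    converged = np.zeros(G, dtype=bool)
    XtWX = None
    for _ in range(max_iter):
        eta = offset + beta @ X.T
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        W = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset) + (y - mu) / mu
        XtWX = np.einsum("gs,sp,sq->gpq", W, X, X)
        XtWX += np.eye(P) * 1e-9
        XtWz = np.einsum("gs,gs,sp->gp", W, z, X)
        new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        step = np.abs(new - beta).max(axis=1)
        beta = new
        converged = step < tol
        if converged.all():
            break
    cov = np.linalg.inv(XtWX)
    return beta, cov, converged


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood (used by the oracle tests and the LRT option)."""
    if alpha <= 0:
        return float(stats.poisson.logpmf(y, mu).sum())
    r = 1.0 / alpha
    p = r / (r + mu)
    return float(stats.nbinom.logpmf(y, r, p).sum())


def _prepare_two_condition(cm: CountMatrix, conditions=None):
    meta = cm.meta.loc[cm.counts.columns]
    if conditions is None:
        conditions = list(pd.unique(meta["condition"]))
    if len(conditions) != 2:
        raise EstimationError(
            f"two-condition design required, got conditions {conditions!r}")
    ind = (meta["condition"] == conditions[1]).to_numpy(dtype=float)
    if ind.min() == ind.max():
        raise EstimationError("all samples in one condition")
    X = np.column_stack([np.ones_like(ind), ind])
    return X, conditions


def nb_wald_test(cm: CountMatrix, factors: pd.Series | None = None,
                 dispersions: pd.Series | None = None, conditions=None,
                 min_filter_mean: float = DEFAULT_MIN_FILTER_MEAN,
                 use_lrt: bool = False) -> pd.DataFrame:
    """Two-condition NB-GLM Wald test with size-factor offsets.

    Returns one row per gene: base_mean (mean normalized count), log2_fc with
    its SE, the Wald statistic, p_value and BH-adjusted p_adj.  Genes with
    base_mean below ``min_filter_mean`` are excluded from BH (status
    'low_count', p_adj NaN).  Genes where one condition is all zeros are fit
    with a 0.5-count ridge and flagged 'zero_ridge'.  ``use_lrt=True`` swaps
    the Wald p-value for a likelihood-ratio test against the intercept model.
    """
    if factors is None:
        factors = cm.size_factors if cm.size_factors is not None \
            else size_factors_median_of_ratios(cm.counts)
    factors = factors.loc[cm.counts.columns]
    X, conditions = _prepare_two_condition(cm, conditions)
    y = cm.counts.to_numpy(dtype=float)
    if dispersions is None:
        dispersions = estimate_dispersion(
            CountMatrix(cm.counts, cm.meta, cm.read_class, factors))
    alpha = dispersions.loc[cm.counts.index].to_numpy()
    offset = np.log(factors.to_numpy())

    # ridge genes with an all-zero condition to keep estimates finite
    cond1 = X[:, 1] == 1.0
    zero_ridge = (y[:, ~cond1].sum(axis=1) == 0) | (y[:, cond1].sum(axis=1) == 0)
    y_fit = y.copy()
    y_fit[zero_ridge] += 0.5

    beta, cov, converged = nb_irls(y_fit, X, offset, alpha)
    ln2 = np.log(2.0)
    log2_fc = beta[:, 1] / ln2
    se = np.sqrt(np.maximum(cov[:, 1, 1], 0.0)) / ln2
    wald = np.divide(log2_fc, se, out=np.zeros_like(se), where=se > 0)
    if use_lrt:
        p = np.empty(len(y))
        X0 = X[:, :1]
        beta0, _, _ = nb_irls(y_fit, X0, offset, alpha)
        for g in range(len(y)):
            mu1 = np.exp(offset + X @ beta[g])
            mu0 = np.exp(offset + X0 @ beta0[g])
            lr = 2.0 * (nb_loglik(y_fit[g], mu1, alpha[g]) - nb_loglik(y_fit[g], mu0, alpha[g]))
            p[g] = stats.chi2.sf(max(lr, 0.0), df=1)
    else:
        p = 2.0 * stats.norm.sf(np.abs(wald))

    base_mean = (y / factors.to_numpy()).mean(axis=1)
    low = base_mean < min_filter_mean
    p_adj = np.full(len(y), np.nan)
    keep = ~low
    if keep.any():
        p_adj[keep] = bh_adjust(p[keep])

    status = np.where(low, "low_count", np.where(zero_ridge, "zero_ridge",
                      np.where(converged, "ok", "no_convergence")))
    return pd.DataFrame(
        {
            "gene_id": cm.counts.index,
            "base_mean": base_mean,
            "log2_fc": log2_fc,
            "lfc_se": se,
            "wald_stat": wald,
            "p_value": p,
            "p_adj": p_adj,
            "status": status,
        }
    ).set_index("gene_id")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_degs(results: pd.DataFrame, alpha: float = DEFAULT_ALPHA,
              lfc_threshold: float = DEFAULT_LFC_THRESHOLD):
    """Split results into up/down DEG sets: p_adj < alpha and |log2FC| > threshold."""
    sig = results["p_adj"] < alpha
    up = set(results.index[sig & (results["log2_fc"] > lfc_threshold)])
    down = set(results.index[sig & (results["log2_fc"] < -lfc_threshold)])
    assert not up & down
    return up, down
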
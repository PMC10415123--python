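"""Joint transcriptome/translatome modelling and regulation-mode classification.

Fits, per gene, an NB-GLM over the combined RNA and TRAP samples with terms
condition + assay + condition:assay (total-read size factors as offsets).  The
interaction coefficient is the translation-efficiency change; the within-assay
condition contrasts give the RNA and TRAP effects.  Genes are then classified
into the four regulation modes by the significance pattern of the three
effects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .differential_expression import (
    CountMatrix,
    bh_adjust,
    estimate_dispersion,
    nb_irls,
)
from .errors import EstimationError, ValidationError

CATEGORIES = ("forwarded", "exclusive", "intensified", "buffered", "undetermined")


def _combine(rna: CountMatrix, trap: CountMatrix):
    if list(rna.counts.index) != list(trap.counts.index):
        raise ValidationError("RNA and TRAP matrices must share the gene universe")
    counts = pd.concat([rna.counts, trap.counts], axis=1)
    if counts.columns.duplicated().any():
        raise ValidationError("duplicate sample ids across assays")
    meta = pd.concat([rna.meta.loc[rna.counts.columns],
                      trap.meta.loc[trap.counts.columns]])
    meta = meta.copy()
    meta.loc[rna.counts.columns, "assay_role"] = "rna"
    meta.loc[trap.counts.columns, "assay_role"] = "trap"
    return counts, meta


def fit_interaction_model(rna: CountMatrix, trap: CountMatrix,
                          size_factors: pd.Series, conditions=None,
                          dispersions: pd.Series | None = None,
                          min_filter_mean: float = 5.0) -> pd.DataFrame:
    """Per-gene condition x assay interaction model.

    ``size_factors`` must cover every sample of both assays and be computed
    from total reads.  Returns a DataFrame indexed by gene with log2 effects
    ``lfc_rna`` / ``lfc_trap`` / ``lfc_te`` (interaction), their Wald p-values
    and BH-adjusted values (adjusted per effect across genes).
    """
    counts, meta = _combine(rna, trap)
    missing = set(counts.columns) - set(size_factors.index)
    if missing:
        raise ValidationError(f"size factor missing for samples: {sorted(missing)}")
    if conditions is None:
        conditions = list(pd.unique(meta["condition"]))
    if len(conditions) != 2:
        raise EstimationError(f"two conditions required, got {conditions!r}")
    for role in ("rna", "trap"):
        for cond in conditions:
            n = ((meta["assay_role"] == role) & (meta["condition"] == cond)).sum()
            if n < 2:
                raise EstimationError(
                    f"need >= 2 replicates per condition per assay "
                    f"(got {n} for {role}/{cond})")

    cond_ind = (meta["condition"] == conditions[1]).to_numpy(dtype=float)
    assay_ind = (meta["assay_role"] == "trap").to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(cond_ind), cond_ind, assay_ind,
                         cond_ind * assay_ind])

    factors = size_factors.loc[counts.columns]
    if dispersions is None:
        # dispersion shared across assays: pooled within condition x assay groups
        cm_all = CountMatrix(counts, meta.assign(assay=meta["assay_role"]),
                             read_class=rna.read_class, size_factors=factors)
        dispersions = estimate_dispersion(cm_all, factors, group_by=("condition", "assay"))
    alpha = dispersions.loc[counts.index].to_numpy()

    y = counts.to_numpy(dtype=float)
    y_fit = y.copy()
    # ridge genes with an all-zero design cell
    cells = [np.flatnonzero((cond_ind == c) & (assay_ind == a))
             for c in (0.0, 1.0) for a in (0.0, 1.0)]
    zero_ridge = np.zeros(len(y), dtype=bool)
    for idx in cells:
        zero_ridge |= y[:, idx].sum(axis=1) == 0
    y_fit[zero_ridge] += 0.5

    beta, cov, converged = nb_irls(y_fit, X, np.log(factors.to_numpy()), alpha)
    ln2 = np.log(2.0)
    lfc_rna = beta[:, 1] / ln2
    lfc_te = beta[:, 3] / ln2
    lfc_trap = (beta[:, 1] + beta[:, 3]) / ln2
    se_rna = np.sqrt(np.maximum(cov[:, 1, 1], 0.0)) / ln2
    se_te = np.sqrt(np.maximum(cov[:, 3, 3], 0.0)) / ln2
    var_trap = cov[:, 1, 1] + cov[:, 3, 3] + 2.0 * cov[:, 1, 3]
    se_trap = np.sqrt(np.maximum(var_trap, 0.0)) / ln2

    def wald_p(lfc, se):
        z = np.divide(lfc, se, out=np.zeros_like(se), where=se > 0)
        return 2.0 * stats.norm.sf(np.abs(z))

    p_rna = wald_p(lfc_rna, se_rna)
    p_trap = wald_p(lfc_trap, se_trap)
    p_te = wald_p(lfc_te, se_te)

    base_mean = (y / factors.to_numpy()).mean(axis=1)
    keep = base_mean >= min_filter_mean
    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "lfc_rna": lfc_rna,
            "lfc_trap": lfc_trap,
            "lfc_te": lfc_te,
            "p_rna": p_rna,
            "p_trap": p_trap,
            "p_te": p_te,
            "status": np.where(~keep, "low_count",
                               np.where(zero_ridge, "zero_ridge",
                                        np.where(converged, "ok", "no_convergence"))),
        },
        index=counts.index,
    )
    for eff in ("rna", "trap", "te"):
        adj = np.full(len(out), np.nan)
        if keep.any():
            adj[keep] = bh_adjust(out.loc[keep, f"p_{eff}"].to_numpy())
        out[f"padj_{eff}"] = adj
    return out


def classify_regulation(results: pd.DataFrame, alpha: float = 0.05,
                        lfc_threshold: float = 0.0,
                        require_same_sign_forwarded: bool = True) -> pd.Series:
    """Assign each gene one of the four regulation modes (or 'undetermined').

    With S(x) = significant (adjusted p < alpha and |lfc| > lfc_threshold):
    intensified = S(TE) & S(RNA), same sign; buffered = S(TE) & S(RNA),
    opposite signs; exclusive = S(TE) & !S(RNA); forwarded = S(RNA) & S(TRAP)
    & !S(TE) (same-sign RNA/TRAP by default); everything else undetermined.
    """
    for col in ("lfc_rna", "lfc_trap", "lfc_te", "padj_rna", "padj_trap", "padj_te"):
        if col not in results.columns:
            raise ValidationError(f"results missing column {col!r}")

    def sig(eff):
        p = results[f"padj_{eff}"]
        return (p < alpha) & (results[f"lfc_{eff}"].abs() > lfc_threshold) & p.notna()

    s_rna, s_trap, s_te = sig("rna"), sig("trap"), sig("te")
    same_sign = np.sign(results["lfc_te"]) == np.sign(results["lfc_rna"])
    fwd_sign_ok = (np.sign(results["lfc_rna"]) == np.sign(results["lfc_trap"])) \
        if require_same_sign_forwarded else pd.Series(True, index=results.index)

    cat = pd.Series("undetermined", index=results.index, name="category")
    cat[s_te & s_rna & same_sign] = "intensified"
    cat[s_te & s_rna & ~same_sign] = "buffered"
    cat[s_te & ~s_rna] = "exclusive"
    cat[~s_te & s_rna & s_trap & fwd_sign_ok] = "forwarded"
    return cat


def category_recovery_report(called: pd.Series, planted: pd.Series):
    """Confusion matrix plus per-mode precision/recall for a planted simulation.

    ``called`` and ``planted`` are gene-indexed Series; planted 'null' genes
    are expected to be called 'undetermined'.
    """
    planted = planted.reindex(called.index)
    if planted.isna().any():
        raise ValidationError("planted modes missing for some genes")
    truth = planted.replace({"null": "undetermined"})
    rows = sorted(truth.unique())
    confusion = pd.crosstab(truth, called).reindex(
        index=rows, columns=list(CATEGORIES), fill_value=0)
    confusion.index.name = "planted"
    confusion.columns.name = "called"

    metrics = []
    for mode in CATEGORIES:
        tp = int(confusion.loc[mode, mode]) if mode in confusion.index else 0
        n_planted = int(confusion.loc[mode].sum()) if mode in confusion.index else 0
        n_called = int(confusion[mode].sum())
        metrics.append(
            {
                "mode": mode,
                "n_planted": n_planted,
                "n_called": n_called,
                "recall": tp / n_planted if n_planted else np.nan,
                "precision": tp / n_called if n_called else np.nan,
            }
        )
    return confusion, pd.DataFrame(metrics).set_index("mode")
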
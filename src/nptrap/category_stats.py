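"""Gene-category statistics: ECDF shifts, group comparisons, ORA.

Mann-Whitney U comparisons of fold-change distributions for annotated gene
sets against the background, pairwise comparisons of per-gene nascent
proportions across groups, ORF-length stratification with a trend statistic,
and hypergeometric over-representation analysis against user-supplied sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential_expression import bh_adjust
from .errors import ValidationError

DEFAULT_MIN_SET_SIZE = 5
EXACT_MAX_N = 16  # exact Mann-Whitney p when n_x + n_y <= this and no ties


@dataclass
class GeneSet:
    name: str
    members: set
    source: str = ""

    def __post_init__(self) -> None:
        self.members = set(self.members)
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")


@dataclass
class ShiftTestResult:
    set_name: str
    n_set: int
    n_background: int
    u_stat: float
    p_value: float
    median_shift: float
    ecdf_set: pd.DataFrame = field(repr=False, default=None)
    ecdf_background: pd.DataFrame = field(repr=False, default=None)


def mann_whitney_u(x, y, alternative: str = "two-sided"):
    """Mann-Whitney U for x vs y with midrank ties.

    Exact p by enumeration when the pooled sample is small (<= 16) and
    tie-free; otherwise the normal approximation with tie-corrected variance
    and continuity correction.  Returns ``(U_x, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _ecdf(values: np.ndarray) -> pd.DataFrame:
    v = np.sort(values)
    return pd.DataFrame({"value": v, "cum_frac": np.arange(1, len(v) + 1) / len(v)})


def ecdf_shift(gene_set: GeneSet, lfc_by_gene: pd.Series,
               min_set_size: int = DEFAULT_MIN_SET_SIZE):
    """Compare a gene set's fold-change distribution to all other genes.

    The background is the universe minus the set, avoiding self-comparison.
    Returns a :class:`ShiftTestResult` or None if fewer than ``min_set_size``
    members are present in the universe (skipped with a warning).
    """
    lfc = lfc_by_gene.dropna()
    members = gene_set.members & set(lfc.index)
    if len(members) < min_set_size:
        warnings.warn(f"gene set {gene_set.name!r}: only {len(members)} members "
                      "in the universe; skipped", stacklevel=2)
        return None
    in_set = lfc.loc[sorted(members)].to_numpy()
    background = lfc.drop(index=sorted(members)).to_numpy()
    if background.size == 0:
        raise ValidationError("background is empty")
    u, p = mann_whitney_u(in_set, background)
    return ShiftTestResult(
        set_name=gene_set.name,
        n_set=len(in_set),
        n_background=len(background),
        u_stat=u,
        p_value=p,
        median_shift=float(np.median(in_set) - np.median(background)),
        ecdf_set=_ecdf(in_set),
        ecdf_background=_ecdf(background),
    )


def compare_nascent_proportions(props: pd.DataFrame, group_col: str = "group",
                                value_col: str = "raw_proportion",
                                min_group_size: int = 5) -> pd.DataFrame:
    """Pairwise Mann-Whitney tests of per-gene proportions across groups.

    ``props`` is long-format with one row per gene x group.  Groups with fewer
    than ``min_group_size`` finite values are excluded.  Returns one row per
    group pair with U, p and box-plot statistics (median and quartiles).
    """
    clean = props.dropna(subset=[value_col])
    by_group = {g: sub[value_col].to_numpy() for g, sub in clean.groupby(group_col)}
    by_group = {g: v for g, v in by_group.items() if len(v) >= min_group_size}
    if len(by_group) < 2:
        raise ValidationError("need at least two groups with enough genes")
    names = sorted(by_group)
    rows = []
    for i, g1 in enumerate(names):
        for g2 in names[i + 1:]:
            u, p = mann_whitney_u(by_group[g1], by_group[g2])
            q1a, meda, q3a = np.percentile(by_group[g1], [25, 50, 75])
            q1b, medb, q3b = np.percentile(by_group[g2], [25, 50, 75])
            rows.append(
                {
                    "group1": g1, "group2": g2,
                    "n1": len(by_group[g1]), "n2": len(by_group[g2]),
                    "median1": meda, "q1_1": q1a, "q3_1": q3a,
                    "median2": medb, "q1_2": q1b, "q3_2": q3b,
                    "u_stat": u, "p_value": p,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class OrfLengthTrend:
    per_bin: pd.DataFrame
    trend_rho: float
    trend_p: float


def stratify_by_orf_length(props_a: pd.Series, props_b: pd.Series,
                           orf_lengths: pd.Series, bin_edges=None,
                           n_bins: int = 4) -> OrfLengthTrend:
    """Compare two per-gene proportion profiles within ORF-length bins.

    ``props_a`` is the reference (e.g. transcriptome) and ``props_b`` the
    comparison profile (e.g. translatome), both gene-indexed.  Default bins
    are quantiles of the observed lengths.  The trend statistic is the
    Spearman correlation of bin midpoints against per-bin median differences
    (b minus a); empty bins are reported but excluded from the trend.
    """
    genes = props_a.dropna().index.intersection(props_b.dropna().index)
    genes = genes.intersection(orf_lengths.dropna().index)
    if len(genes) == 0:
        raise ValidationError("no genes shared between proportions and lengths")
    a = props_a.loc[genes]
    b = props_b.loc[genes]
    lengths = orf_lengths.loc[genes].astype(float)
    if bin_edges is None:
        qs = np.linspace(0, 1, n_bins + 1)
        bin_edges = np.unique(np.quantile(lengths, qs))
    bin_edges = np.asarray(bin_edges, dtype=float)
    if lengths.min() < bin_edges[0] or lengths.max() > bin_edges[-1]:
        raise ValidationError("bin edges do not cover the observed ORF lengths")

    idx = np.clip(np.searchsorted(bin_edges, lengths, side="right") - 1, 0,
                  len(bin_edges) - 2)
    rows = []
    for k in range(len(bin_edges) - 1):
        mask = idx == k
        mid = 0.5 * (bin_edges[k] + bin_edges[k + 1])
        if mask.sum() == 0:
            rows.append({"bin_low": bin_edges[k], "bin_high": bin_edges[k + 1],
                         "midpoint": mid, "n": 0, "median_diff": np.nan,
                         "u_stat": np.nan, "p_value": np.nan})
            continue
        av, bv = a[mask].to_numpy(), b[mask].to_numpy()
        u, p = mann_whitney_u(bv, av)
        rows.append(
            {
                "bin_low": bin_edges[k], "bin_high": bin_edges[k + 1],
                "midpoint": mid, "n": int(mask.sum()),
                "median_diff": float(np.median(bv - av)),
                "u_stat": u, "p_value": p,
            }
        )
    per_bin = pd.DataFrame(rows)
    usable = per_bin.dropna(subset=["median_diff"])
    if len(usable) >= 3:
        rho, p_trend = stats.spearmanr(usable["midpoint"], usable["median_diff"])
    else:
        rho, p_trend = np.nan, np.nan
    return OrfLengthTrend(per_bin=per_bin, trend_rho=float(rho), trend_p=float(p_trend))


def hypergeometric_ora(query, universe, annotation) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set in annotation sets.

    ``p`` is the upper-tail probability P(X >= k) of the overlap under random
    sampling from the universe; the enrichment ratio is the overlap fraction
    of the query over the set's fraction of the universe.  BH adjustment is
    applied across annotation sets.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    query = set(query)
    if not query <= universe:
        raise ValidationError("query must be a subset of the universe")
    rows = []
    for gs in annotation:
        members = gs.members & universe
        dropped = len(gs.members) - len(members)
        if not members:
            continue
        k = len(query & members)
        expected = len(query) * len(members) / len(universe)
        ratio = (k / len(query)) / (len(members) / len(universe)) if query else np.nan
        p = stats.hypergeom.sf(k - 1, len(universe), len(members), len(query))
        rows.append(
            {
                "set_name": gs.name,
                "n_set": len(members),
                "n_dropped": dropped,
                "overlap": k,
                "expected": expected,
                "enrichment_ratio": ratio,
                "p_value": float(p),
            }
        )
    if not rows:
        raise ValidationError("no annotation set overlaps the universe")
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_value"].to_numpy())
    return out.sort_values("p_value").reset_index(drop=True)
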
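"""Nascent/pre-existing decomposition of tcount tables.

Implements the per-gene nascent proportion (T>C reads over total reads), a
detection-sensitivity estimator based on the most strongly induced genes, the
sensitivity correction of raw proportions, non-T>C (pre-existing) count
tables, and bulk proportions for group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EstimationError, ValidationError

DEFAULT_MIN_SUPPORT = 20
DEFAULT_TOP_K = 3


@dataclass
class SensitivityEstimate:
    """Pooled probability that a nascent-derived read is detected as T>C."""

    s: float
    per_gene: pd.DataFrame = field(repr=False, default=None)
    genes_used: list = field(default_factory=list)
    formulation: str = "excess"

    def __post_init__(self) -> None:
        if not 0.0 < self.s <= 1.0:
            raise ValidationError(f"sensitivity must lie in (0, 1], got {self.s}")
        if not self.genes_used:
            raise ValidationError("genes_used must be nonempty")


def _check_table(table: pd.DataFrame) -> None:
    for col in ("gene_id", "ReadCount", "TcReadCount"):
        if col not in table.columns:
            raise ValidationError(f"tcount table missing column {col!r}")
    if (table["TcReadCount"] > table["ReadCount"]).any():
        raise ValidationError("TcReadCount exceeds ReadCount")


def nascent_proportion(table: pd.DataFrame, min_support: int = DEFAULT_MIN_SUPPORT) -> pd.DataFrame:
    """Raw per-gene nascent proportion: TcReadCount / ReadCount.

    Genes with fewer than ``min_support`` reads get a missing (NaN) proportion
    rather than zero — low-coverage ratios are noise, not absence of signal.
    """
    _check_table(table)
    reads = table["ReadCount"].to_numpy(dtype=float)
    tc = table["TcReadCount"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(reads > 0, tc / np.maximum(reads, 1), np.nan)
    raw = np.where(reads >= min_support, raw, np.nan)
    return pd.DataFrame(
        {
            "gene_id": table["gene_id"].to_numpy(),
            "raw_proportion": raw,
            "read_support": reads.astype(int),
        }
    )


def sum_tables(tables) -> pd.DataFrame:
    """Sum ReadCount/TcReadCount across replicate tcount tables (by gene)."""
    tables = list(tables)
    if not tables:
        raise ValidationError("no tables to sum")
    for t in tables:
        _check_table(t)
    acc = tables[0][["gene_id", "ReadCount", "TcReadCount"]].set_index("gene_id")
    for t in tables[1:]:
        other = t[["gene_id", "ReadCount", "TcReadCount"]].set_index("gene_id")
        if not acc.index.equals(other.index):
            other = other.reindex(acc.index)
            if other.isna().any().any():
                raise ValidationError("tables do not share a gene universe")
        acc = acc + other
    return acc.reset_index()


def estimate_sensitivity(control: pd.DataFrame, treated: pd.DataFrame,
                         top_k: int = DEFAULT_TOP_K,
                         formulation: str = "excess") -> SensitivityEstimate:
    """Estimate T>C detection sensitivity from the most induced genes.

    Both tables are scaled to the control library size, genes are ranked by
    their induction ratio (pseudocount 1), and over the ``top_k`` genes the
    pooled sensitivity is computed as excess T>C reads over excess total reads.
    Induced excess reads are (approximately) all nascent, so the ratio
    estimates the probability that a nascent read carries a detected T>C.

    ``formulation="excess"`` subtracts the control T>C background from the
    numerator (default); ``formulation="treated"`` uses the treated T>C count
    alone.
    """
    _check_table(control)
    _check_table(treated)
    if formulation not in ("excess", "treated"):
        raise EstimationError(f"unknown formulation {formulation!r}")
    merged = control.set_index("gene_id")[["ReadCount", "TcReadCount"]].join(
        treated.set_index("gene_id")[["ReadCount", "TcReadCount"]],
        how="inner", lsuffix="_c", rsuffix="_t",
    )
    if merged.empty:
        raise EstimationError("tables share no genes")
    depth_c = merged["ReadCount_c"].sum()
    depth_t = merged["ReadCount_t"].sum()
    if depth_c == 0 or depth_t == 0:
        raise EstimationError("a table has zero total reads")
    scale = depth_c / depth_t
    n_t = merged["ReadCount_t"] * scale
    tc_t = merged["TcReadCount_t"] * scale
    ratio = (n_t + 1.0) / (merged["ReadCount_c"] + 1.0)
    top = ratio.sort_values(ascending=False).head(top_k).index

    excess = n_t.loc[top] - merged.loc[top, "ReadCount_c"]
    if formulation == "excess":
        excess_tc = tc_t.loc[top] - merged.loc[top, "TcReadCount_c"]
    else:
        excess_tc = tc_t.loc[top]
    if excess.sum() <= 0:
        raise EstimationError(
            "no positive excess reads among top-induced genes; "
            f"induction ratios: {ratio.loc[top].round(2).to_dict()}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        per_gene_s = np.clip(excess_tc / excess.where(excess > 0), 1e-12, 1.0)
    s = float(np.clip(excess_tc.sum() / excess.sum(), 1e-12, 1.0))
    per_gene = pd.DataFrame(
        {
            "gene_id": top,
            "excess_reads": excess.to_numpy(),
            "excess_tc_reads": excess_tc.to_numpy(),
            "s_gene": per_gene_s.to_numpy(),
        }
    )
    return SensitivityEstimate(s=s, per_gene=per_gene, genes_used=list(top),
                               formulation=formulation)


def correct_proportion(props: pd.DataFrame, s) -> pd.DataFrame:
    """Divide raw proportions by the detection sensitivity, clipping to [0, 1]."""
    s_val = s.s if isinstance(s, SensitivityEstimate) else float(s)
    if s_val <= 0:
        raise EstimationError("sensitivity must be > 0")
    out = props.copy()
    out["corrected_proportion"] = np.clip(out["raw_proportion"] / s_val, 0.0, 1.0)
    return out


def pre_existing_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Non-T>C read counts (total minus T>C) as a pre-existing-RNA proxy."""
    _check_table(table)
    out = table[["gene_id", "ReadCount", "TcReadCount"]].copy()
    out["NonTcReadCount"] = out["ReadCount"] - out["TcReadCount"]
    assert (out["NonTcReadCount"] >= 0).all()
    return out


def bulk_nascent_proportion(tables: dict, min_support: int = DEFAULT_MIN_SUPPORT):
    """Bulk and per-gene nascent proportions for a set of samples.

    Returns ``(bulk, per_gene)``: ``bulk`` is a Series of per-sample pooled
    proportions (sum Tc / sum reads over genes); ``per_gene`` is a long
    DataFrame of per-gene raw proportions suitable for box plots and tests.
    """
    if not tables:
        raise ValidationError("need at least one sample")
    bulk = {}
    frames = []
    for sample_id, table in tables.items():
        _check_table(table)
        total = table["ReadCount"].sum()
        bulk[sample_id] = float(table["TcReadCount"].sum() / total) if total > 0 else np.nan
        props = nascent_proportion(table, min_support=min_support)
        props.insert(0, "sample_id", sample_id)
        frames.append(props)
    return pd.Series(bulk, name="bulk_proportion"), pd.concat(frames, ignore_index=True)
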
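"""Read trimming, substitution counting and per-gene tcount tallies.

Desk-scale re-implementation of the quantification layer used for SLAM-seq
style data: trim aligned 3'-end reads, compare them to the reference, classify
reads carrying T>C conversions and accumulate per-gene ReadCount/TcReadCount
tables with conversion-rate QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyTableError, ParseError, ValidationError

#: the 12 ref>read substitution types, in fixed output order
SUBSTITUTION_TYPES = tuple(
    f"{a}>{b}" for a in "ACGT" for b in "ACGT" if a != b
)

_VALID = set("ACGTN")

DEFAULT_TRIM5 = 12          # 5' bases clipped from each read
DEFAULT_MAX_POLYA_KEEP = 4  # terminal A-runs longer than this are removed
DEFAULT_MIN_BASE_QUALITY = 27
DEFAULT_MIN_TC = 1


@dataclass
class AlignedRead:
    """A sense-strand read aligned to a single gene's 3'UTR reference."""

    read_id: str
    gene_id: str
    start: int                      # 0-based offset in the reference
    sequence: str
    base_qualities: list
    trimmed: bool = False
    discarded: bool = False

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"{self.read_id}: negative start")
        if len(self.base_qualities) != len(self.sequence):
            raise ValidationError(f"{self.read_id}: quality/sequence length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ConversionVector:
    """Per-read substitution counts and eligible-base coverage."""

    counts: dict = field(default_factory=lambda: {t: 0 for t in SUBSTITUTION_TYPES})
    base_coverage: dict = field(default_factory=lambda: {b: 0 for b in "ACGT"})

    @property
    def t_coverage(self) -> int:
        return self.base_coverage["T"]

    @property
    def tc_count(self) -> int:
        return self.counts["T>C"]


def trim_read(read: AlignedRead, trim5: int = DEFAULT_TRIM5,
              max_polya_keep: int = DEFAULT_MAX_POLYA_KEEP) -> AlignedRead:
    """Clip ``trim5`` bases from the 5' end, then strip a terminal poly(A) run.

    A 3' adenine run longer than ``max_polya_keep`` is removed entirely (runs
    of at most ``max_polya_keep`` are kept).  Trimming is recorded on the read
    and is idempotent: an already-trimmed read is returned unchanged.  Reads
    shorter than ``trim5`` come back empty and flagged discarded.
    """
    if trim5 < 0 or max_polya_keep < 0:
        raise ConfigError("trim5 and max_polya_keep must be >= 0")
    if read.trimmed:
        return read
    if len(read.sequence) <= trim5:
        return AlignedRead(read.read_id, read.gene_id, read.start + len(read.sequence),
                           "", [], trimmed=True, discarded=True)
    seq = read.sequence[trim5:]
    quals = list(read.base_qualities[trim5:])
    run = len(seq) - len(seq.rstrip("A"))
    if run > max_polya_keep:
        seq = seq[: len(seq) - run]
        quals = quals[: len(seq)]
    if not seq:
        return AlignedRead(read.read_id, read.gene_id, read.start + trim5, "", [],
                           trimmed=True, discarded=True)
    return AlignedRead(read.read_id, read.gene_id, read.start + trim5, seq, quals,
                       trimmed=True)


def count_conversions(read: AlignedRead, reference: str,
                      min_base_quality: int = DEFAULT_MIN_BASE_QUALITY) -> ConversionVector:
    """Compare a read to its reference and tally substitutions.

    Positions with base quality below ``min_base_quality`` are excluded from
    both the numerators and the coverage denominators; N bases (either side)
    are ignored.
    """
    if read.start + len(read.sequence) > len(reference):
        raise ValidationError(f"{read.read_id}: alignment exceeds reference length")
    vec = ConversionVector()
    ref_seg = reference[read.start:read.start + len(read.sequence)].upper()
    for ref_base, read_base, q in zip(ref_seg, read.sequence.upper(), read.base_qualities):
        if ref_base not in _VALID or read_base not in _VALID:
            raise ParseError(f"{read.read_id}: invalid base {ref_base!r}/{read_base!r}")
        if ref_base == "N" or read_base == "N" or q < min_base_quality:
            continue
        vec.base_coverage[ref_base] += 1
        if read_base != ref_base:
            vec.counts[f"{ref_base}>{read_base}"] += 1
    return vec


def classify_tc_read(conv: ConversionVector, min_tc: int = DEFAULT_MIN_TC) -> bool:
    """A read is a T>C read iff it carries at least ``min_tc`` T>C conversions."""
    if min_tc < 1:
        raise ConfigError("min_tc must be >= 1")
    return conv.tc_count >= min_tc


def detection_sensitivity(p_conv, n_uridines):
    """Probability that a labeled read shows >= 1 T>C: ``1 - (1-p)^n``."""
    p = np.asarray(p_conv, dtype=float)
    n = np.asarray(n_uridines)
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p_conv must lie in [0, 1]")
    if np.any(n < 0):
        raise ValidationError("n_uridines must be >= 0")
    out = 1.0 - (1.0 - p) ** n
    if np.isscalar(p_conv) and np.isscalar(n_uridines):
        return float(out)
    return out


def _iter_reads(read_set):
    return read_set.reads if hasattr(read_set, "reads") else read_set


def tally_gene_counts(read_set, references: dict,
                      min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
                      min_tc: int = DEFAULT_MIN_TC,
                      apply_trim: bool = False,
                      trim5: int = DEFAULT_TRIM5,
                      max_polya_keep: int = DEFAULT_MAX_POLYA_KEEP) -> pd.DataFrame:
    """Accumulate a per-gene tcount table from aligned reads.

    Every gene present in ``references`` gets a row (zero counts when no read
    maps to it).  ``readsCPM`` is computed over the whole sample.
    """
    stats = {
        g: {"ReadCount": 0, "TcReadCount": 0, "coverageOnTs": 0, "conversionsOnTs": 0}
        for g in references
    }
    for read in _iter_reads(read_set):
        if apply_trim:
            read = trim_read(read, trim5=trim5, max_polya_keep=max_polya_keep)
        if read.discarded or not read.sequence:
            continue
        if read.gene_id not in references:
            raise ValidationError(f"{read.read_id}: unknown gene {read.gene_id!r}")
        vec = count_conversions(read, references[read.gene_id], min_base_quality)
        s = stats[read.gene_id]
        s["ReadCount"] += 1
        s["coverageOnTs"] += vec.t_coverage
        s["conversionsOnTs"] += vec.tc_count
        if classify_tc_read(vec, min_tc):
            s["TcReadCount"] += 1

    total_reads = sum(s["ReadCount"] for s in stats.values())
    if total_reads == 0:
        raise EmptyTableError("no reads survive filtering; cannot tally counts")

    genes = sorted(stats)
    table = pd.DataFrame(
        {
            "gene_id": genes,
            "length": [len(references[g]) for g in genes],
            "ReadCount": [stats[g]["ReadCount"] for g in genes],
            "TcReadCount": [stats[g]["TcReadCount"] for g in genes],
            "coverageOnTs": [stats[g]["coverageOnTs"] for g in genes],
            "conversionsOnTs": [stats[g]["conversionsOnTs"] for g in genes],
        }
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        table["conversionRate"] = np.where(
            table["coverageOnTs"] > 0,
            table["conversionsOnTs"] / table["coverageOnTs"].replace(0, 1),
            np.nan,
        )
    table["readsCPM"] = table["ReadCount"] / total_reads * 1e6
    assert (table["TcReadCount"] <= table["ReadCount"]).all()
    return table


def conversion_rate_summary(read_set, references: dict,
                            min_base_quality: int = DEFAULT_MIN_BASE_QUALITY) -> pd.Series:
    """Median per-gene conversion rate for each of the 12 substitution types.

    For each gene, the rate of substitution ``X>Y`` is (events / covered
    reference-X bases); genes with zero eligible coverage for X are excluded
    from that type's median.
    """
    events = {}
    coverage = {}
    for read in _iter_reads(read_set):
        vec = count_conversions(read, references[read.gene_id], min_base_quality)
        ev = events.setdefault(read.gene_id, dict.fromkeys(SUBSTITUTION_TYPES, 0))
        cov = coverage.setdefault(read.gene_id, dict.fromkeys("ACGT", 0))
        for t in SUBSTITUTION_TYPES:
            ev[t] += vec.counts[t]
        for b in "ACGT":
            cov[b] += vec.base_coverage[b]
    if not events:
        raise EmptyTableError("no reads to summarize")

    medians = {}
    for t in SUBSTITUTION_TYPES:
        ref_base = t[0]
        rates = [
            events[g][t] / coverage[g][ref_base]
            for g in events
            if coverage[g][ref_base] > 0
        ]
        medians[t] = float(np.median(rates)) if rates else np.nan
    return pd.Series(medians, name="median_rate")
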
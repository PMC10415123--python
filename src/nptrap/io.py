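"""Readers and writers for the formats the pipeline touches.

TSV dialect everywhere: tab-separated, header row, '.' decimal, no quoting,
empty field for NA.  Coordinates are 0-based half-open internally and 1-based
in SAM, per the standard.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .category_stats import GeneSet
from .conversion_counting import AlignedRead
from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

TCOUNT_REQUIRED = ("gene_id", "ReadCount", "TcReadCount")
_FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# tcount tables
# ---------------------------------------------------------------------------

def read_tcount(path) -> pd.DataFrame:
    """Read a tcount-style TSV; SLAM-DUNK's ``gene_name`` is accepted for
    ``gene_id`` and extra columns are preserved verbatim."""
    table = pd.read_csv(path, sep="\t")
    if "gene_id" not in table.columns and "gene_name" in table.columns:
        table = table.rename(columns={"gene_name": "gene_id"})
    for col in TCOUNT_REQUIRED:
        if col not in table.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    bad = table.index[table["TcReadCount"] > table["ReadCount"]]
    if len(bad):
        raise ValidationError(
            f"{path}: TcReadCount > ReadCount at row {int(bad[0]) + 2} "
            f"(gene {table.loc[bad[0], 'gene_id']!r})")
    return table


def write_tcount(table: pd.DataFrame, path) -> None:
    for col in TCOUNT_REQUIRED:
        if col not in table.columns:
            raise ValidationError(f"cannot write tcount: missing column {col!r}")
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# count matrices + metadata
# ---------------------------------------------------------------------------

def write_matrix(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id", float_format=_FLOAT_FORMAT)


def read_matrix(path) -> pd.DataFrame:
    mat = pd.read_csv(path, sep="\t", index_col="gene_id")
    if (mat.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative counts")
    return mat


def write_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    for col in ("condition",):
        if col not in meta.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    return meta


def matrices_from_tcounts(tables: dict, meta: pd.DataFrame) -> dict:
    """Build total/tc/non_tc count matrices from per-sample tcount tables."""
    from .differential_expression import CountMatrix

    genes = None
    cols = {}
    for sample_id, table in tables.items():
        t = table.set_index("gene_id")
        if genes is None:
            genes = t.index
        elif not genes.equals(t.index):
            raise ValidationError("tcount tables do not share a gene universe")
        cols[sample_id] = t
    total = pd.DataFrame({s: t["ReadCount"] for s, t in cols.items()})
    tc = pd.DataFrame({s: t["TcReadCount"] for s, t in cols.items()})
    non_tc = total - tc
    return {
        "total": CountMatrix(total, meta, read_class="total"),
        "tc": CountMatrix(tc, meta, read_class="tc"),
        "non_tc": CountMatrix(non_tc, meta, read_class="non_tc"),
    }


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict:
    """Reference sequences as a dict id -> upper-case string."""
    refs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        refs[rec.id] = str(rec.seq).upper()
    if not refs:
        raise ParseError(f"{path}: no FASTA records")
    return refs


def write_fasta(references: dict, path) -> None:
    records = [SeqRecord(Seq(seq), id=gene, description="") for gene, seq in references.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# minimal SAM
# ---------------------------------------------------------------------------

def _md_tag(read_seq: str, ref_seg: str) -> tuple[str, int]:
    parts = []
    match = 0
    nm = 0
    for rb, qb in zip(ref_seg, read_seq):
        if rb == qb:
            match += 1
        else:
            parts.append(f"{match}{rb}")
            match = 0
            nm += 1
    parts.append(str(match))
    return "".join(parts), nm


def write_sam(reads, references: dict, path) -> None:
    """Write aligned reads as plain-text SAM (FLAG 0, all-match CIGAR, MD tag)."""
    ref_names = list(references)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": g, "LN": len(references[g])} for g in ref_names],
    }
    ref_index = {g: i for i, g in enumerate(ref_names)}
    reads_iter = reads.reads if hasattr(reads, "reads") else reads
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for read in reads_iter:
            if read.discarded or not read.sequence:
                continue
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = read.read_id
            seg.flag = 0
            seg.reference_id = ref_index[read.gene_id]
            seg.reference_start = read.start  # pysam is 0-based; POS printed 1-based
            seg.mapping_quality = 60
            seg.cigartuples = [(0, len(read.sequence))]
            seg.query_sequence = read.sequence
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in read.base_qualities))
            ref_seg = references[read.gene_id][read.start:read.start + len(read.sequence)]
            md, nm = _md_tag(read.sequence, ref_seg)
            seg.set_tag("MD", md)
            seg.set_tag("NM", nm)
            fh.write(seg)


def read_sam_minimal(path) -> list:
    """Read a minimal SAM file into :class:`AlignedRead` objects (0-based starts)."""
    reads = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            quals = list(seg.query_qualities) if seg.query_qualities is not None \
                else [40] * len(seg.query_sequence)
            reads.append(
                AlignedRead(
                    read_id=seg.query_name,
                    gene_id=seg.reference_name,
                    start=seg.reference_start,
                    sequence=seg.query_sequence.upper(),
                    base_qualities=quals,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> list:
    """Read gene sets from GMT (name <tab> description <tab> members...)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            unique = set(members)
            if len(unique) < len(members):
                logger.info("GMT set %s: deduplicated %d members",
                            name, len(members) - len(unique))
            sets.append(GeneSet(name=name, members=unique, source=desc))
    if not sets:
        raise ParseError(f"{path}: no gene sets")
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.source or "na", *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# generic result frames
# ---------------------------------------------------------------------------

def write_results(frame: pd.DataFrame, path, index: bool = True,
                  index_label: str = "gene_id") -> None:
    frame.to_csv(path, sep="\t", index=index,
                 index_label=index_label if index else None,
                 float_format=_FLOAT_FORMAT)
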
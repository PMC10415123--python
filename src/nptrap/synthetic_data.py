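"""Ground-truth transcript models and simulators for metabolic-labeling sequencing.

This module generates everything the downstream analysis stages consume:

* per-gene kinetic/sequence models (:class:`TranscriptModel`),
* planted regulation modes for parameter-recovery studies,
* per-sample count tables with negative-binomial noise and a T>C detection
  channel (:func:`simulate_counts`),
* read-level data with per-uridine conversions and a background error channel
  (:func:`simulate_reads`).

All generators are deterministic given an integer seed; independent sub-streams
per sample are derived from fixed index tuples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError

REGULATION_MODES = ("null", "forwarded", "exclusive", "intensified", "buffered")
TRANSLATOME_ASSAYS = frozenset({"ptrap", "l10a"})
KNOWN_ASSAYS = ("rna", "ptrap", "l10a")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_T = ord("T")
_C = ord("C")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """Latent per-gene truth: kinetics, sequence context and planted regulation.

    ``k_syn`` and ``te`` are dictionaries keyed by condition label; ``k_deg``
    is condition-independent.  ``loading_lag`` scales the nascent fraction seen
    by translatome assays (1.0 = no lag).  Planted log2 effect sizes are
    recorded so recovery can be checked against the mode that produced them.
    """

    gene_id: str
    utr_length: int
    n_uridines_per_read: int
    orf_length: int
    k_syn: dict
    k_deg: float
    te: dict
    loading_lag: float = 1.0
    regulation_mode: str = "null"
    lfc_syn: float = 0.0
    lfc_te: float = 0.0

    def __post_init__(self) -> None:
        if self.k_deg <= 0:
            raise ValidationError(f"{self.gene_id}: k_deg must be > 0")
        if any(v <= 0 for v in self.k_syn.values()):
            raise ValidationError(f"{self.gene_id}: k_syn must be > 0")
        if any(v <= 0 for v in self.te.values()):
            raise ValidationError(f"{self.gene_id}: te must be > 0")
        if not 0.0 <= self.loading_lag <= 1.0:
            raise ValidationError(f"{self.gene_id}: loading_lag outside [0, 1]")
        if self.n_uridines_per_read < 0:
            raise ValidationError(f"{self.gene_id}: negative uridine count")
        if self.regulation_mode not in REGULATION_MODES:
            raise ValidationError(f"{self.gene_id}: unknown mode {self.regulation_mode!r}")


@dataclass
class SimDesign:
    """Experimental design for count/read simulation."""

    conditions: tuple = ("control", "stress")
    n_replicates: int = 3
    assays: tuple = ("rna", "ptrap")
    labeling_time: float = 3.0          # hours
    library_size: float = 1e6           # expected reads per sample
    dispersion: float = 0.05            # NB dispersion (0 -> Poisson)
    p_conv: float = 0.024               # per-uridine T>C probability, labeled
    p_err: float = 0.001                # per-base background substitution rate
    kinetics: str = "steady_state"      # or "step" (induction during the pulse)
    base_quality: int = 37
    seed: int = 0

    def __post_init__(self) -> None:
        if self.labeling_time <= 0:
            raise ConfigError("labeling_time must be > 0")
        if not (0.0 <= self.p_err < 1.0) or not (0.0 <= self.p_conv <= 1.0):
            raise ConfigError("conversion probabilities must lie in [0, 1]")
        if self.p_conv > 0 and self.p_err >= self.p_conv:
            raise ConfigError("p_err must be smaller than p_conv")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.library_size <= 0:
            raise ConfigError("library_size must be > 0")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if self.kinetics not in ("steady_state", "step"):
            raise ConfigError(f"unknown kinetics {self.kinetics!r}")
        if len(self.conditions) != 2:
            raise ConfigError("exactly two conditions are supported")
        for a in self.assays:
            if a not in KNOWN_ASSAYS:
                raise ConfigError(f"unknown assay {a!r}")

    def samples(self):
        """Yield (sample_id, assay, condition, replicate) for every library."""
        out = []
        for ai, assay in enumerate(self.assays):
            for ci, cond in enumerate(self.conditions):
                for rep in range(1, self.n_replicates + 1):
                    out.append((f"{assay}_{cond}_rep{rep}", assay, cond, rep))
        return out

    def sample_meta(self) -> pd.DataFrame:
        rows = [
            {"sample_id": s, "assay": a, "condition": c, "replicate": r}
            for s, a, c, r in self.samples()
        ]
        return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def nascent_fraction(k_deg, t):
    """Fraction of molecules synthesized during a labeling pulse of length ``t``.

    First-order birth-death kinetics at steady state give ``1 - exp(-k_deg*t)``.
    Accepts scalars or arrays; monotone increasing in both arguments.
    """
    k = np.asarray(k_deg, dtype=float)
    tt = np.asarray(t, dtype=float)
    if np.any(k < 0) or np.any(tt < 0):
        raise ValidationError("nascent_fraction: k_deg and t must be >= 0")
    out = -np.expm1(-k * tt)
    if np.isscalar(k_deg) and np.isscalar(t):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# transcriptome generation
# ---------------------------------------------------------------------------

def generate_transcriptome(
    n_genes: int,
    utr_length_range=(250, 800),
    u_content_range=(0.15, 0.35),
    orf_length_range=(300, 3000),
    seed: int = 0,
    read_length: int = 50,
    conditions=("control", "stress"),
    k_deg_range=(0.05, 1.0),
    k_syn_log_sd: float = 0.8,
    te_log_sd: float = 0.3,
    loading_lag: float = 1.0,
    loading_lag_orf_range=None,
):
    """Draw ``n_genes`` :class:`TranscriptModel` objects.

    Uridine counts per read are binomial draws at the gene's uridine content
    over ``read_length`` positions.  ``k_deg`` is log-uniform over
    ``k_deg_range``; ``k_syn`` and ``te`` are log-normal around fixed medians.
    If ``loading_lag_orf_range=(lo, hi)`` is given, the lag decreases linearly
    with ORF length from ``hi`` (shortest ORF) to ``lo`` (longest); otherwise
    every gene gets the scalar ``loading_lag``.
    """
    if n_genes < 1:
        raise ConfigError("n_genes must be >= 1")
    for name, rng_ in (
        ("utr_length_range", utr_length_range),
        ("u_content_range", u_content_range),
        ("orf_length_range", orf_length_range),
        ("k_deg_range", k_deg_range),
    ):
        lo, hi = rng_
        if hi < lo:
            raise ConfigError(f"{name}: empty range {rng_!r}")
    if not 0.0 <= u_content_range[0] and u_content_range[1] <= 1.0:
        raise ConfigError("u_content_range must lie in [0, 1]")

    rng = np.random.default_rng([int(seed), 101])
    utr = rng.integers(utr_length_range[0], utr_length_range[1] + 1, size=n_genes)
    u_content = rng.uniform(u_content_range[0], u_content_range[1], size=n_genes)
    orf = rng.integers(orf_length_range[0], orf_length_range[1] + 1, size=n_genes)
    win = np.minimum(utr, read_length)
    n_u = rng.binomial(win, u_content)
    k_deg = np.exp(rng.uniform(np.log(k_deg_range[0]), np.log(k_deg_range[1]), size=n_genes))
    k_syn = np.exp(np.log(50.0) + rng.normal(0.0, k_syn_log_sd, size=n_genes))
    te = np.exp(rng.normal(0.0, te_log_sd, size=n_genes))

    if loading_lag_orf_range is not None:
        lo, hi = loading_lag_orf_range
        span = max(int(orf_length_range[1]) - int(orf_length_range[0]), 1)
        frac = (orf - orf_length_range[0]) / span
        lags = hi - (hi - lo) * frac
    else:
        lags = np.full(n_genes, float(loading_lag))

    width = len(str(n_genes))
    models = []
    for i in range(n_genes):
        models.append(
            TranscriptModel(
                gene_id=f"g{i:0{width}d}",
                utr_length=int(utr[i]),
                n_uridines_per_read=int(n_u[i]),
                orf_length=int(orf[i]),
                k_syn={c: float(k_syn[i]) for c in conditions},
                k_deg=float(k_deg[i]),
                te={c: float(te[i]) for c in conditions},
                loading_lag=float(lags[i]),
            )
        )
    return models


def assign_regulation(
    models,
    mode_fractions,
    effect_size_log2: float = 2.0,
    seed: int = 0,
    stress_condition: str | None = None,
):
    """Plant regulation modes by perturbing stress-condition parameters.

    forwarded: synthesis changes, TE unchanged; exclusive: TE changes only;
    intensified: both change with the same sign; buffered: both change with
    opposite signs; null: nothing changes.  Effect signs are random per gene;
    planted log2 effects are recorded on the returned (new) models.
    """
    fracs = {m: float(mode_fractions.get(m, 0.0)) for m in REGULATION_MODES}
    if any(v < 0 for v in fracs.values()):
        raise ConfigError("mode fractions must be non-negative")
    total = sum(fracs.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"mode fractions must sum to 1 (got {total})")

    rng = np.random.default_rng([int(seed), 202])
    modes = rng.choice(REGULATION_MODES, size=len(models), p=[fracs[m] for m in REGULATION_MODES])
    signs = rng.choice([-1.0, 1.0], size=len(models))

    out = []
    for model, mode, sign in zip(models, modes, signs):
        conds = list(model.k_syn)
        stress = stress_condition if stress_condition is not None else conds[-1]
        control = conds[0]
        e = sign * effect_size_log2
        lfc_syn = lfc_te = 0.0
        if mode == "forwarded":
            lfc_syn = e
        elif mode == "exclusive":
            lfc_te = e
        elif mode == "intensified":
            lfc_syn, lfc_te = e, e
        elif mode == "buffered":
            lfc_syn, lfc_te = e, -e
        k_syn = dict(model.k_syn)
        te = dict(model.te)
        k_syn[stress] = k_syn[control] * 2.0**lfc_syn
        te[stress] = te[control] * 2.0**lfc_te
        out.append(
            replace(model, k_syn=k_syn, te=te, regulation_mode=str(mode),
                    lfc_syn=float(lfc_syn), lfc_te=float(lfc_te))
        )
    return out


# ---------------------------------------------------------------------------
# count-level simulation
# ---------------------------------------------------------------------------

def _abundance_and_fraction(model: TranscriptModel, design: SimDesign, condition: str):
    """Expected relative abundance and nascent fraction for one gene/condition.

    ``steady_state`` applies condition parameters as the new steady state; the
    labeled fraction is the standard turnover formula.  ``step`` models a step
    change in synthesis rate at pulse start: pre-existing molecules decay from
    the control steady state while nascent molecules accumulate at the new
    rate, so induced genes' excess reads are all nascent.
    """
    t = design.labeling_time
    control = design.conditions[0]
    decay = np.exp(-model.k_deg * t)
    if design.kinetics == "steady_state":
        abundance = model.k_syn[condition] / model.k_deg
        f = 1.0 - decay
    else:  # step induction
        pre = model.k_syn[control] / model.k_deg * decay
        nas = model.k_syn[condition] / model.k_deg * (1.0 - decay)
        abundance = pre + nas
        f = nas / (pre + nas)
    return abundance, f


def expected_profile(models, design: SimDesign) -> pd.DataFrame:
    """Per gene x sample expected mean count, nascent fraction and T>C rates."""
    rows = []
    t_frames = {}
    for sample_id, assay, cond, rep in design.samples():
        if (assay, cond) in t_frames:
            rows.append(t_frames[(assay, cond)].assign(sample_id=sample_id))
            continue
        ab = np.empty(len(models))
        fr = np.empty(len(models))
        for i, m in enumerate(models):
            a, f = _abundance_and_fraction(m, design, cond)
            if assay in TRANSLATOME_ASSAYS:
                a *= m.te[cond]
                f *= m.loading_lag
            ab[i] = a
            fr[i] = f
        mean = ab / ab.sum() * design.library_size
        n_u = np.array([m.n_uridines_per_read for m in models])
        p_tc_nascent = 1.0 - ((1.0 - design.p_conv) * (1.0 - design.p_err)) ** n_u
        p_tc_pre = 1.0 - (1.0 - design.p_err) ** n_u
        frame = pd.DataFrame(
            {
                "gene_id": [m.gene_id for m in models],
                "expected_total_count": mean,
                "true_nascent_fraction": fr,
                "expected_tc_detectable_fraction": p_tc_nascent,
                "p_tc_pre": p_tc_pre,
            }
        )
        t_frames[(assay, cond)] = frame
        rows.append(frame.assign(sample_id=sample_id))
    return pd.concat(rows, ignore_index=True)


def simulate_counts(models, design: SimDesign, seed: int | None = None):
    """Simulate per-sample tcount-style tables plus the matching ground truth.

    Returns ``(tables, truth)`` where ``tables`` maps sample_id to a tcount
    DataFrame (gene_id, length, ReadCount, TcReadCount, coverageOnTs,
    conversionsOnTs, conversionRate, readsCPM) and ``truth`` is a long
    DataFrame with the realized and expected per-gene quantities.
    """
    if seed is None:
        seed = design.seed
    n_u = np.array([m.n_uridines_per_read for m in models])
    utr = np.array([m.utr_length for m in models])
    gene_ids = [m.gene_id for m in models]

    profile = expected_profile(models, design)
    tables = {}
    truth_rows = []
    for si, (sample_id, assay, cond, rep) in enumerate(design.samples()):
        rng = np.random.default_rng([int(seed), 303, si])
        prof = profile[profile["sample_id"] == sample_id]
        mean = prof["expected_total_count"].to_numpy()
        f = prof["true_nascent_fraction"].to_numpy()
        p_tc_n = prof["expected_tc_detectable_fraction"].to_numpy()
        p_tc_p = prof["p_tc_pre"].to_numpy()

        if design.dispersion == 0:
            total = rng.poisson(mean)
        else:
            r = 1.0 / design.dispersion
            total = rng.negative_binomial(r, r / (r + mean))
        nascent = rng.binomial(total, f)
        tc = rng.binomial(nascent, p_tc_n) + rng.binomial(total - nascent, p_tc_p)

        cov_t = total * n_u
        conv_t = rng.binomial(nascent * n_u, design.p_conv) + rng.binomial(cov_t, design.p_err)
        with np.errstate(invalid="ignore", divide="ignore"):
            conv_rate = np.where(cov_t > 0, conv_t / np.maximum(cov_t, 1), np.nan)
        lib = total.sum()
        tables[sample_id] = pd.DataFrame(
            {
                "gene_id": gene_ids,
                "length": utr,
                "ReadCount": total,
                "TcReadCount": tc,
                "coverageOnTs": cov_t,
                "conversionsOnTs": conv_t,
                "conversionRate": conv_rate,
                "readsCPM": total / max(lib, 1) * 1e6,
            }
        )
        truth_rows.append(
            pd.DataFrame(
                {
                    "sample_id": sample_id,
                    "gene_id": gene_ids,
                    "assay": assay,
                    "condition": cond,
                    "replicate": rep,
                    "true_nascent_fraction": f,
                    "expected_total_count": mean,
                    "expected_tc_detectable_fraction": p_tc_n,
                    "realized_total_count": total,
                    "realized_nascent_count": nascent,
                }
            )
        )
    truth = pd.concat(truth_rows, ignore_index=True)
    return tables, truth


# ---------------------------------------------------------------------------
# read-level simulation
# ---------------------------------------------------------------------------

@dataclass
class AlignedReadSet:
    """Reads for one sample plus test-only origin labels (nascent/pre-existing)."""

    sample_id: str
    reads: list = field(default_factory=list)
    origins: dict = field(default_factory=dict)


def build_references(models, design: SimDesign, read_length: int = 50, seed: int | None = None):
    """Deterministic 3'UTR reference sequences.

    The terminal ``read_length`` window of each UTR carries exactly
    ``n_uridines_per_read`` T bases (randomly placed); remaining window bases
    are drawn from {A, C, G} and upstream bases from all four.  A terminal
    adenine run longer than 4 nt is broken so default poly(A) trimming cannot
    clip simulated reads.
    """
    if seed is None:
        seed = design.seed
    refs = {}
    for gi, m in enumerate(models):
        rng = np.random.default_rng([int(seed), 404, gi])
        window = min(m.utr_length, read_length)
        if m.utr_length < read_length:
            warnings.warn(
                f"{m.gene_id}: utr_length {m.utr_length} < read_length {read_length}; "
                "reads truncated to the UTR",
                stacklevel=2,
            )
        n_u = min(m.n_uridines_per_read, window)
        upstream = rng.choice(_BASES, size=m.utr_length - window)
        win = rng.choice(np.frombuffer(b"ACG", dtype=np.uint8), size=window)
        if n_u > 0:
            pos = rng.choice(window, size=n_u, replace=False)
            win[pos] = _T
        seq = np.concatenate([upstream, win])
        # avoid a terminal poly(A)-like run
        if len(seq) >= 5 and np.all(seq[-5:] == ord("A")):
            seq[-1] = ord("G")
        refs[m.gene_id] = seq.tobytes().decode("ascii")
    return refs


def simulate_reads(models, truth: pd.DataFrame, design: SimDesign, read_length: int = 50,
                   seed: int | None = None, samples=None):
    """Generate aligned sense-strand reads consistent with ``truth``.

    Returns ``(read_sets, references)``; ``read_sets`` maps sample_id to an
    :class:`AlignedReadSet`.  Reads from nascent molecules convert each covered
    uridine with probability ``p_conv``; every base additionally mutates to
    each of the three alternative bases with probability ``p_err``.
    """
    from .conversion_counting import AlignedRead  # local import to avoid a cycle

    if seed is None:
        seed = design.seed
    refs = build_references(models, design, read_length=read_length, seed=seed)
    model_by_id = {m.gene_id: m for m in models}
    wanted = set(samples) if samples is not None else None

    read_sets = {}
    sample_ids = truth["sample_id"].unique()
    for si, sample_id in enumerate(sample_ids):
        if wanted is not None and sample_id not in wanted:
            continue
        rs = AlignedReadSet(sample_id=sample_id)
        sub = truth[truth["sample_id"] == sample_id]
        for gi, row in enumerate(sub.itertuples(index=False)):
            m = model_by_id[row.gene_id]
            n = int(row.realized_total_count)
            if n == 0:
                continue
            n_nas = int(row.realized_nascent_count)
            rng = np.random.default_rng([int(seed), 505, si, gi])
            window = min(m.utr_length, read_length)
            start = m.utr_length - window
            ref_win = np.frombuffer(refs[m.gene_id][start:].encode("ascii"), dtype=np.uint8)
            t_pos = np.flatnonzero(ref_win == _T)

            mat = np.tile(ref_win, (n, 1))
            if n_nas > 0 and t_pos.size > 0 and design.p_conv > 0:
                conv = rng.random((n_nas, t_pos.size)) < design.p_conv
                rows_, cols_ = np.nonzero(conv)
                mat[rows_, t_pos[cols_]] = _C
            if design.p_err > 0:
                err = rng.random(mat.shape) < 3.0 * design.p_err
                rows_, cols_ = np.nonzero(err)
                if rows_.size:
                    base_idx = np.searchsorted(_BASES, mat[rows_, cols_])
                    shift = rng.integers(1, 4, size=rows_.size)
                    mat[rows_, cols_] = _BASES[(base_idx + shift) % 4]

            quals = [design.base_quality] * window
            for i in range(n):
                rid = f"{m.gene_id}|{sample_id}|{i}"
                rs.reads.append(
                    AlignedRead(
                        read_id=rid,
                        gene_id=m.gene_id,
                        start=start,
                        sequence=mat[i].tobytes().decode("ascii"),
                        base_qualities=list(quals),
                    )
                )
                rs.origins[rid] = "nascent" if i < n_nas else "preexisting"
        read_sets[sample_id] = rs
    return read_sets, refs
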
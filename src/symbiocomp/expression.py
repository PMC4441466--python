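"""Read counting, RPKM, assembly summaries and qPCR relative expression.

RPKM (reads per kilobase of transcript per million mapped reads) is

    RPKM = raw_count * 1e9 / (total_mapped * length_bp)

with the denominator taken over the pooled library (host + symbiont reads
together) by default, since the underlying experiment sequences one pooled
mRNA sample.  Read assignment reuses the same local aligner as origin
binning, with an exact-substring fast path and equal splitting of ties;
conservation of read mass is exact (tie fractions are tracked as rationals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import numpy as np

from .align import ScoringScheme, alignment_score, local_align
from .binning import ThresholdConfig
from .seqio import ReadSet, Transcript, reverse_complement

__all__ = [
    "ExpressionRecord",
    "ReadAssignment",
    "AssemblySummary",
    "QpcrMeasurement",
    "assign_reads",
    "compute_rpkm",
    "quantify_expression",
    "summarize_assembly",
    "proportion_percent",
    "relative_expression_ddct",
    "flag_high_expression",
    "DEFAULT_LENGTH_BINS",
]

# S1-Fig-style length bins: 150-500, 501-1000, 1001-5000, >5000 bp.
DEFAULT_LENGTH_BINS: tuple[tuple[int, float], ...] = (
    (150, 500),
    (501, 1000),
    (1001, 5000),
    (5001, math.inf),
)


@dataclass
class ExpressionRecord:
    transcript_id: str
    raw_count: float
    rpkm: float = 0.0


@dataclass
class ReadAssignment:
    """Per-transcript read counts plus the unassigned remainder.

    Counts are exact rationals so that assigned + unassigned always equals the
    number of reads, tie fractions included.
    """

    counts: dict[str, Fraction] = field(default_factory=dict)
    unassigned: Fraction = Fraction(0)
    n_reads: int = 0

    @property
    def total_assigned(self) -> Fraction:
        return sum(self.counts.values(), Fraction(0))


def _seed_candidates(
    read_seq: str, transcripts: list[Transcript], n_chunks: int = 3
) -> list[int]:
    """Indices of transcripts containing any of ``n_chunks`` read chunks exactly.

    With substitution-only errors, a read with fewer errors than chunks always
    has one error-free chunk, so its source transcript is always a candidate.
    """
    step = -(-len(read_seq) // n_chunks)  # ceil division: n_chunks equal slices
    chunks = [
        chunk
        for i in range(n_chunks)
        if len(chunk := read_seq[i * step : (i + 1) * step]) >= 12
    ]
    if not chunks:
        return []
    hits = []
    for i, transcript in enumerate(transcripts):
        if any(chunk in transcript.sequence for chunk in chunks):
            hits.append(i)
    return hits


def assign_reads(
    reads: ReadSet,
    transcripts: list[Transcript],
    scoring: ScoringScheme | None = None,
    min_identity_pct: float = 95.0,
) -> ReadAssignment:
    """Assign each read to its best-aligning transcript(s).

    A read counts toward a transcript when at least ``min_identity_pct`` of
    the read bases match in the best local alignment; reads tying across
    several transcripts are split equally; everything else is unassigned.

    Exact substring occurrences (either strand) short-circuit the aligner.
    When no transcript contains an exact read chunk, the read is aligned
    against the full collection.
    """
    if not transcripts:
        raise ValueError("transcript collection must be non-empty")
    scoring = scoring or ScoringScheme()
    result = ReadAssignment(
        counts={t.id: Fraction(0) for t in transcripts}, n_reads=len(reads)
    )
    for read in reads:
        seq = read.sequence
        rc = reverse_complement(seq)
        exact = [
            t.id for t in transcripts if seq in t.sequence or rc in t.sequence
        ]
        if exact:
            share = Fraction(1, len(exact))
            for tid in exact:
                result.counts[tid] += share
            continue
        candidates = _seed_candidates(seq, transcripts) or _seed_candidates(
            rc, transcripts
        )
        pool = [transcripts[i] for i in candidates] if candidates else transcripts
        scores = [alignment_score(seq, t.sequence, scoring) for t in pool]
        top = max(scores)
        winners = []
        for transcript, score in zip(pool, scores):
            if score < top - 1e-9:
                continue
            aln = local_align(seq, transcript.sequence, scoring)
            # identity over the read: matched bases relative to read length
            if 100.0 * aln.n_matches / len(seq) >= min_identity_pct:
                winners.append(transcript.id)
        if winners:
            share = Fraction(1, len(winners))
            for tid in winners:
                result.counts[tid] += share
        else:
            result.unassigned += 1
    return result


def compute_rpkm(raw_count: float, length_bp: int, total_mapped: float) -> float:
    """RPKM = raw_count * 1e9 / (total_mapped * length_bp)."""
    if length_bp <= 0:
        raise ValueError("transcript length must be positive")
    if total_mapped <= 0:
        raise ValueError("library size must be positive")
    if raw_count < 0:
        raise ValueError("raw count must be non-negative")
    return float(raw_count) * 1e9 / (float(total_mapped) * float(length_bp))


def quantify_expression(
    reads: ReadSet,
    transcripts: list[Transcript],
    scoring: ScoringScheme | None = None,
    min_identity_pct: float = 95.0,
    denominator: str = "pooled",
    origins: dict[str, str] | None = None,
) -> list[ExpressionRecord]:
    """Count reads and normalize to RPKM in one pass.

    ``denominator='pooled'`` (default) uses all assigned reads across both
    organisms as the million-mapped-reads base; ``'per_origin'`` normalizes
    each transcript against its own partner's assigned total and requires an
    ``origins`` map.
    """
    assignment = assign_reads(reads, transcripts, scoring, min_identity_pct)
    lengths = {t.id: t.length_bp for t in transcripts}
    if denominator == "pooled":
        totals = {tid: assignment.total_assigned for tid in assignment.counts}
    elif denominator == "per_origin":
        if origins is None:
            raise ValueError("per-origin normalization needs an origins map")
        per_origin: dict[str, Fraction] = {}
        for tid, count in assignment.counts.items():
            per_origin[origins[tid]] = per_origin.get(origins[tid], Fraction(0)) + count
        totals = {tid: per_origin[origins[tid]] for tid in assignment.counts}
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    records = []
    for transcript in transcripts:
        count = assignment.counts[transcript.id]
        total = totals[transcript.id]
        rpkm = (
            compute_rpkm(float(count), lengths[transcript.id], float(total))
            if total > 0
            else 0.0
        )
        records.append(
            ExpressionRecord(
                transcript_id=transcript.id, raw_count=float(count), rpkm=rpkm
            )
        )
    return records


@dataclass
class AssemblySummary:
    n_sequences: int
    n_contigs: int | None = None
    n_singletons: int | None = None
    longest_bp: int | None = None
    smallest_bp: int | None = None
    mean_bp: float | None = None
    length_histogram: dict[str, int] = field(default_factory=dict)


def _bin_label(lo: float, hi: float) -> str:
    return f">{int(lo) - 1}" if math.isinf(hi) else f"{int(lo)}-{int(hi)}"


def summarize_assembly(
    transcripts: list[Transcript] | None = None,
    n_contigs: int | None = None,
    n_singletons: int | None = None,
    bins: tuple[tuple[int, float], ...] = DEFAULT_LENGTH_BINS,
) -> AssemblySummary:
    """Assembly summary statistics, or counts-only totals.

    With a transcript collection, computes extremes, mean length (one decimal,
    half-up) and a length histogram over ``bins`` (inclusive edges).  In
    counts-only mode (collection omitted) both ``n_contigs`` and
    ``n_singletons`` are required and ``n_sequences`` is their sum.
    """
    if not transcripts:
        if n_contigs is None or n_singletons is None:
            raise ValueError(
                "counts-only mode requires both n_contigs and n_singletons"
            )
        return AssemblySummary(
            n_sequences=n_contigs + n_singletons,
            n_contigs=n_contigs,
            n_singletons=n_singletons,
        )
    lengths = np.array([t.length_bp for t in transcripts])
    if n_contigs is not None and n_singletons is not None:
        if n_contigs + n_singletons != len(lengths):
            raise ValueError("contig + singleton counts must equal the collection size")
    mean = float(
        (Decimal(int(lengths.sum())) / Decimal(len(lengths))).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )
    histogram = {
        _bin_label(lo, hi): int(((lengths >= lo) & (lengths <= hi)).sum())
        for lo, hi in bins
    }
    return AssemblySummary(
        n_sequences=len(lengths),
        n_contigs=n_contigs,
        n_singletons=n_singletons,
        longest_bp=int(lengths.max()),
        smallest_bp=int(lengths.min()),
        mean_bp=mean,
        length_histogram=histogram,
    )


def proportion_percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to 0 or 1 decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    if decimals not in (0, 1):
        raise ValueError("decimals must be 0 or 1")
    quantum = Decimal("1") if decimals == 0 else Decimal("0.1")
    value = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return float(value)


@dataclass(frozen=True)
class QpcrMeasurement:
    """One ddCt quadruple: target/reference Ct in sample and calibrator."""

    ct_target_sample: float
    ct_reference_sample: float
    ct_target_calibrator: float
    ct_reference_calibrator: float

    def __post_init__(self) -> None:
        for value in (
            self.ct_target_sample,
            self.ct_reference_sample,
            self.ct_target_calibrator,
            self.ct_reference_calibrator,
        ):
            if not math.isfinite(value) or value <= 0:
                raise ValueError("Ct values must be finite and positive")


def relative_expression_ddct(m: QpcrMeasurement) -> float:
    """Fold change 2^-ddCt against a reference gene and calibrator sample."""
    ddct = (m.ct_target_sample - m.ct_reference_sample) - (
        m.ct_target_calibrator - m.ct_reference_calibrator
    )
    return float(2.0 ** (-ddct))


def flag_high_expression(
    records: list[ExpressionRecord],
    thresholds: ThresholdConfig | None = None,
) -> list[ExpressionRecord]:
    """Records with RPKM strictly above the high-expression threshold (>50)."""
    thresholds = thresholds or ThresholdConfig()
    return [r for r in records if r.rpkm > thresholds.high_expression_rpkm]
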
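"""Local nucleotide alignment and alignment statistics.

The classifier stands in for a blastn search at desk scale: optimal local
(Smith-Waterman) alignment with affine gap penalties over both strands of the
query, with percent identity and query coverage computed from the traceback,
and Karlin-Altschul E-values for hit significance.

The dynamic programming itself is delegated to ``Bio.Align.PairwiseAligner``
(local mode); ``N`` is treated as a universal mismatch via a custom ACGTN
substitution matrix.  Gap convention: a gap of length ``k`` scores
``gap_open + (k - 1) * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

import numpy as np
from Bio import Align
from scipy.optimize import brentq

from .seqio import reverse_complement

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "local_align",
    "estimate_evalue",
    "karlin_altschul_lambda",
]

_ALPHABET = "ACGTN"


def karlin_altschul_lambda(
    match: float,
    mismatch: float,
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for lambda > 0.

    Requires a negative expected score per aligned pair of random letters,
    the usual condition for local alignment statistics to exist.
    """
    freqs = np.asarray(base_freqs, dtype=float)
    if freqs.shape != (4,) or not np.isclose(freqs.sum(), 1.0):
        raise ValueError("base_freqs must be four probabilities summing to 1")
    scores = np.full((4, 4), mismatch, dtype=float)
    np.fill_diagonal(scores, match)
    expected = float(freqs @ scores @ freqs)
    if expected >= 0:
        raise ValueError("expected score per aligned pair must be negative")
    if match <= 0:
        raise ValueError("match score must be positive")

    def f(lam: float) -> float:
        return float(freqs @ np.exp(lam * scores) @ freqs) - 1.0

    hi = 1.0
    while f(hi) <= 0:
        hi *= 2.0
        if hi > 1e4:  # pragma: no cover - defensive
            raise RuntimeError("failed to bracket lambda")
    return float(brentq(f, 1e-12, hi, xtol=1e-12))


@dataclass
class ScoringScheme:
    """Match/mismatch/affine-gap scores plus Karlin-Altschul parameters.

    ``lam`` (the Karlin-Altschul scale) is solved from the substitution scores
    at ``base_freqs`` when not given.  ``k`` is the E-value prefactor; the
    exact ungapped series is not evaluated here, so ``k`` is a configurable
    constant (default 0.1, the order of magnitude of typical ungapped
    nucleotide values).
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    lam: float | None = None
    k: float = 0.1
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("mismatch and gap scores must be negative")
        if self.k <= 0:
            raise ValueError("K must be positive")
        if self.lam is None:
            self.lam = karlin_altschul_lambda(self.match, self.mismatch, self.base_freqs)
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


@dataclass(frozen=True)
class AlignmentResult:
    """Best local alignment of a query against a subject.

    Spans are 0-based half-open intervals on the *original* (plus-strand)
    query and on the subject.  ``identity_pct`` is matches over aligned
    columns (gap columns included); ``query_coverage_pct`` is the aligned
    query span over the query length.
    """

    score: float
    identity_pct: float
    query_coverage_pct: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    strand: str
    n_matches: int = 0
    n_columns: int = 0

    @property
    def query_span_bp(self) -> int:
        return self.query_span[1] - self.query_span[0]


@lru_cache(maxsize=8)
def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    matrix = Align.substitution_matrices.Array(_ALPHABET, dims=2)
    for a, b in product(_ALPHABET, repeat=2):
        matrix[a, b] = match if (a == b and a != "N") else mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _validate_seq(seq: str, label: str) -> str:
    if not seq:
        raise ValueError(f"{label} sequence must be non-empty")
    seq = seq.upper()
    bad = set(seq) - set(_ALPHABET)
    if bad:
        raise ValueError(f"{label} contains non-nucleotide characters {sorted(bad)}")
    return seq


_EMPTY = AlignmentResult(0.0, 0.0, 0.0, (0, 0), (0, 0), "+")


def alignment_score(query: str, subject: str, scoring: ScoringScheme) -> float:
    """Best local score over both strands (no traceback; fast path)."""
    query = _validate_seq(query, "query")
    subject = _validate_seq(subject, "subject")
    aligner = _aligner(scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend)
    fwd = aligner.score(subject, query)
    rev = aligner.score(subject, reverse_complement(query))
    return float(max(fwd, rev, 0.0))


def local_align(query: str, subject: str, scoring: ScoringScheme) -> AlignmentResult:
    """Maximal-scoring local alignment of ``query`` against ``subject``.

    Both strands of the query are tried and the better kept (ties favour
    plus).  Identity and coverage come from the traceback of the winning
    alignment.
    """
    query = _validate_seq(query, "query")
    subject = _validate_seq(subject, "subject")
    aligner = _aligner(scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend)

    best: AlignmentResult = _EMPTY
    for strand, qseq in (("+", query), ("-", reverse_complement(query))):
        score = aligner.score(subject, qseq)
        if score <= best.score or score <= 0:
            continue
        aln = next(iter(aligner.align(subject, qseq)))
        best = _result_from_alignment(aln, qseq, subject, score, strand, len(query))
    return best


def _result_from_alignment(
    aln, qseq: str, subject: str, score: float, strand: str, query_len: int
) -> AlignmentResult:
    coords = np.asarray(aln.coordinates)
    matches = 0
    columns = 0
    for i in range(coords.shape[1] - 1):
        t0, t1 = coords[0, i], coords[0, i + 1]
        q0, q1 = coords[1, i], coords[1, i + 1]
        dt, dq = t1 - t0, q1 - q0
        columns += int(max(dt, dq))
        if dt and dq:  # diagonal block
            for a, b in zip(subject[t0:t1], qseq[q0:q1]):
                if a == b and a != "N":
                    matches += 1
    q_start, q_end = int(coords[1, 0]), int(coords[1, -1])
    s_start, s_end = int(coords[0, 0]), int(coords[0, -1])
    if strand == "-":
        q_start, q_end = query_len - q_end, query_len - q_start
    identity = 100.0 * matches / columns if columns else 0.0
    coverage = 100.0 * (q_end - q_start) / query_len
    return AlignmentResult(
        score=float(score),
        identity_pct=identity,
        query_coverage_pct=coverage,
        query_span=(q_start, q_end),
        subject_span=(s_start, s_end),
        strand=strand,
        n_matches=matches,
        n_columns=columns,
    )


def estimate_evalue(
    score: float, query_len: int, db_len: int, scoring: ScoringScheme
) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    if score < 0:
        raise ValueError("score must be non-negative")
    if query_len <= 0 or db_len <= 0:
        raise ValueError("sequence lengths must be positive")
    return float(scoring.k * query_len * db_len * np.exp(-scoring.lam * score))
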
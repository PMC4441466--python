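"""Origin binning and homolog screening.

A transcript is attributed to the endosymbiont when its best local alignment
against the symbiont reference exceeds an identity threshold (default >90%,
the blastn rule used for symbiont unitig identification) over a minimum
aligned span; everything else is treated as host.  A separate screen finds
putative homologs of a protein/transporter database at blast-like thresholds
(E-value <= 1e-6, identity and query coverage > 60%).
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import (
    AlignmentResult,
    ScoringScheme,
    alignment_score,
    estimate_evalue,
    local_align,
)
from .seqio import Transcript

__all__ = [
    "ThresholdConfig",
    "OriginCall",
    "HomologHit",
    "classify_origin",
    "classify_origins",
    "screen_homologs",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """All classification cut-offs in one place.

    ``symbiont_identity_pct`` is exclusive (>90 means strictly greater), as
    are the homolog identity/coverage thresholds; ``homolog_evalue_max`` is
    inclusive.  ``min_alignment_span_bp`` guards the symbiont rule against
    spuriously short perfect hits.
    """

    symbiont_identity_pct: float = 90.0
    homolog_evalue_max: float = 1e-6
    homolog_identity_pct: float = 60.0
    homolog_coverage_pct: float = 60.0
    min_alignment_span_bp: int = 50
    high_expression_rpkm: float = 50.0

    def __post_init__(self) -> None:
        for pct in (
            self.symbiont_identity_pct,
            self.homolog_identity_pct,
            self.homolog_coverage_pct,
        ):
            if not 0 < pct <= 100:
                raise ValueError("percentage thresholds must lie in (0, 100]")
        if self.homolog_evalue_max <= 0:
            raise ValueError("e-value threshold must be positive")
        if self.min_alignment_span_bp < 0:
            raise ValueError("minimum span must be non-negative")


@dataclass(frozen=True)
class OriginCall:
    transcript_id: str
    origin: str  # {'host', 'symbiont'}
    identity_pct: float
    query_coverage_pct: float
    subject_id: str | None
    evidence: AlignmentResult | None


@dataclass(frozen=True)
class HomologHit:
    query_id: str
    subject_id: str
    score: float
    e_value: float
    identity_pct: float
    query_coverage_pct: float


def _best_against(
    query: Transcript,
    database: list[Transcript],
    scoring: ScoringScheme,
) -> tuple[str, AlignmentResult]:
    """Best subject by score; ties broken by higher coverage, then subject id.

    Scores are computed without traceback first; the traceback (for identity,
    coverage and spans) is only run for the top-scoring subjects.
    """
    scores = [alignment_score(query.sequence, s.sequence, scoring) for s in database]
    top = max(scores)
    best_id: str | None = None
    best: AlignmentResult | None = None
    for subject, score in zip(database, scores):
        if score < top - 1e-9:
            continue
        result = local_align(query.sequence, subject.sequence, scoring)
        if best is None:
            best_id, best = subject.id, result
            continue
        key = (result.score, result.query_coverage_pct)
        best_key = (best.score, best.query_coverage_pct)
        if key > best_key or (key == best_key and subject.id < best_id):
            best_id, best = subject.id, result
    return best_id, best


def classify_origin(
    transcript: Transcript,
    symbiont_reference: list[Transcript],
    scoring: ScoringScheme | None = None,
    thresholds: ThresholdConfig | None = None,
) -> OriginCall:
    """Attribute one transcript to host or symbiont.

    Symbiont iff the best local alignment over the whole reference has
    identity strictly above ``symbiont_identity_pct`` *and* an aligned query
    span of at least ``min_alignment_span_bp``; host otherwise (including
    transcripts matching nothing at all).
    """
    if not symbiont_reference:
        raise ValueError("symbiont reference must be non-empty")
    scoring = scoring or ScoringScheme()
    thresholds = thresholds or ThresholdConfig()
    subject_id, best = _best_against(transcript, symbiont_reference, scoring)
    is_symbiont = (
        best.identity_pct > thresholds.symbiont_identity_pct
        and best.query_span_bp >= thresholds.min_alignment_span_bp
    )
    return OriginCall(
        transcript_id=transcript.id,
        origin="symbiont" if is_symbiont else "host",
        identity_pct=best.identity_pct,
        query_coverage_pct=best.query_coverage_pct,
        subject_id=subject_id,
        evidence=best,
    )


def classify_origins(
    transcripts: list[Transcript],
    symbiont_reference: list[Transcript],
    scoring: ScoringScheme | None = None,
    thresholds: ThresholdConfig | None = None,
) -> list[OriginCall]:
    scoring = scoring or ScoringScheme()
    thresholds = thresholds or ThresholdConfig()
    return [
        classify_origin(t, symbiont_reference, scoring, thresholds)
        for t in transcripts
    ]


def screen_homologs(
    queries: list[Transcript],
    database: list[Transcript],
    scoring: ScoringScheme | None = None,
    thresholds: ThresholdConfig | None = None,
) -> list[HomologHit]:
    """Top-hit homolog screen at blast-like thresholds.

    For each query only the top-scoring subject is considered; it is kept iff
    E-value <= ``homolog_evalue_max``, identity > ``homolog_identity_pct``
    and query coverage > ``homolog_coverage_pct``.  Hits are returned sorted
    ascending by E-value.
    """
    if not database:
        raise ValueError("homolog database must be non-empty")
    scoring = scoring or ScoringScheme()
    thresholds = thresholds or ThresholdConfig()
    db_len = sum(s.length_bp for s in database)
    hits: list[HomologHit] = []
    for query in queries:
        subject_id, best = _best_against(query, database, scoring)
        e_value = estimate_evalue(best.score, query.length_bp, db_len, scoring)
        if (
            e_value <= thresholds.homolog_evalue_max
            and best.identity_pct > thresholds.homolog_identity_pct
            and best.query_coverage_pct > thresholds.homolog_coverage_pct
        ):
            hits.append(
                HomologHit(
                    query_id=query.id,
                    subject_id=subject_id,
                    score=best.score,
                    e_value=e_value,
                    identity_pct=best.identity_pct,
                    query_coverage_pct=best.query_coverage_pct,
                )
            )
    hits.sort(key=lambda h: (h.e_value, h.query_id))
    return hits
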
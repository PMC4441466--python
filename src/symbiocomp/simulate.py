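"""Synthetic two-organism transcript communities with known ground truth.

The generator emulates the statistical structure of a pooled host-insect /
bacterial-endosymbiont RNA-seq library: symbiont transcripts are near-copies
of a symbiont reference (low per-site divergence, default 2%), host
transcripts are deeply diverged from that reference (default 30%), enzyme
(EC) annotations are planted according to the expected host/symbiont split of
the amino-acid pathways, and reads are drawn from the pool with known
abundance weights and a per-base substitution error rate.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .seqio import ReadSet, SequenceRead, Transcript

__all__ = [
    "CommunitySpec",
    "GroundTruth",
    "TranscriptTruth",
    "generate_community",
    "simulate_reads",
    "default_ec_plan",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_HOST_TERMINAL_ECS = frozenset({"2.6.1.1", "2.6.1.42"})


def default_ec_plan(n_host: int, n_symbiont: int) -> dict[int, frozenset[str]]:
    """Plant the expected partner split of the amino-acid pathway enzymes.

    Non-essential-pathway ECs go on host transcripts; essential-pathway ECs on
    symbiont transcripts, except the terminal aminotransferases EC 2.6.1.1 and
    EC 2.6.1.42, which the symbiont genome lacks and which therefore go on
    host transcripts.  Transcript indices 0..n_host-1 are host,
    n_host..n_host+n_symbiont-1 are symbiont; ECs are dealt round-robin.
    """
    from .complementation import default_pathways

    host_ecs: list[str] = []
    symbiont_ecs: list[str] = []
    seen: set[str] = set()
    for pathway in default_pathways():
        for step in pathway.steps:
            for ec in sorted(step):
                if ec in seen:
                    continue
                seen.add(ec)
                if not pathway.essential or ec in _HOST_TERMINAL_ECS:
                    host_ecs.append(ec)
                else:
                    symbiont_ecs.append(ec)
    plan: dict[int, set[str]] = {}
    if n_host > 0:
        for i, ec in enumerate(host_ecs):
            plan.setdefault(i % n_host, set()).add(ec)
    if n_symbiont > 0:
        for i, ec in enumerate(symbiont_ecs):
            plan.setdefault(n_host + i % n_symbiont, set()).add(ec)
    return {idx: frozenset(ecs) for idx, ecs in plan.items()}


@dataclass
class CommunitySpec:
    """Parameters of the synthetic host+symbiont transcript pool."""

    n_host: int = 25
    n_symbiont: int = 25
    length_range_bp: tuple[int, int] = (300, 900)
    symbiont_divergence: float = 0.02
    host_divergence: float = 0.30
    ec_plan: dict[int, frozenset[str]] | None = None
    abundance_profile: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_host < 0 or self.n_symbiont < 0:
            raise ValueError("transcript counts must be non-negative")
        lo, hi = self.length_range_bp
        if lo > hi or lo <= 0:
            raise ValueError(f"invalid length range {self.length_range_bp}")
        for d in (self.symbiont_divergence, self.host_divergence):
            if not 0.0 <= d <= 1.0:
                raise ValueError("divergences must lie in [0, 1]")
        if self.host_divergence <= self.symbiont_divergence:
            raise ValueError("host divergence must exceed symbiont divergence")
        if self.abundance_profile is not None:
            weights = np.asarray(self.abundance_profile, dtype=float)
            if len(weights) != self.n_host + self.n_symbiont:
                raise ValueError("abundance profile length must match transcript count")
            if not np.all(np.isfinite(weights)) or np.any(weights <= 0):
                raise ValueError("abundance weights must be positive and finite")


@dataclass
class TranscriptTruth:
    origin: str
    ecs: frozenset[str]
    weight: float
    read_count: int = 0


@dataclass
class GroundTruth:
    """Per-transcript truth: origin label, EC set, abundance weight, read count."""

    records: dict[str, TranscriptTruth] = field(default_factory=dict)

    def origin_of(self, transcript_id: str) -> str:
        return self.records[transcript_id].origin

    def total_reads(self) -> int:
        return sum(r.read_count for r in self.records.values())


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, sequence: str, rate: float) -> str:
    """Substitute each site independently with probability ``rate``.

    A substituted site always changes to one of the three other bases, so the
    expected column-wise identity to the template is exactly 1 - rate.
    """
    arr = np.frombuffer(sequence.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    if hit.any():
        idx = np.flatnonzero(hit)
        offsets = rng.integers(1, 4, size=len(idx))
        codes = np.searchsorted(_BASES, arr[idx])
        arr[idx] = _BASES[(codes + offsets) % 4]
    return arr.tobytes().decode()


def generate_community(
    spec: CommunitySpec,
) -> tuple[list[Transcript], list[Transcript], GroundTruth]:
    """Generate (symbiont reference, mixed transcript pool, ground truth).

    Each symbiont transcript is a copy of one reference sequence mutated at
    ``symbiont_divergence``; each host transcript is a reference sequence (or
    a de novo random sequence when no reference exists) mutated at
    ``host_divergence``, modelling deep divergence from the symbiont.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range_bp
    n_total = spec.n_host + spec.n_symbiont

    n_ref = max(spec.n_symbiont, 1)
    ref_lengths = rng.integers(lo, hi + 1, size=n_ref)
    reference = [
        Transcript(id=f"CPA_ref_{i + 1:04d}", sequence=_random_sequence(rng, int(L)))
        for i, L in enumerate(ref_lengths)
    ]

    ec_plan = spec.ec_plan
    if ec_plan is None:
        ec_plan = default_ec_plan(spec.n_host, spec.n_symbiont)
    if spec.abundance_profile is not None:
        weights = np.asarray(spec.abundance_profile, dtype=float)
    else:
        # moderate dispersion, no undetectable genes: every planted enzyme is
        # expressed, as in the reference expression table being emulated
        weights = rng.uniform(0.5, 2.0, size=n_total)

    transcripts: list[Transcript] = []
    truth = GroundTruth()
    for i in range(n_total):
        origin = "host" if i < spec.n_host else "symbiont"
        if origin == "host":
            template = reference[i % n_ref].sequence
            seq = _mutate(rng, template, spec.host_divergence)
        else:
            template = reference[i - spec.n_host].sequence
            seq = _mutate(rng, template, spec.symbiont_divergence)
        ecs = ec_plan.get(i, frozenset())
        tid = f"Unitig_{i + 1:05d}"
        transcripts.append(
            Transcript(id=tid, sequence=seq, ec_annotations=ecs, truth_origin=origin)
        )
        truth.records[tid] = TranscriptTruth(
            origin=origin, ecs=frozenset(ecs), weight=float(weights[i])
        )
    return reference, transcripts, truth


def simulate_reads(
    transcripts: list[Transcript],
    truth: GroundTruth,
    n_reads: int,
    read_length_bp: int = 100,
    error_rate: float = 0.01,
    seed: int = 0,
) -> ReadSet:
    """Draw reads from the pool with probability proportional to weight x length.

    Start positions are uniform along each transcript; substitution errors are
    applied per base at ``error_rate``.  ``truth`` read counts are updated in
    place and sum to ``n_reads``.  Reads are emitted forward-strand, as
    independent single-end reads.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be non-negative")
    if not transcripts:
        raise ValueError("no transcripts to sample from")
    shortest = min(t.length_bp for t in transcripts)
    if read_length_bp > shortest:
        raise ValueError(
            f"read length {read_length_bp} exceeds shortest transcript ({shortest} bp)"
        )
    rng = np.random.default_rng(seed)
    weights = np.array([truth.records[t.id].weight for t in transcripts])
    lengths = np.array([t.length_bp for t in transcripts], dtype=float)
    probs = weights * lengths
    probs /= probs.sum()
    counts = rng.multinomial(n_reads, probs) if n_reads else np.zeros(len(transcripts), int)

    reads: list[SequenceRead] = []
    serial = 0
    for transcript, count in zip(transcripts, counts):
        truth.records[transcript.id].read_count = int(count)
        if count == 0:
            continue
        starts = rng.integers(0, transcript.length_bp - read_length_bp + 1, size=count)
        for start in starts:
            serial += 1
            fragment = transcript.sequence[start : start + read_length_bp]
            if error_rate > 0:
                fragment = _mutate(rng, fragment, error_rate)
            reads.append(SequenceRead(id=f"read_{serial:07d}", sequence=fragment))
    return ReadSet(reads=reads, paired=False)
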
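"""Pathway complementation inference between host insect and endosymbiont.

Given per-transcript origin calls, EC annotations and expression, each
enzymatic step of each amino-acid biosynthesis pathway is assigned a provider
(host, symbiont, both, or none), each pathway is classified as
host-complete / symbiont-complete / chimeric-complete / incomplete, and
"hand-off" steps — adjacent steps provided by different single partners,
implying transport of the intermediate metabolite across the host-symbiont
boundary — are reported.

Pathways are linearized: steps are the printed enzyme list of each amino-acid
block in order, the last step being terminal.  A step may accept several EC
numbers (isofunctional enzymes); it is satisfied by any of them, and a step
satisfied by different partners via different ECs has provider "both".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .binning import OriginCall
from .expression import ExpressionRecord
from .fixtures import FixtureTable
from .seqio import Transcript

__all__ = [
    "PathwayDefinition",
    "EnzymeAssignment",
    "PathwayResult",
    "ComplementationReport",
    "default_pathways",
    "assign_enzyme_provider",
    "pathway_status",
    "classify_pathway",
    "detect_handoffs",
    "build_complementation_report",
    "report_from_fixture",
    "query_expression",
]

_KEGG_MAPS = frozenset({250, 260, 270, 290, 300, 330, 340, 400})

STATUSES = ("host_complete", "symbiont_complete", "chimeric_complete", "incomplete")


@dataclass(frozen=True)
class PathwayDefinition:
    """Ordered enzymatic steps (EC sets) of one amino-acid pathway group."""

    amino_acid: str
    kegg_map: int
    steps: tuple[frozenset[str], ...]
    essential: bool

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError(f"pathway {self.amino_acid} must have at least one step")
        if self.kegg_map not in _KEGG_MAPS:
            raise ValueError(f"unexpected KEGG map number {self.kegg_map}")
        object.__setattr__(
            self, "steps", tuple(frozenset(step) for step in self.steps)
        )

    @property
    def terminal_index(self) -> int:
        return len(self.steps) - 1


@dataclass(frozen=True)
class EnzymeAssignment:
    """Provider attribution for one enzymatic activity (EC set of one step)."""

    ec: str
    provider: str  # {'host', 'symbiont', 'both', 'none'}
    supporting: tuple[tuple[str, str, float], ...] = ()  # (transcript, origin, rpkm)


@dataclass(frozen=True)
class PathwayResult:
    amino_acid: str
    kegg_map: int
    essential: bool
    step_assignments: tuple[EnzymeAssignment, ...]
    status: str
    handoffs: tuple[tuple[int, str, str], ...]


@dataclass
class ComplementationReport:
    """Provider map, status class and hand-off steps for every pathway."""

    pathways: list[PathwayResult] = field(default_factory=list)

    def status_of(self, amino_acid: str) -> str:
        for result in self.pathways:
            if result.amino_acid == amino_acid:
                return result.status
        raise KeyError(amino_acid)

    def result_of(self, amino_acid: str) -> PathwayResult:
        for result in self.pathways:
            if result.amino_acid == amino_acid:
                return result
        raise KeyError(amino_acid)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for result in self.pathways:
            for step_index, assignment in enumerate(result.step_assignments):
                rows.append(
                    {
                        "amino_acid": result.amino_acid,
                        "kegg_map": result.kegg_map,
                        "essential": "yes" if result.essential else "no",
                        "step": step_index,
                        "ec": assignment.ec,
                        "provider": assignment.provider,
                        "status": result.status,
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            result.amino_acid: {
                "kegg_map": result.kegg_map,
                "essential": result.essential,
                "status": result.status,
                "providers": {
                    a.ec: a.provider for a in result.step_assignments
                },
                "handoffs": [
                    {"step": i, "from": src, "to": dst}
                    for i, src, dst in result.handoffs
                ],
            }
            for result in self.pathways
        }


def default_pathways() -> list[PathwayDefinition]:
    """The packaged amino-acid pathway definitions (printed-row order)."""
    ref = resources.files("symbiocomp.data").joinpath("pathways.tsv")
    with ref.open("r", encoding="utf-8") as handle:
        frame = pd.read_csv(handle, sep="\t")
    pathways = []
    for (name, kegg, essential), group in frame.groupby(
        ["amino_acid", "kegg_map", "essential"], sort=False
    ):
        group = group.sort_values("step_index")
        steps = tuple(
            frozenset(ecs.split(",")) for ecs in group["ecs"]
        )
        pathways.append(
            PathwayDefinition(
                amino_acid=name,
                kegg_map=int(kegg),
                steps=steps,
                essential=essential == "yes",
            )
        )
    return pathways


class ConsistencyError(ValueError):
    """Transcript annotated with an EC but missing from the origin calls."""


def _partner_support(
    ecs: frozenset[str] | str,
    origin_calls: dict[str, str],
    expression: dict[str, float],
    annotations: dict[str, frozenset[str]],
    detection_floor_rpkm: float,
) -> tuple[str, tuple[tuple[str, str, float], ...]]:
    wanted = frozenset([ecs]) if isinstance(ecs, str) else frozenset(ecs)
    supporting = []
    for tid, tid_ecs in annotations.items():
        if not wanted & tid_ecs:
            continue
        if tid not in origin_calls:
            raise ConsistencyError(
                f"transcript {tid} is annotated with {sorted(wanted & tid_ecs)} "
                "but has no origin call"
            )
        rpkm = expression.get(tid, 0.0)
        if rpkm > detection_floor_rpkm:
            supporting.append((tid, origin_calls[tid], rpkm))
    supporting.sort(key=lambda row: (-row[2], row[0]))
    partners = {origin for _, origin, _ in supporting}
    if not partners:
        provider = "none"
    elif partners == {"host"}:
        provider = "host"
    elif partners == {"symbiont"}:
        provider = "symbiont"
    else:
        provider = "both"
    return provider, tuple(supporting)


def _normalize_inputs(origin_calls, expression, annotations):
    if not isinstance(origin_calls, dict):
        origin_calls = {c.transcript_id: c.origin for c in origin_calls}
    if not isinstance(expression, dict):
        expression = {r.transcript_id: r.rpkm for r in expression}
    annotations = {tid: frozenset(ecs) for tid, ecs in annotations.items()}
    return origin_calls, expression, annotations


def assign_enzyme_provider(
    ec: str | frozenset[str],
    origin_calls: list[OriginCall] | dict[str, str],
    expression: list[ExpressionRecord] | dict[str, float],
    annotations: dict[str, frozenset[str]],
    detection_floor_rpkm: float = 0.0,
) -> EnzymeAssignment:
    """Attribute one enzymatic activity to the partner(s) expressing it.

    The provider is determined by which partners have at least one annotated
    transcript with RPKM above the detection floor (default 0: any expressed
    transcript counts).  Supporting transcripts are listed by descending RPKM.
    """
    origin_calls, expression, annotations = _normalize_inputs(
        origin_calls, expression, annotations
    )
    provider, supporting = _partner_support(
        ec, origin_calls, expression, annotations, detection_floor_rpkm
    )
    label = ec if isinstance(ec, str) else "/".join(sorted(ec))
    return EnzymeAssignment(ec=label, provider=provider, supporting=supporting)


def pathway_status(providers: list[str]) -> str:
    """Status class of a provider vector.

    incomplete iff any step has provider none; host_complete iff every step is
    host or both with at least one host-only step; symbiont_complete
    symmetrically; chimeric_complete otherwise (including all-both).
    """
    for provider in providers:
        if provider not in ("host", "symbiont", "both", "none"):
            raise ValueError(f"unknown provider {provider!r}")
    if "none" in providers:
        return "incomplete"
    if all(p in ("host", "both") for p in providers) and "host" in providers:
        return "host_complete"
    if all(p in ("symbiont", "both") for p in providers) and "symbiont" in providers:
        return "symbiont_complete"
    return "chimeric_complete"


def classify_pathway(
    defn: PathwayDefinition, assignments: list[EnzymeAssignment]
) -> str:
    if len(assignments) != len(defn.steps):
        raise ValueError(
            f"pathway {defn.amino_acid}: {len(assignments)} assignments for "
            f"{len(defn.steps)} steps"
        )
    return pathway_status([a.provider for a in assignments])


def detect_handoffs(
    defn: PathwayDefinition, assignments: list[EnzymeAssignment]
) -> list[tuple[int, str, str]]:
    """Steps where the providing partner changes between adjacent steps.

    Emits (step index, from-partner, to-partner) whenever two adjacent steps
    are each provided by a single (and different) partner; steps with provider
    'both' or 'none' break no hand-off.
    """
    if len(assignments) != len(defn.steps):
        raise ValueError(
            f"pathway {defn.amino_acid}: {len(assignments)} assignments for "
            f"{len(defn.steps)} steps"
        )
    handoffs = []
    for i in range(1, len(assignments)):
        prev, curr = assignments[i - 1].provider, assignments[i].provider
        if {prev, curr} <= {"host", "symbiont"} and prev != curr:
            handoffs.append((i, prev, curr))
    return handoffs


def build_complementation_report(
    pathways: list[PathwayDefinition],
    origin_calls: list[OriginCall] | dict[str, str],
    expression: list[ExpressionRecord] | dict[str, float],
    annotations: dict[str, frozenset[str]],
    detection_floor_rpkm: float = 0.0,
) -> ComplementationReport:
    """Run the full provider/status/hand-off inference over every pathway.

    Rows are ordered deterministically: non-essential pathways first, then by
    amino-acid name within each block.
    """
    names = [p.amino_acid for p in pathways]
    if len(names) != len(set(names)):
        raise ValueError("duplicated amino-acid names in pathway collection")
    origin_calls, expression, annotations = _normalize_inputs(
        origin_calls, expression, annotations
    )
    results = []
    for defn in sorted(pathways, key=lambda p: (p.essential, p.amino_acid)):
        assignments = [
            assign_enzyme_provider(
                step, origin_calls, expression, annotations, detection_floor_rpkm
            )
            for step in defn.steps
        ]
        status = classify_pathway(defn, assignments)
        handoffs = detect_handoffs(defn, assignments)
        results.append(
            PathwayResult(
                amino_acid=defn.amino_acid,
                kegg_map=defn.kegg_map,
                essential=defn.essential,
                step_assignments=tuple(assignments),
                status=status,
                handoffs=tuple(handoffs),
            )
        )
    return ComplementationReport(pathways=results)


def report_from_fixture(
    fixture: FixtureTable, pathways: list[PathwayDefinition] | None = None
) -> ComplementationReport:
    """Re-ingest the packaged pathway/expression table as (origin, EC, RPKM).

    Each fixture row carries exactly one RPKM value; the partner holding it
    defines the transcript's origin.
    """
    if fixture.name != "pathway_expression":
        raise ValueError("expected the pathway_expression fixture")
    pathways = pathways if pathways is not None else default_pathways()
    origin_calls: dict[str, str] = {}
    expression: dict[str, float] = {}
    annotations: dict[str, set[str]] = {}
    for row in fixture.frame.itertuples():
        origin = "symbiont" if pd.notna(row.symbiont_rpkm) else "host"
        rpkm = row.symbiont_rpkm if origin == "symbiont" else row.insect_rpkm
        origin_calls[row.unitig] = origin
        expression[row.unitig] = float(rpkm)
        annotations.setdefault(row.unitig, set()).add(row.ec)
    return build_complementation_report(
        pathways,
        origin_calls,
        expression,
        {tid: frozenset(ecs) for tid, ecs in annotations.items()},
    )


def query_expression(
    source: ComplementationReport | FixtureTable,
    ec: str | None = None,
    partner: str | None = None,
) -> list[float]:
    """All RPKM values matching an EC (and optionally a partner), descending.

    Works on a complementation report (via its supporting transcripts) or
    directly on the packaged fixtures; absent combinations yield an empty
    list.
    """
    import re

    if ec is not None and not re.match(r"^\d+\.\d+\.\d+\.(?:\d+|-)$", ec):
        raise ValueError(f"malformed EC number: {ec!r}")
    if partner not in (None, "host", "symbiont"):
        raise ValueError(f"unknown partner {partner!r}")

    values: list[float] = []
    if isinstance(source, ComplementationReport):
        for result in source.pathways:
            for assignment in result.step_assignments:
                if ec is not None and ec not in assignment.ec.split("/"):
                    continue
                for _, origin, rpkm in assignment.supporting:
                    if partner is None or origin == partner:
                        values.append(rpkm)
    elif isinstance(source, FixtureTable):
        frame = source.frame
        if source.name == "pathway_expression":
            if ec is not None:
                frame = frame[frame["ec"] == ec]
            if partner == "host":
                values = frame["insect_rpkm"].dropna().tolist()
            elif partner == "symbiont":
                values = frame["symbiont_rpkm"].dropna().tolist()
            else:
                values = (
                    frame["insect_rpkm"].dropna().tolist()
                    + frame["symbiont_rpkm"].dropna().tolist()
                )
        elif source.name == "transporter_homologs":
            values = frame["rpkm"].dropna().tolist()
        else:
            raise ValueError(f"fixture {source.name!r} holds no expression values")
    else:
        raise TypeError(f"cannot query {type(source).__name__}")
    return sorted((float(v) for v in values), reverse=True)
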
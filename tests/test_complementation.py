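"""Provider assignment, pathway status classes and hand-off detection."""

from itertools import product

import pytest

from symbiocomp import (
    ComplementationReport,
    EnzymeAssignment,
    PathwayDefinition,
    assign_enzyme_provider,
    build_complementation_report,
    classify_pathway,
    default_pathways,
    detect_handoffs,
    load_fixture,
    pathway_status,
    report_from_fixture,
)
from symbiocomp.complementation import ConsistencyError

PROVIDERS = ("host", "symbiont", "both", "none")


def rule_oracle(providers):
    """Literal restatement of the status rule, kept independent of the
    implementation: incomplete iff any none; host_complete iff all in
    {host, both} with >=1 host; symbiont_complete symmetric; else chimeric."""
    if any(p == "none" for p in providers):
        return "incomplete"
    if set(providers) <= {"host", "both"} and "host" in providers:
        return "host_complete"
    if set(providers) <= {"symbiont", "both"} and "symbiont" in providers:
        return "symbiont_complete"
    return "chimeric_complete"


def make_defn(k, name="test", essential=True):
    return PathwayDefinition(
        amino_acid=name, kegg_map=400,
        steps=tuple(frozenset({f"1.1.1.{i + 1}"}) for i in range(k)),
        essential=essential,
    )


def make_assignments(providers):
    return [
        EnzymeAssignment(ec=f"1.1.1.{i + 1}", provider=p)
        for i, p in enumerate(providers)
    ]


def test_status_equals_rule_oracle_for_all_vectors_up_to_four_steps():
    """Exhaustive agreement with a brute-force rule evaluation over every
    provider vector of length 1..4 (4 + 16 + 64 + 256 cases)."""
    for k in range(1, 5):
        defn = make_defn(k)
        for providers in product(PROVIDERS, repeat=k):
            expected = rule_oracle(providers)
            assert pathway_status(list(providers)) == expected
            assert classify_pathway(defn, make_assignments(providers)) == expected


def test_all_both_pathway_is_chimeric():
    assert pathway_status(["both", "both"]) == "chimeric_complete"


def test_assignment_count_must_match_steps():
    with pytest.raises(ValueError):
        classify_pathway(make_defn(3), make_assignments(["host"]))
    with pytest.raises(ValueError):
        detect_handoffs(make_defn(3), make_assignments(["host"]))


@pytest.mark.parametrize(
    "providers,expected",
    [
        (["symbiont", "symbiont", "host"], [(2, "symbiont", "host")]),
        (["host", "host", "host"], []),
        (["host"], []),
        (["symbiont", "both", "host"], []),  # 'both' breaks no hand-off
        (["symbiont", "none", "host"], []),
        (["host", "symbiont", "host"], [(1, "host", "symbiont"), (2, "symbiont", "host")]),
    ],
)
def test_handoff_detection(providers, expected):
    defn = make_defn(len(providers))
    assert detect_handoffs(defn, make_assignments(providers)) == expected


def test_provider_from_expressed_support():
    origin_calls = {"u1": "symbiont", "u2": "symbiont", "u3": "host"}
    expression = {"u1": 16.4, "u2": 25.6, "u3": 0.0}
    annotations = {
        "u1": frozenset({"4.2.1.20"}),
        "u2": frozenset({"4.2.1.20"}),
        "u3": frozenset({"4.2.1.20"}),
    }
    assignment = assign_enzyme_provider("4.2.1.20", origin_calls, expression, annotations)
    assert assignment.provider == "symbiont"  # u3 has no expression
    assert [row[0] for row in assignment.supporting] == ["u2", "u1"]  # desc rpkm


def test_provider_none_without_expressed_support():
    assignment = assign_enzyme_provider(
        "1.1.1.1", {"u1": "host"}, {"u1": 0.0}, {"u1": frozenset({"1.1.1.1"})}
    )
    assert assignment.provider == "none"


def test_provider_both_via_different_ecs_of_one_step():
    origin_calls = {"u_host": "host", "u_sym": "symbiont"}
    expression = {"u_host": 30.1, "u_sym": 16.2}
    annotations = {
        "u_host": frozenset({"2.1.1.10"}),
        "u_sym": frozenset({"2.1.1.14"}),
    }
    assignment = assign_enzyme_provider(
        frozenset({"2.1.1.10", "2.1.1.14"}), origin_calls, expression, annotations
    )
    assert assignment.provider == "both"


def test_annotated_transcript_missing_from_origin_calls_is_an_error():
    with pytest.raises(ConsistencyError):
        assign_enzyme_provider(
            "1.1.1.1", {}, {"u1": 5.0}, {"u1": frozenset({"1.1.1.1"})}
        )


def test_empty_pathway_collection_gives_empty_report():
    report = build_complementation_report([], {}, {}, {})
    assert report.pathways == []


def test_duplicate_pathway_names_rejected():
    with pytest.raises(ValueError):
        build_complementation_report(
            [make_defn(1, "x"), make_defn(2, "x")], {}, {}, {}
        )


def test_report_order_is_non_essential_then_alphabetical():
    report = report_from_fixture(load_fixture("pathway_expression"))
    essentials = [p.essential for p in report.pathways]
    assert essentials == sorted(essentials)
    names_non = [p.amino_acid for p in report.pathways if not p.essential]
    names_ess = [p.amino_acid for p in report.pathways if p.essential]
    assert names_non == sorted(names_non)
    assert names_ess == sorted(names_ess)


def test_fixture_report_reproduces_published_narrative():
    """Tryptophan/threonine have no host-only gap; the branched-chain and
    phenylalanine pathways end in a host terminal step fed by the symbiont."""
    report = report_from_fixture(load_fixture("pathway_expression"))
    for result in report.pathways:
        if not result.essential:
            assert result.status == "host_complete"
    assert report.status_of("tryptophan") == "symbiont_complete"
    for amino_acid in ("tryptophan", "threonine"):
        assert report.status_of(amino_acid) != "incomplete"
        providers = [a.provider for a in report.result_of(amino_acid).step_assignments]
        assert "none" not in providers
    for amino_acid in ("valine_leucine_isoleucine", "phenylalanine"):
        result = report.result_of(amino_acid)
        assert result.status == "chimeric_complete"
        assert result.step_assignments[-1].provider == "host"
        terminal = len(result.step_assignments) - 1
        assert (terminal, "symbiont", "host") in result.handoffs


def test_permutation_invariance_of_fixture_report():
    fixture = load_fixture("pathway_expression")
    shuffled = fixture.to_frame().sample(frac=1.0, random_state=3).reset_index(drop=True)
    from symbiocomp.fixtures import FixtureTable

    report_a = report_from_fixture(fixture)
    report_b = report_from_fixture(FixtureTable("pathway_expression", shuffled))
    assert {p.amino_acid: p.status for p in report_a.pathways} == {
        p.amino_acid: p.status for p in report_b.pathways
    }
    assert {p.amino_acid: p.handoffs for p in report_a.pathways} == {
        p.amino_acid: p.handoffs for p in report_b.pathways
    }


def test_adding_host_support_never_breaks_a_complete_pathway():
    """Monotonicity: an extra expressed host transcript can only move a
    provider none->host or symbiont->both, never complete->incomplete."""
    pathways = [make_defn(3, "toy")]
    origin_calls = {"s1": "symbiont", "s2": "symbiont", "s3": "symbiont"}
    expression = {"s1": 5.0, "s2": 5.0, "s3": 5.0}
    annotations = {
        "s1": frozenset({"1.1.1.1"}),
        "s2": frozenset({"1.1.1.2"}),
        "s3": frozenset({"1.1.1.3"}),
    }
    before = build_complementation_report(pathways, origin_calls, expression, annotations)
    assert before.status_of("toy") == "symbiont_complete"
    origin_calls["h1"] = "host"
    expression["h1"] = 9.0
    annotations["h1"] = frozenset({"1.1.1.2"})
    after = build_complementation_report(pathways, origin_calls, expression, annotations)
    assert after.status_of("toy") != "incomplete"
    assert after.result_of("toy").step_assignments[1].provider == "both"


def test_default_pathways_structure():
    pathways = {p.amino_acid: p for p in default_pathways()}
    assert len(pathways) == 18
    assert len(pathways["valine_leucine_isoleucine"].steps) == 7
    assert pathways["valine_leucine_isoleucine"].steps[-1] == frozenset({"2.6.1.42"})
    assert pathways["methionine"].steps[0] == frozenset({"2.1.1.10", "2.1.1.14"})
    assert sum(1 for p in pathways.values() if not p.essential) == 10


def test_report_serialization_round_trip(tmp_path):
    from symbiocomp import write_report
    from symbiocomp.seqio import read_table

    report = report_from_fixture(load_fixture("pathway_expression"))
    write_report(report, tmp_path / "rep.tsv", "tsv")
    back = read_table(tmp_path / "rep.tsv")
    assert set(back["status"]) == {
        "host_complete", "symbiont_complete", "chimeric_complete"
    }
    write_report(report, tmp_path / "rep.json", "json")
    import json

    payload = json.loads((tmp_path / "rep.json").read_text())
    assert payload["valine_leucine_isoleucine"]["handoffs"] == [
        {"step": 6, "from": "symbiont", "to": "host"}
    ]
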
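"""ACD parsing, OBO import, taxonomy building, auto-domain fidelity, stats."""

import pytest

from flowsynth import workbench
from flowsynth.domain_model import subsumes, validate_domain
from flowsynth.errors import ParseError, UnknownNameError
from flowsynth.importers import (
    TermRef,
    annotation_stats,
    build_auto_domain,
    parse_acd,
    parse_obo,
    sanitize,
    taxonomy_from_ontology,
)

MINI_OBO = """\
[Term]
id: X:1
name: data

[Term]
id: X:2
name: sequence record
is_a: X:1 ! data

[Term]
id: X:3
name: protein sequence record
is_a: X:2

[Term]
id: X:9
name: retired thing
is_a: X:1
is_obsolete: true
"""


class TestParseACD:
    def test_edialign_fixture_anatomy(self):
        doc = parse_acd(workbench.load_fixture("edialign_acd"))
        assert doc.application.name == "edialign"
        assert doc.application.attributes["groups"] == "Alignment:Multiple"
        by_kind = {s.kind: s.parameters for s in doc.sections}
        assert [p.datatype for p in by_kind["input"]] == ["seqset"]
        assert sorted(p.datatype for p in by_kind["output"]) == ["outfile", "seqoutall"]
        seqset = by_kind["input"][0]
        assert seqset.relations and seqset.relations[0].id == "EDAM:0000003"
        # unknown attributes survive verbatim
        assert seqset.attributes["type"] == "gapany"

    def test_application_only_document(self):
        doc = parse_acd('application: nothing [\n  documentation: "No parameters."\n]\n')
        assert doc.application.name == "nothing"
        assert doc.parameters() == []

    def test_every_parameter_relation_is_captured(self):
        text = (
            "application: toy [ ]\n"
            "section: input [ ]\n"
            '  infile: a [ relation: "EDAM: 1 ! alpha" ]\n'
            '  infile: b [ relation: "EDAM: 2 ! beta" ]\n'
            "endsection: input\n"
            "section: output [ ]\n"
            '  outfile: c [ relation: "EDAM: 3 ! gamma" relation: "EDAM: 4 ! delta" ]\n'
            "endsection: output\n"
        )
        doc = parse_acd(text)
        assert [len(p.relations) for p in doc.parameters()] == [1, 1, 2]

    @pytest.mark.parametrize(
        "text,match",
        [
            ("section: input [ ]\nendsection: input\n", "application"),
            ("application: x [\n", "never closed"),
            ("application: x [ ]\nsection: input [ ]\n  infile: a [ ]\n  infile: a [ ]\n"
             "endsection: input\n", "duplicate parameter"),
            ("application: x [ ]\nsection: input [ ]\nendsection: output\n", "does not match"),
            ("application: x [ ]\ninfile: stray [ ]\n", "outside any section"),
        ],
    )
    def test_malformed_documents(self, text, match):
        with pytest.raises(ParseError, match=match):
            parse_acd(text)

    def test_quoted_string_spans_lines(self):
        doc = parse_acd('application: x [\n  documentation: "two\nlines"\n]\n')
        assert doc.application.attributes["documentation"] == "two\nlines"


class TestTermRef:
    def test_standard_form(self):
        ref = TermRef.parse("EDAM: 0001929 ! sequence_record")
        assert ref == TermRef(id="EDAM:0001929", label="sequence_record")

    def test_lenient_fallback(self):
        assert TermRef.parse("just a label").id is None


class TestParseOBO:
    def test_empty_text(self):
        assert parse_obo("").terms == {}

    def test_mini_chain(self):
        onto = parse_obo(MINI_OBO)
        assert len(onto.terms) == 4
        assert onto.terms["X:3"].parents == ("X:2",)
        assert onto.terms["X:2"].parents == ("X:1",)
        assert onto.terms["X:9"].obsolete

    def test_stanza_without_id_is_parse_error(self):
        with pytest.raises(ParseError, match="without id"):
            parse_obo("[Term]\nname: orphan\n")

    def test_bundled_ontology(self):
        onto = parse_obo(workbench.load_fixture("mini_edam_obo"))
        assert "EDAM:0000003" in onto
        assert {t.name for t in onto.top_level()} == {"data", "operation"}


class TestTaxonomyFromOntology:
    def test_chain_becomes_subsumption(self):
        tax = taxonomy_from_ontology(parse_obo(MINI_OBO), {"X:1"})
        assert subsumes(tax, "sequence_record", "protein_sequence_record")
        assert subsumes(tax, "data", "protein_sequence_record")
        assert not tax.cycles()

    def test_obsolete_terms_excluded(self):
        tax = taxonomy_from_ontology(parse_obo(MINI_OBO), {"X:1"})
        assert "retired_thing" not in tax.classes

    def test_empty_roots(self):
        tax = taxonomy_from_ontology(parse_obo(MINI_OBO), set())
        assert tax.classes == {tax.root}

    def test_unknown_root(self):
        with pytest.raises(UnknownNameError):
            taxonomy_from_ontology(parse_obo(MINI_OBO), {"X:404"})

    def test_bundled_type_branch(self):
        onto = parse_obo(workbench.load_fixture("mini_edam_obo"))
        tax = taxonomy_from_ontology(onto, {"EDAM:0000001"})
        for cls in ("identifier", "sequence_record", "sequence_report",
                    "sequence_signature", "sequence_profile_alignment"):
            assert cls in tax.classes
        assert subsumes(tax, "sequence_record", "dna_sequence_record")


from reference_tables import TABLE3


class TestBuildAutoDomain:
    def test_reference_table_reproduced_cell_for_cell(self, auto_domain):
        assert set(auto_domain.services) == set(TABLE3)
        for name, (ins, outs) in TABLE3.items():
            svc = auto_domain.services[name]
            assert svc.inputs == frozenset(ins), name
            assert svc.outputs == frozenset(outs), name

    def test_validates_clean_with_no_unknown_types(self, auto_domain):
        assert [d for d in validate_domain(auto_domain) if d.code == "unknown-type"] == []
        assert validate_domain(auto_domain) == []

    def test_service_taxonomy_placement(self, auto_domain):
        tax = auto_domain.service_taxonomy
        assert subsumes(tax, "sequence_alignment", "edialign")
        assert subsumes(tax, "sequence_alignment", "emma")
        assert subsumes(tax, "sequence_visualisation", "showalign")
        # the rest stay direct instances of the root
        for name in set(TABLE3) - {"edialign", "emma", "showalign"}:
            assert tax.instance_of[name] in (set(), {tax.root})

    def test_alignment_outputs_classified_as_records_only(self, auto_domain):
        tax = auto_domain.type_taxonomy
        assert subsumes(tax, "sequence_record", "emma_seqoutset_output")
        assert subsumes(tax, "sequence_record", "edialign_seqoutall_output")
        # the alignment display input remains unconnected to any record type
        assert tax.instance_of["sequence_alignment_data"] in (set(), {tax.root})

    def test_acd_without_parameters_gives_empty_service(self):
        onto = parse_obo(workbench.load_fixture("mini_edam_obo"))
        doc = parse_acd("application: bare [ ]\n")
        domain = build_auto_domain([doc], onto)
        assert domain.services["bare"].inputs == frozenset()
        assert domain.services["bare"].outputs == frozenset()


class TestAnnotationStats:
    def test_no_relations_anywhere(self):
        docs = [parse_acd("application: a [ ]\nsection: input [ ]\n  infile: x [ ]\nendsection: input\n")]
        stats = annotation_stats(docs)
        assert stats.pct_files_with_any_relation == 0
        assert stats.pct_parameters_with_relation == 0

    def test_hand_counted_fixture(self):
        def doc(app, app_rel, annotated, plain):
            lines = [f"application: {app} ["]
            if app_rel:
                lines.append('  relation: "EDAM: 9 ! something"')
            lines += ["]", "section: input [ ]"]
            for i in range(annotated):
                lines.append(f'  infile: a{i} [ relation: "EDAM: {i} ! term" ]')
            for i in range(plain):
                lines.append(f"  infile: p{i} [ ]")
            lines += ["endsection: input"]
            return parse_acd("\n".join(lines) + "\n")

        # 3 files: two annotated, one bare; 9 of 10 parameters annotated
        docs = [doc("one", True, 4, 0), doc("two", False, 5, 1), doc("three", False, 0, 0)]
        stats = annotation_stats(docs)
        assert stats.n_files == 3
        assert stats.pct_files_with_any_relation == pytest.approx(200 / 3)
        assert stats.pct_files_with_application_relation == pytest.approx(100 / 3)
        assert stats.pct_files_with_parameter_relation == pytest.approx(200 / 3)
        assert stats.pct_parameters_with_relation == pytest.approx(90.0)
        assert stats.app_relations_per_file == (1, 1, 1.0)
        assert stats.param_relations_per_file == (4, 5, 4.5)

    def test_empty_collection(self):
        stats = annotation_stats([])
        assert stats.n_files == 0
        assert stats.app_relations_per_file == (0, 0, 0.0)

    def test_bundled_fixture_coverage(self):
        docs = [parse_acd(t) for t in workbench.acd_texts().values()]
        stats = annotation_stats(docs)
        assert stats.n_files == 17
        assert stats.pct_files_with_any_relation == 100.0
        assert 0 < stats.pct_files_with_application_relation < 100
        invariant_min, invariant_max, invariant_mean = stats.param_relations_per_file
        assert invariant_min <= invariant_mean <= invariant_max


def test_sanitize_labels():
    assert sanitize("HMMER hidden Markov model") == "hmmer_hidden_markov_model"
    assert sanitize("  edialign output ") == "edialign_output"
    assert sanitize("weird--chars!!") == "weird_chars"
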
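import random

import pytest

from alignqc.alignment_io import Relation
from alignqc.checks import (
    STATUS_FINDINGS,
    STATUS_NOT_APPLICABLE,
    STATUS_PASS,
    STATUS_SKIPPED,
    RunOptions,
    check1_input_provenance,
    check2a_missing_classes,
    check2b_label_changes,
    check3_format,
    check4_reference_ambiguity,
    check5_relation_types,
    check6_multiple_targets,
    check7_inferred_subclass,
    check8_label_identity,
    check9_label_inclusion,
    check10_trivial,
    inferred_subsumptions,
    run_all,
)
from alignqc.alignment_io import resolve_references
from conftest import brute_force_entailed, build_doc, make_alignment

NS1 = "http://example.org/one#"
NS2 = "http://example.org/two#"


def pair_docs():
    doc1 = build_doc(
        NS1,
        {"Heart": "heart", "Aorta": "aorta", "Valve": "valve"},
        iri="http://example.org/one",
    )
    doc2 = build_doc(
        NS2,
        {"Heart": "heart", "Aorta": "aorta", "Valve": "valve"},
        iri="http://example.org/two",
    )
    return doc1, doc2


class TestCheck1:
    def test_pass_when_bundled_and_versioned(self):
        doc1, doc2 = pair_docs()
        alignment = make_alignment(
            [(NS1 + "Heart", NS2 + "Heart")],
            onto1_ref="http://example.org/one",
            onto2_ref="http://example.org/two",
        )
        assert check1_input_provenance(alignment, doc1, doc2).status == STATUS_PASS

    def test_url_only_references(self):
        doc1, doc2 = pair_docs()
        alignment = make_alignment(
            [(NS1 + "Heart", NS2 + "Heart")],
            onto1_ref="http://download.example.org/one.owl",
            onto2_ref="http://download.example.org/two.owl",
        )
        report = check1_input_provenance(alignment, doc1, doc2)
        assert report.status == STATUS_FINDINGS
        assert sum(f.category == "url_reference" for f in report.findings) == 2

    def test_missing_version_info(self):
        doc1, doc2 = pair_docs()
        doc2.version_info = ""
        alignment = make_alignment(
            [(NS1 + "Heart", NS2 + "Heart")],
            onto1_ref="http://example.org/one",
            onto2_ref="http://example.org/two",
        )
        report = check1_input_provenance(alignment, doc1, doc2)
        assert [f.category for f in report.findings] == ["version_unverifiable"]

    def test_empty_refs(self):
        doc1, doc2 = pair_docs()
        alignment = make_alignment([(NS1 + "Heart", NS2 + "Heart")])
        report = check1_input_provenance(alignment, doc1, doc2)
        assert sum(f.category == "no_ontology_reference"
                   for f in report.findings) == 2


class TestCheck2a:
    def test_all_resolved_passes(self):
        doc1, doc2 = pair_docs()
        alignment = resolve_references(
            make_alignment([(NS1 + "Heart", NS2 + "Heart")]), doc1, doc2
        )
        assert check2a_missing_classes(alignment, doc1, doc2).status == STATUS_PASS

    def test_missing_counts(self):
        doc1, doc2 = pair_docs()
        alignment = resolve_references(
            make_alignment(
                [
                    (NS1 + "Ghost", NS2 + "Heart"),
                    (NS1 + "Ghost", NS2 + "Aorta"),
                    (NS1 + "Heart", NS2 + "Phantom"),
                ]
            ),
            doc1,
            doc2,
        )
        report = check2a_missing_classes(alignment, doc1, doc2)
        assert report.summary_counts["missing_classes"] == 2
        assert report.summary_counts["affected_correspondences"] == 3


class TestCheck2b:
    def test_not_applicable_without_tables(self):
        doc1, doc2 = pair_docs()
        report = check2b_label_changes(None, None, doc1, doc2)
        assert report.status == STATUS_NOT_APPLICABLE

    def test_label_change_detected(self):
        doc1, doc2 = pair_docs()
        doc1.classes[NS1 + "Heart"].labels = [("Cerebral Cortex", "")]
        table = [(NS1 + "Heart", "Cortex"), (NS1 + "Aorta", "aorta")]
        report = check2b_label_changes(table, None, doc1, doc2)
        changed = [f for f in report.findings if f.category == "label_changed"]
        assert len(changed) == 1
        assert changed[0].evidence["old_label"] == "Cortex"
        assert changed[0].evidence["new_label"] == "Cerebral Cortex"

    def test_swap_suspicion(self):
        doc1, doc2 = pair_docs()
        doc1.classes[NS1 + "Heart"].labels = [("brain grey matter", "")]
        doc1.classes[NS1 + "Aorta"].labels = [("brain white matter", "")]
        table = [
            (NS1 + "Heart", "brain white matter"),
            (NS1 + "Aorta", "brain grey matter"),
        ]
        report = check2b_label_changes(table, None, doc1, doc2)
        swaps = [f for f in report.findings if f.category == "swap_suspicion"]
        assert len(swaps) == 1
        assert set(swaps[0].entities) == {NS1 + "Heart", NS1 + "Aorta"}

    def test_absent_uri_routed_as_missing_class(self):
        doc1, doc2 = pair_docs()
        report = check2b_label_changes([(NS1 + "Gone", "label")], None, doc1, doc2)
        assert [f.category for f in report.findings] == ["missing_class"]


class TestCheck3:
    def test_alignment_api_passes(self, tmp_path):
        path = tmp_path / "ok.rdf"
        make_and_write = make_alignment([(NS1 + "A", NS2 + "B")])
        from alignqc.alignment_io import write_alignment

        write_alignment(make_and_write, path)
        assert check3_format(path).status == STATUS_PASS

    def test_delimited_is_non_standard(self, tmp_path):
        path = tmp_path / "lod.csv"
        path.write_text("Heart,Heart,equivalent\nBad row only two\n")
        report = check3_format(path)
        categories = [f.category for f in report.findings]
        assert "non_standard_format" in categories
        assert "format_irregularity" in categories


class TestCheck4:
    def test_uri_refs_pass(self):
        doc1, doc2 = pair_docs()
        alignment = resolve_references(
            make_alignment([(NS1 + "Heart", NS2 + "Heart")]), doc1, doc2
        )
        assert check4_reference_ambiguity(alignment, doc1, doc2).status == STATUS_PASS

    def test_ambiguous_local_name(self):
        from alignqc.alignment_io import (
            Alignment,
            Correspondence,
            EntityRef,
        )

        doc1, doc2 = pair_docs()
        doc2.classes["http://example.org/alt#Heart"] = type(
            doc2.classes[NS2 + "Heart"]
        )(uri="http://example.org/alt#Heart")
        alignment = resolve_references(
            Alignment(
                correspondences=[
                    Correspondence(
                        entity1=EntityRef.from_token("Heart"),
                        entity2=EntityRef.from_token("Heart"),
                        relation=Relation.EQUIVALENT,
                        row_provenance="row:1",
                    )
                ]
            ),
            doc1,
            doc2,
        )
        report = check4_reference_ambiguity(alignment, doc1, doc2)
        assert len(report.findings) == 1
        assert len(report.findings[0].evidence["candidates"]) == 2


class TestCheck5:
    def test_typed_passes(self):
        alignment = make_alignment([(NS1 + "A", NS2 + "B")])
        assert check5_relation_types(alignment).status == STATUS_PASS

    def test_unknowns_flagged(self):
        alignment = make_alignment(
            [
                (NS1 + "A", NS2 + "B", Relation.UNKNOWN),
                (NS1 + "C", NS2 + "D", Relation.EQUIVALENT),
                (NS1 + "E", NS2 + "F", Relation.UNKNOWN),
            ]
        )
        report = check5_relation_types(alignment)
        assert len(report.findings) == 2


class TestCheck6:
    def test_injective_alignment_passes(self):
        doc1, doc2 = pair_docs()
        alignment = resolve_references(
            make_alignment(
                [(NS1 + "Heart", NS2 + "Heart"), (NS1 + "Aorta", NS2 + "Aorta")]
            ),
            doc1,
            doc2,
        )
        assert check6_multiple_targets(alignment, doc1, doc2).status == STATUS_PASS

    @pytest.mark.parametrize(
        "edges,expected",
        [
            ({"equivalence": [("Heart", "Aorta")]}, "equivalentClass"),
            ({"subclass": [("Heart", "Aorta")]}, "subClassOf"),
            ({"partof": [("Heart", "Aorta")]}, "partOf"),
            ({"disjoint": [("Heart", "Aorta")]}, "disjoint"),
            ({}, "none"),
        ],
    )
    def test_target_pair_classification(self, edges, expected):
        doc1, _ = pair_docs()
        doc2 = build_doc(
            NS2,
            {"Heart": "heart", "Aorta": "aorta", "Valve": "valve"},
            **edges,
        )
        alignment = resolve_references(
            make_alignment(
                [(NS1 + "Heart", NS2 + "Heart"), (NS1 + "Heart", NS2 + "Aorta")]
            ),
            doc1,
            doc2,
        )
        report = check6_multiple_targets(alignment, doc1, doc2)
        assert len(report.findings) == 1
        finding = report.findings[0]
        assert finding.entities[0] == NS1 + "Heart"
        assert finding.evidence["target_relations"][0]["relation"] == expected

    def test_sibling_classification(self):
        doc1, _ = pair_docs()
        doc2 = build_doc(
            NS2,
            {"Heart": "h", "Aorta": "a", "Root": "r"},
            subclass=[("Heart", "Root"), ("Aorta", "Root")],
        )
        alignment = resolve_references(
            make_alignment(
                [(NS1 + "Heart", NS2 + "Heart"), (NS1 + "Heart", NS2 + "Aorta")]
            ),
            doc1,
            doc2,
        )
        report = check6_multiple_targets(alignment, doc1, doc2)
        assert report.findings[0].evidence["target_relations"][0]["relation"] == (
            "sibling"
        )

    def test_reverse_direction_detected(self):
        doc1, doc2 = pair_docs()
        alignment = resolve_references(
            make_alignment(
                [(NS1 + "Heart", NS2 + "Heart"), (NS1 + "Aorta", NS2 + "Heart")]
            ),
            doc1,
            doc2,
        )
        report = check6_multiple_targets(alignment, doc1, doc2)
        assert len(report.findings) == 1
        assert report.findings[0].evidence["direction"] == "2->1"


class TestCheck7:
    def test_smallest_nontrivial_closure(self):
        doc1 = build_doc(NS1, {"a": "a", "a_child": "ac"},
                         subclass=[("a_child", "a")])
        doc2 = build_doc(NS2, {"b": "b", "b_parent": "bp"},
                         subclass=[("b", "b_parent")])
        alignment = make_alignment([(NS1 + "a", NS2 + "b")])
        inferred, _ = inferred_subsumptions(alignment, doc1, doc2)
        assert inferred == {
            (NS1 + "a_child", NS2 + "b", Relation.SUBCLASS),
            (NS1 + "a_child", NS2 + "b_parent", Relation.SUBCLASS),
            (NS1 + "a", NS2 + "b_parent", Relation.SUBCLASS),
        }
        report = check7_inferred_subclass(alignment, doc1, doc2)
        assert report.summary_counts["inferred_total"] == 3
        assert report.summary_counts["inferred_new"] == 3

    def test_flat_ontologies_infer_nothing(self):
        doc1, doc2 = pair_docs()
        alignment = make_alignment([(NS1 + "Heart", NS2 + "Heart")])
        report = check7_inferred_subclass(alignment, doc1, doc2)
        assert report.summary_counts["inferred_total"] == 0
        assert report.status == STATUS_PASS

    def test_superclass_family_reported_in_onto1_orientation(self):
        doc1 = build_doc(NS1, {"a": "a", "a_parent": "ap"},
                         subclass=[("a", "a_parent")])
        doc2 = build_doc(NS2, {"b": "b", "b_child": "bc"},
                         subclass=[("b_child", "b")])
        alignment = make_alignment([(NS1 + "a", NS2 + "b")])
        inferred, _ = inferred_subsumptions(alignment, doc1, doc2)
        assert inferred == {
            (NS1 + "a_parent", NS2 + "b", Relation.SUPERCLASS),
            (NS1 + "a_parent", NS2 + "b_child", Relation.SUPERCLASS),
            (NS1 + "a", NS2 + "b_child", Relation.SUPERCLASS),
        }

    def test_present_pairs_labeled(self):
        doc1 = build_doc(NS1, {"a": "a", "c": "c"}, subclass=[("c", "a")])
        doc2 = build_doc(NS2, {"b": "b"})
        alignment = make_alignment(
            [
                (NS1 + "a", NS2 + "b", Relation.EQUIVALENT),
                (NS1 + "c", NS2 + "b", Relation.SUBCLASS),
            ]
        )
        report = check7_inferred_subclass(alignment, doc1, doc2)
        assert report.summary_counts["inferred_total"] == 1
        assert report.summary_counts["inferred_new"] == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_random_fixture_matches_bruteforce(self, seed):
        rng = random.Random(seed)
        n = 20
        names1 = {"C%d" % i: None for i in range(n)}
        names2 = {"D%d" % i: None for i in range(n)}
        edges1 = {("C%d" % i, "C%d" % rng.randrange(i)) for i in range(1, n)
                  if rng.random() < 0.8}
        edges2 = {("D%d" % i, "D%d" % rng.randrange(i)) for i in range(1, n)
                  if rng.random() < 0.8}
        doc1 = build_doc(NS1, names1, subclass=edges1)
        doc2 = build_doc(NS2, names2, subclass=edges2)
        equivs = {
            (NS1 + "C%d" % rng.randrange(n), NS2 + "D%d" % rng.randrange(n))
            for _ in range(5)
        }
        alignment = make_alignment(sorted(equivs))
        inferred, _ = inferred_subsumptions(alignment, doc1, doc2)
        assert inferred == brute_force_entailed(equivs, doc1, doc2)


class TestCheck8:
    def test_identical_label_without_equivalence(self):
        doc1 = build_doc(NS1, {"RenalPapilla": "renal papilla", "Other": "other"})
        doc2 = build_doc(NS2, {"MA123": "Renal Papilla", "Misc": "misc"})
        alignment = make_alignment([(NS1 + "Other", NS2 + "Misc")])
        report = check8_label_identity(alignment, doc1, doc2)
        found = [f for f in report.findings
                 if f.category == "label_identity_missing_equiv"]
        assert len(found) == 1
        assert found[0].entities == (NS1 + "RenalPapilla", NS2 + "MA123")

    def test_correspondence_suppresses_finding(self):
        doc1 = build_doc(NS1, {"A": "renal papilla"})
        doc2 = build_doc(NS2, {"B": "renal papilla"})
        alignment = make_alignment([(NS1 + "A", NS2 + "B")])
        assert check8_label_identity(alignment, doc1, doc2).status == STATUS_PASS

    def test_shared_uri_category(self):
        shared = "http://w3.org/time#Instant"
        doc1 = build_doc(NS1, {"A": "alpha"})
        doc2 = build_doc(NS2, {"B": "beta"})
        for doc in (doc1, doc2):
            doc.classes[shared] = type(doc.classes[next(iter(doc.classes))])(
                uri=shared, labels=[("instant", "")]
            )
        alignment = make_alignment([(NS1 + "A", NS2 + "B")])
        report = check8_label_identity(alignment, doc1, doc2)
        assert [f.category for f in report.findings] == ["shared_uri"]

    def test_local_name_fallback(self):
        doc1 = build_doc(NS1, {"GastrointestinalSystem": None})
        doc2 = build_doc(NS2, {"gastrointestinal_system": None})
        alignment = make_alignment([])
        report = check8_label_identity(alignment, doc1, doc2)
        assert len(report.findings) == 1

    def test_primary_labels_mode_ignores_synonyms(self):
        doc1 = build_doc(NS1, {"A": [("primary a", ""), ("shared", "")]})
        doc2 = build_doc(NS2, {"B": [("primary b", ""), ("shared", "")]})
        alignment = make_alignment([])
        assert check8_label_identity(alignment, doc1, doc2, "all").status == (
            STATUS_FINDINGS
        )
        assert check8_label_identity(alignment, doc1, doc2, "primary").status == (
            STATUS_PASS
        )

    def test_monotone_under_added_correspondences(self):
        doc1 = build_doc(NS1, {"A": "same label", "B": "other"})
        doc2 = build_doc(NS2, {"C": "same label", "D": "other"})
        without = check8_label_identity(make_alignment([]), doc1, doc2)
        with_corr = check8_label_identity(
            make_alignment([(NS1 + "A", NS2 + "C")]), doc1, doc2
        )
        assert len(with_corr.findings) <= len(without.findings)


class TestCheck9:
    def test_record_label_proposal(self):
        doc1 = build_doc(NS1, {"RecordLabel": None})
        doc2 = build_doc(NS2, {"Label": None})
        alignment = make_alignment([])
        report = check9_label_inclusion(alignment, doc1, doc2)
        assert len(report.findings) == 1
        finding = report.findings[0]
        assert finding.entities == (NS1 + "RecordLabel", NS2 + "Label")
        assert finding.evidence["relation"] == "subClassOf"  # longer is subclass

    def test_inbook_detected_for_human_review(self):
        doc1 = build_doc(NS1, {"InBook": None})
        doc2 = build_doc(NS2, {"Book": None})
        report = check9_label_inclusion(make_alignment([]), doc1, doc2)
        assert len(report.findings) == 1

    def test_different_heads_not_proposed(self):
        doc1 = build_doc(NS1, {"A": "arch of aorta"})
        doc2 = build_doc(NS2, {"B": "aorta"})
        report = check9_label_inclusion(make_alignment([]), doc1, doc2)
        assert report.status == STATUS_PASS

    def test_existing_subclass_correspondence_suppresses(self):
        doc1 = build_doc(NS1, {"DoctoralThesis": None})
        doc2 = build_doc(NS2, {"Thesis": None})
        alignment = make_alignment(
            [(NS1 + "DoctoralThesis", NS2 + "Thesis", Relation.SUBCLASS)]
        )
        assert check9_label_inclusion(alignment, doc1, doc2).status == STATUS_PASS

    def test_equivalence_suppresses(self):
        doc1 = build_doc(NS1, {"DoctoralThesis": None})
        doc2 = build_doc(NS2, {"Thesis": None})
        alignment = make_alignment([(NS1 + "DoctoralThesis", NS2 + "Thesis")])
        assert check9_label_inclusion(alignment, doc1, doc2).status == STATUS_PASS

    def test_already_inferred_is_noted_not_suppressed(self):
        doc1 = build_doc(NS1, {"DoctoralThesis": None, "Publication": None},
                         subclass=[("DoctoralThesis", "Publication")])
        doc2 = build_doc(NS2, {"Thesis": None, "Work": None},
                        subclass=[("Thesis", "Work")])
        alignment = make_alignment([(NS1 + "Publication", NS2 + "Work")])
        report = check9_label_inclusion(alignment, doc1, doc2)
        # DoctoralThesis included-in Thesis is not entailed by the equivalence,
        # but DoctoralThesis below Work is; the lexical pair is reported with
        # its inference status rather than being dropped.
        assert len(report.findings) == 1
        assert report.findings[0].evidence["already_inferred"] is False

    def test_monotonicity_adding_correspondence(self):
        doc1 = build_doc(NS1, {"RecordLabel": None})
        doc2 = build_doc(NS2, {"Label": None})
        base = check9_label_inclusion(make_alignment([]), doc1, doc2)
        extended = check9_label_inclusion(
            make_alignment([(NS1 + "RecordLabel", NS2 + "Label",
                            Relation.SUBCLASS)]),
            doc1,
            doc2,
        )
        assert len(extended.findings) <= len(base.findings)


class TestCheck10:
    def test_identical_labels_trivial(self):
        doc1 = build_doc(NS1, {"A": "renal papilla"})
        doc2 = build_doc(NS2, {"B": "Renal_Papilla"})
        alignment = make_alignment([(NS1 + "A", NS2 + "B")])
        report = check10_trivial(alignment, doc1, doc2)
        assert report.summary_counts["trivial"] == 1
        assert report.summary_counts["trivial_fraction"] == 1.0

    def test_synonym_pair_non_trivial(self):
        doc1 = build_doc(NS1, {"A": "Nostril"})
        doc2 = build_doc(NS2, {"B": "External Nare"})
        alignment = make_alignment([(NS1 + "A", NS2 + "B")])
        report = check10_trivial(alignment, doc1, doc2)
        assert report.summary_counts["non_trivial"] == 1

    def test_subclass_trivial_via_inclusion_and_head(self):
        doc1 = build_doc(NS1, {"DoctoralThesis": None})
        doc2 = build_doc(NS2, {"Thesis": None})
        alignment = make_alignment(
            [(NS1 + "DoctoralThesis", NS2 + "Thesis", Relation.SUBCLASS)]
        )
        report = check10_trivial(alignment, doc1, doc2)
        assert report.summary_counts["trivial"] == 1

    def test_subclass_wrong_direction_not_trivial(self):
        # superclass on the longer-label side cannot be lexically evident
        doc1 = build_doc(NS1, {"Thesis": None})
        doc2 = build_doc(NS2, {"DoctoralThesis": None})
        alignment = make_alignment(
            [(NS1 + "Thesis", NS2 + "DoctoralThesis", Relation.SUBCLASS)]
        )
        report = check10_trivial(alignment, doc1, doc2)
        assert report.summary_counts["non_trivial"] == 1
        # converse relation on the same pair is trivial
        alignment2 = make_alignment(
            [(NS1 + "Thesis", NS2 + "DoctoralThesis", Relation.SUPERCLASS)]
        )
        assert check10_trivial(alignment2, doc1, doc2).summary_counts["trivial"] == 1

    def test_check8_consistency_coupling(self):
        # every equivalence the check-8 detector would emit if absent is trivial
        doc1 = build_doc(NS1, {"A": "renal papilla", "B": "nostril"})
        doc2 = build_doc(NS2, {"C": "renal papilla", "D": "external nare"})
        alignment = make_alignment([(NS1 + "A", NS2 + "C"), (NS1 + "B", NS2 + "D")])
        report10 = check10_trivial(alignment, doc1, doc2)
        trivial_pairs = {f.entities for f in report10.findings
                         if f.category == "trivial"}
        report8 = check8_label_identity(make_alignment([]), doc1, doc2)
        detector_pairs = {f.entities for f in report8.findings}
        assert trivial_pairs == detector_pairs


class TestRunAll:
    def _write_inputs(self, tmp_path, with_defects: bool):
        from alignqc.fixtures import FixtureSpec, generate_fixture

        rates = (
            {"deleted_class": 2, "ambiguous_local_name": 1}
            if with_defects
            else {}
        )
        spec = FixtureSpec(
            n_classes_per_side=21, trivial_fraction=0.5, seed=11,
            defect_rates=rates,
        )
        fixture = generate_fixture(spec)
        paths = fixture.write(tmp_path / "fx")
        from alignqc.ontology_io import load_ontology

        return (
            paths["alignment"],
            load_ontology(paths["onto1"]),
            load_ontology(paths["onto2"]),
        )

    def test_order_and_ids(self, tmp_path):
        source, doc1, doc2 = self._write_inputs(tmp_path, False)
        reports = run_all(source, doc1, doc2)
        assert [r.check_id for r in reports] == [
            "1", "2a", "2b", "3", "4", "5", "6", "7", "8", "9", "10",
        ]

    def test_no_subclass_skips_7_and_9(self, tmp_path):
        source, doc1, doc2 = self._write_inputs(tmp_path, False)
        reports = {r.check_id: r for r in run_all(
            source, doc1, doc2, RunOptions(include_subclass=False))}
        assert reports["7"].status == STATUS_SKIPPED
        assert reports["9"].status == STATUS_SKIPPED
        assert reports["6"].status != STATUS_SKIPPED

    def test_force_untyped_skips_6_to_10(self, tmp_path):
        source, doc1, doc2 = self._write_inputs(tmp_path, False)
        reports = {r.check_id: r for r in run_all(
            source, doc1, doc2, RunOptions(force_untyped=True))}
        assert reports["5"].status == STATUS_FINDINGS
        for check_id in ("6", "7", "8", "9", "10"):
            assert reports[check_id].status == STATUS_SKIPPED

    def test_check1_pass_skips_check2(self, tmp_path):
        from alignqc.fixtures import FixtureSpec, generate_fixture
        from alignqc.ontology_io import load_ontology

        spec = FixtureSpec(n_classes_per_side=11, trivial_fraction=0.5, seed=5,
                           alignment_dialect="alignment_api")
        fixture = generate_fixture(spec)
        paths = fixture.write(tmp_path / "api")
        doc1 = load_ontology(paths["onto1"])
        doc2 = load_ontology(paths["onto2"])
        reports = {r.check_id: r for r in run_all(paths["alignment"], doc1, doc2)}
        assert reports["1"].status == STATUS_PASS
        assert reports["2a"].status == STATUS_SKIPPED
        assert reports["2b"].status == STATUS_SKIPPED

    def test_determinism(self, tmp_path):
        source, doc1, doc2 = self._write_inputs(tmp_path, True)
        options = RunOptions(cleanup=True)
        first = [r.to_dict() for r in run_all(source, doc1, doc2, options)]
        second = [r.to_dict() for r in run_all(source, doc1, doc2, options)]
        assert first == second

    def test_checks_filter(self, tmp_path):
        source, doc1, doc2 = self._write_inputs(tmp_path, False)
        reports = {r.check_id: r for r in run_all(
            source, doc1, doc2, RunOptions(checks_filter=("8", "10")))}
        assert reports["8"].status in (STATUS_PASS, STATUS_FINDINGS)
        assert reports["10"].status in (STATUS_PASS, STATUS_FINDINGS)
        assert reports["1"].status == STATUS_SKIPPED
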
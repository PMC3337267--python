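"""The ten alignment quality checks and their orchestrator.

Checks 1-5 address usability (provenance, missing classes, label drift,
format, reference ambiguity, relation typing); checks 6-9 address
completeness via taxonomy structure and class labels; check 10
partitions the alignment into trivial and non-trivial correspondences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

from . import lexical
from .alignment_io import (
    Alignment,
    AlignmentParseError,
    Correspondence,
    DelimitedOptions,
    Relation,
    Resolution,
    parse_alignment,
    resolve_references,
)
from .lexical import DEFAULT_PREPOSITIONS, NormalizedLabel
from .ontology_io import OntologyDocument, ancestors, descendants

CHECK_ORDER = ("1", "2a", "2b", "3", "4", "5", "6", "7", "8", "9", "10")

STATUS_PASS = "pass"
STATUS_FINDINGS = "findings"
STATUS_SKIPPED = "skipped"
STATUS_NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class Finding:
    check_id: str
    category: str
    entities: tuple[str, ...]
    evidence: dict = field(default_factory=dict)

    def sort_key(self):
        return (self.category, self.entities)

    def to_dict(self) -> dict:
        return {
            "check_id": self.check_id,
            "category": self.category,
            "entities": list(self.entities),
            "evidence": self.evidence,
        }


@dataclass
class CheckReport:
    check_id: str
    status: str = STATUS_PASS
    findings: list[Finding] = field(default_factory=list)
    summary_counts: dict = field(default_factory=dict)
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "check_id": self.check_id,
            "status": self.status,
            "findings": [f.to_dict() for f in self.findings],
            "summary_counts": self.summary_counts,
            "reason": self.reason,
        }


def _finish(report: CheckReport) -> CheckReport:
    report.findings.sort(key=Finding.sort_key)
    if report.status in (STATUS_PASS, STATUS_FINDINGS):
        report.status = STATUS_FINDINGS if report.findings else STATUS_PASS
    counts: dict[str, int] = {}
    for finding in report.findings:
        counts[finding.category] = counts.get(finding.category, 0) + 1
    for key, value in counts.items():
        report.summary_counts.setdefault(key, value)
    return report


def _skipped(check_id: str, reason: str) -> CheckReport:
    return CheckReport(check_id=check_id, status=STATUS_SKIPPED, reason=reason)


# --------------------------------------------------------------------------
# Check 1 - input provenance
# --------------------------------------------------------------------------


def check1_input_provenance(
    alignment: Alignment, doc1: OntologyDocument, doc2: OntologyDocument
) -> CheckReport:
    """Are the exact input ontology versions bundled with the alignment?"""
    report = CheckReport(check_id="1")
    for side, ref, doc in (("1", alignment.onto1_ref, doc1),
                           ("2", alignment.onto2_ref, doc2)):
        if not ref:
            report.findings.append(
                Finding("1", "no_ontology_reference", (("onto" + side),),
                        {"side": side})
            )
        elif ref not in (doc.ontology_iri, doc.source_location):
            category = (
                "url_reference"
                if ref.startswith(("http://", "https://"))
                else "ontology_reference_mismatch"
            )
            report.findings.append(
                Finding("1", category, (ref,),
                        {"side": side, "loaded_iri": doc.ontology_iri})
            )
        if not doc.version_info:
            report.findings.append(
                Finding("1", "version_unverifiable", (doc.ontology_iri or
                                                      doc.source_location,),
                        {"side": side})
            )
    return _finish(report)


# --------------------------------------------------------------------------
# Check 2a - missing classes
# --------------------------------------------------------------------------


def check2a_missing_classes(
    alignment: Alignment,
    doc1: OntologyDocument | None = None,
    doc2: OntologyDocument | None = None,
) -> CheckReport:
    """Classes referenced by the alignment but absent from the ontologies.

    One finding per distinct missing reference; ``summary_counts`` also
    reports how many correspondences are affected.
    """
    report = CheckReport(check_id="2a")
    missing: dict[tuple[str, str], list[str]] = {}
    affected = 0
    for corr in alignment.correspondences:
        hit = False
        for side, ref in (("1", corr.entity1), ("2", corr.entity2)):
            if ref.resolution == Resolution.MISSING:
                missing.setdefault((side, ref.raw), []).append(corr.row_provenance)
                hit = True
        if hit:
            affected += 1
    for (side, raw), rows in missing.items():
        report.findings.append(
            Finding("2a", "missing_class", (raw,),
                    {"side": side, "correspondences": rows})
        )
    report.summary_counts["missing_classes"] = len(missing)
    report.summary_counts["affected_correspondences"] = affected
    return _finish(report)


# --------------------------------------------------------------------------
# Check 2b - label drift against a URI-label mapping table
# --------------------------------------------------------------------------


def check2b_label_changes(
    mapping_table1: list[tuple[str, str]] | None,
    mapping_table2: list[tuple[str, str]] | None,
    doc1: OntologyDocument,
    doc2: OntologyDocument,
) -> CheckReport:
    """Compare expected URI-label pairs against the loaded ontologies."""
    if mapping_table1 is None and mapping_table2 is None:
        return CheckReport(
            check_id="2b",
            status=STATUS_NOT_APPLICABLE,
            reason="no URI-label mapping table supplied",
        )
    report = CheckReport(check_id="2b")
    for side, table, doc in (("1", mapping_table1, doc1),
                             ("2", mapping_table2, doc2)):
        if not table:
            continue
        changed: list[tuple[str, str, str]] = []  # (uri, expected, current)
        for uri, expected in table:
            if uri not in doc.classes:
                report.findings.append(
                    Finding("2b", "missing_class", (uri,),
                            {"side": side, "expected_label": expected})
                )
                continue
            current = doc.classes[uri].preferred_label()
            if current == expected:
                continue
            normalized_equal = _safe_rendering(expected) == _safe_rendering(current)
            report.findings.append(
                Finding("2b", "label_changed", (uri,),
                        {"side": side, "old_label": expected,
                         "new_label": current,
                         "normalized_equal": normalized_equal})
            )
            changed.append((uri, expected, current))
        # swap suspicion: two rows whose expected labels reappear exchanged
        by_expected = {exp: uri for uri, exp, _ in changed}
        seen_pairs: set[tuple[str, str]] = set()
        for uri, expected, current in changed:
            other = by_expected.get(current)
            if other is None or other == uri:
                continue
            other_current = doc.classes[other].preferred_label()
            if other_current != expected:
                continue
            pair = tuple(sorted((uri, other)))
            if pair in seen_pairs:
                continue
            seen_pairs.add(pair)
            report.findings.append(
                Finding("2b", "swap_suspicion", pair,
                        {"side": side, "labels": sorted((expected, current))})
            )
    return _finish(report)


def _safe_rendering(text: str) -> str:
    try:
        return lexical.normalize(text).rendering
    except lexical.EmptyLabelError:
        return ""


# --------------------------------------------------------------------------
# Check 3 - standard format
# --------------------------------------------------------------------------


def check3_format(
    source,
    dialect: str = "auto",
    delimited_options: DelimitedOptions | None = None,
) -> CheckReport:
    """Is the alignment distributed in the standard Alignment API format?"""
    report = CheckReport(check_id="3")
    try:
        alignment = parse_alignment(source, dialect, delimited_options)
    except AlignmentParseError as exc:
        report.findings.append(Finding("3", "unparsable", (str(source),),
                                       {"error": str(exc)}))
        return _finish(report)
    if alignment.source_format != "alignment_api":
        report.findings.append(
            Finding("3", "non_standard_format", (str(source),),
                    {"format": alignment.source_format})
        )
    for provenance, message in alignment.parse_warnings:
        report.findings.append(
            Finding("3", "format_irregularity", (provenance,),
                    {"message": message})
        )
    return _finish(report)


# --------------------------------------------------------------------------
# Check 4 - reference ambiguity
# --------------------------------------------------------------------------


def check4_reference_ambiguity(
    alignment: Alignment,
    doc1: OntologyDocument | None = None,
    doc2: OntologyDocument | None = None,
) -> CheckReport:
    """Ambiguous local-name references (one finding per distinct name)."""
    report = CheckReport(check_id="4")
    seen: dict[tuple[str, str], tuple] = {}
    for corr in alignment.correspondences:
        for side, ref in (("1", corr.entity1), ("2", corr.entity2)):
            if ref.resolution == Resolution.AMBIGUOUS:
                seen.setdefault((side, ref.raw), ref.candidates)
    for (side, raw), candidates in seen.items():
        report.findings.append(
            Finding("4", "ambiguous_ref", (raw,),
                    {"side": side, "candidates": sorted(candidates)})
        )
    return _finish(report)


# --------------------------------------------------------------------------
# Check 5 - explicit relation types
# --------------------------------------------------------------------------


def check5_relation_types(alignment: Alignment) -> CheckReport:
    """Correspondences without a usable relation type."""
    report = CheckReport(check_id="5")
    for corr in alignment.correspondences:
        if corr.relation is Relation.UNKNOWN:
            report.findings.append(
                Finding("5", "untyped_relation",
                        (corr.entity1.raw, corr.entity2.raw),
                        {"row": corr.row_provenance})
            )
    return _finish(report)


# --------------------------------------------------------------------------
# Check 6 - multiple equivalence targets
# --------------------------------------------------------------------------


def _resolved_equivalences(alignment: Alignment) -> list[Correspondence]:
    return [
        c
        for c in alignment.correspondences
        if c.relation is Relation.EQUIVALENT and c.resolved()
    ]


def _classify_target_pair(a: str, b: str, doc: OntologyDocument) -> str:
    """Relation asserted between two mapping targets in their own ontology."""
    tax = doc.taxonomy
    if tax.equivalent_pair(a, b):
        return "equivalentClass"
    if b in doc.taxonomy.ancestors(a) or a in doc.taxonomy.ancestors(b):
        return "subClassOf"
    if tax.partof_pair(a, b):
        return "partOf"
    if tax.direct_parents(a) & tax.direct_parents(b):
        return "sibling"
    if tax.disjoint_pair(a, b):
        return "disjoint"
    return "none"


def check6_multiple_targets(
    alignment: Alignment, doc1: OntologyDocument, doc2: OntologyDocument
) -> CheckReport:
    """Classes with more than one equivalence target, run in both directions."""
    report = CheckReport(check_id="6")
    equivalences = _resolved_equivalences(alignment)
    for direction, target_doc in (("1->2", doc2), ("2->1", doc1)):
        targets: dict[str, set[str]] = {}
        for corr in equivalences:
            if direction == "1->2":
                source, target = corr.entity1.resolved_uri, corr.entity2.resolved_uri
            else:
                source, target = corr.entity2.resolved_uri, corr.entity1.resolved_uri
            targets.setdefault(source, set()).add(target)
        for source, tset in targets.items():
            if len(tset) < 2:
                continue
            ordered = sorted(tset)
            classifications = [
                {"targets": [a, b],
                 "relation": _classify_target_pair(a, b, target_doc)}
                for i, a in enumerate(ordered)
                for b in ordered[i + 1:]
            ]
            report.findings.append(
                Finding("6", "multi_target", (source, *ordered),
                        {"direction": direction,
                         "target_relations": classifications})
            )
    report.summary_counts["multi_target_sources"] = len(report.findings)
    return _finish(report)


# --------------------------------------------------------------------------
# Check 7 - subsumptions entailed by equivalences + taxonomies
# --------------------------------------------------------------------------


def inferred_subsumptions(
    alignment: Alignment, doc1: OntologyDocument, doc2: OntologyDocument
) -> tuple[set[tuple[str, str, Relation]], int]:
    """All cross-ontology subsumptions entailed per equivalence.

    For each ``equivalentClass(a, b)``: every reflexive descendant of
    ``a`` is a subclass of every reflexive ancestor of ``b`` (and the
    symmetric family, reported in ontology-1-to-ontology-2 orientation
    via ``superClassOf``), minus the generating pair itself.  No
    composition across multiple equivalences.  Returns the deduplicated
    set and the number of correspondences excluded as unresolved.
    """
    inferred: set[tuple[str, str, Relation]] = set()
    excluded = 0
    for corr in alignment.correspondences:
        if corr.relation is not Relation.EQUIVALENT:
            continue
        if not corr.resolved():
            excluded += 1
            continue
        a, b = corr.entity1.resolved_uri, corr.entity2.resolved_uri
        if a not in doc1.classes or b not in doc2.classes:
            excluded += 1
            continue
        desc_a = descendants(doc1, a, reflexive=True)
        anc_b = ancestors(doc2, b, reflexive=True)
        for x in desc_a:
            for y in anc_b:
                if (x, y) != (a, b):
                    inferred.add((x, y, Relation.SUBCLASS))
        anc_a = ancestors(doc1, a, reflexive=True)
        desc_b = descendants(doc2, b, reflexive=True)
        for x in anc_a:
            for y in desc_b:
                if (x, y) != (a, b):
                    inferred.add((x, y, Relation.SUPERCLASS))
    return inferred, excluded


def _alignment_pairs(alignment: Alignment):
    """Resolved (pair -> relations) maps used for presence tests."""
    equivalences: set[tuple[str, str]] = set()
    subsumptions: set[tuple[str, str, Relation]] = set()
    for corr in alignment.correspondences:
        if not corr.resolved():
            continue
        pair = (corr.entity1.resolved_uri, corr.entity2.resolved_uri)
        if corr.relation is Relation.EQUIVALENT:
            equivalences.add(pair)
        elif corr.relation in (Relation.SUBCLASS, Relation.SUPERCLASS):
            subsumptions.add((pair[0], pair[1], corr.relation))
    return equivalences, subsumptions


def check7_inferred_subclass(
    alignment: Alignment, doc1: OntologyDocument, doc2: OntologyDocument
) -> CheckReport:
    """Subsumption correspondences inferable from the equivalences."""
    report = CheckReport(check_id="7")
    inferred, excluded = inferred_subsumptions(alignment, doc1, doc2)
    equivalences, subsumptions = _alignment_pairs(alignment)
    new = 0
    for u1, u2, relation in sorted(inferred, key=lambda t: (t[0], t[1], t[2].value)):
        present = (u1, u2, relation) in subsumptions or (u1, u2) in equivalences
        if not present:
            new += 1
        report.findings.append(
            Finding(
                "7",
                "inferred_subclass_present" if present else "inferred_subclass_new",
                (u1, u2),
                {"relation": relation.value},
            )
        )
    report.summary_counts["inferred_total"] = len(inferred)
    report.summary_counts["inferred_new"] = new
    if excluded:
        report.summary_counts["excluded_correspondences"] = excluded
    return _finish(report)


# --------------------------------------------------------------------------
# Label machinery shared by checks 8, 9 and 10
# --------------------------------------------------------------------------


def _class_renderings(
    doc: OntologyDocument, labels_mode: str
) -> dict[str, list[NormalizedLabel]]:
    """Normalized labels per class URI (local-name fallback included)."""
    out: dict[str, list[NormalizedLabel]] = {}
    for uri in sorted(doc.classes):
        record = doc.classes[uri]
        normals: list[NormalizedLabel] = []
        seen: set[str] = set()
        for text in record.label_texts(labels_mode):
            try:
                normal = lexical.normalize(text)
            except lexical.EmptyLabelError:
                continue
            if normal.rendering not in seen:
                seen.add(normal.rendering)
                normals.append(normal)
        if normals:
            out[uri] = normals
    return out


def _rendering_index(
    renderings: dict[str, list[NormalizedLabel]]
) -> dict[str, list[str]]:
    index: dict[str, list[str]] = {}
    for uri, normals in renderings.items():
        for normal in normals:
            index.setdefault(normal.rendering, []).append(uri)
    return index


def check8_label_identity(
    alignment: Alignment,
    doc1: OntologyDocument,
    doc2: OntologyDocument,
    labels_mode: str = "all",
) -> CheckReport:
    """Cross-ontology label identity without an equivalence correspondence."""
    report = CheckReport(check_id="8")
    equivalences, _ = _alignment_pairs(alignment)
    index1 = _rendering_index(_class_renderings(doc1, labels_mode))
    index2 = _rendering_index(_class_renderings(doc2, labels_mode))
    pairs: dict[tuple[str, str], str] = {}
    for rendering in sorted(set(index1) & set(index2)):
        for u1 in index1[rendering]:
            for u2 in index2[rendering]:
                pair = (u1, u2)
                if pair in equivalences or pair in pairs:
                    continue
                pairs[pair] = rendering
    for (u1, u2), rendering in pairs.items():
        category = "shared_uri" if u1 == u2 else "label_identity_missing_equiv"
        report.findings.append(
            Finding("8", category, (u1, u2), {"label": rendering})
        )
    return _finish(report)


def _head_index(
    renderings: dict[str, list[NormalizedLabel]],
    preposition_set: frozenset[str],
) -> dict[str, list[tuple[str, NormalizedLabel]]]:
    index: dict[str, list[tuple[str, NormalizedLabel]]] = {}
    for uri, normals in renderings.items():
        for normal in normals:
            try:
                head = lexical.extract_head(normal, preposition_set)
            except lexical.DegenerateLabelError:
                continue
            index.setdefault(head, []).append((uri, normal))
    return index


def check9_label_inclusion(
    alignment: Alignment,
    doc1: OntologyDocument,
    doc2: OntologyDocument,
    labels_mode: str = "all",
    preposition_set: frozenset[str] = DEFAULT_PREPOSITIONS,
) -> CheckReport:
    """Label inclusion with identical heads, no subsumption correspondence.

    The longer-label class is proposed as the subclass.  Pairs already
    covered by an equivalence correspondence are suppressed; pairs whose
    subsumption was already derivable by the equivalence entailment of
    check 7 are reported with an ``already_inferred`` note.
    """
    report = CheckReport(check_id="9")
    equivalences, subsumptions = _alignment_pairs(alignment)
    inferred, _ = inferred_subsumptions(alignment, doc1, doc2)
    heads1 = _head_index(_class_renderings(doc1, labels_mode), preposition_set)
    heads2 = _head_index(_class_renderings(doc2, labels_mode), preposition_set)
    proposals: dict[tuple[str, str, Relation], dict] = {}
    for head in sorted(set(heads1) & set(heads2)):
        for u1, n1 in heads1[head]:
            for u2, n2 in heads2[head]:
                inclusion = lexical.label_inclusion(n1, n2)
                if inclusion is lexical.Inclusion.A_INCLUDES_B:
                    direction = Relation.SUBCLASS      # u1 (longer) below u2
                elif inclusion is lexical.Inclusion.B_INCLUDES_A:
                    direction = Relation.SUPERCLASS    # u2 (longer) below u1
                else:
                    continue
                key = (u1, u2, direction)
                if key in proposals:
                    continue
                if (u1, u2) in equivalences:
                    continue
                if key in subsumptions:
                    continue
                proposals[key] = {
                    "labels": sorted((n1.rendering, n2.rendering)),
                    "head": head,
                    "relation": direction.value,
                    "already_inferred": key in inferred,
                }
    for (u1, u2, _), evidence in proposals.items():
        report.findings.append(
            Finding("9", "inclusion_missing_subclass", (u1, u2), evidence)
        )
    return _finish(report)


def check10_trivial(
    alignment: Alignment,
    doc1: OntologyDocument,
    doc2: OntologyDocument,
    labels_mode: str = "all",
    preposition_set: frozenset[str] = DEFAULT_PREPOSITIONS,
) -> CheckReport:
    """Partition correspondences into trivial and non-trivial.

    An equivalence is trivial when the classes share a normalized label
    (or local name); a subsumption is trivial when the subclass label
    strictly includes the superclass label with an identical head.
    """
    report = CheckReport(check_id="10")
    renderings1 = _class_renderings(doc1, labels_mode)
    renderings2 = _class_renderings(doc2, labels_mode)
    trivial = non_trivial = excluded = 0
    for corr in alignment.correspondences:
        if not corr.resolved() or corr.relation is Relation.UNKNOWN:
            excluded += 1
            continue
        u1, u2 = corr.entity1.resolved_uri, corr.entity2.resolved_uri
        n1 = renderings1.get(u1, [])
        n2 = renderings2.get(u2, [])
        if corr.relation is Relation.EQUIVALENT:
            is_trivial = bool(
                {n.rendering for n in n1} & {n.rendering for n in n2}
            )
        elif corr.relation is Relation.SUBCLASS:
            is_trivial = _trivially_included(n1, n2, preposition_set)
        elif corr.relation is Relation.SUPERCLASS:
            is_trivial = _trivially_included(n2, n1, preposition_set)
        else:  # relatedTo carries no lexical trivialness criterion
            is_trivial = False
        if is_trivial:
            trivial += 1
        else:
            non_trivial += 1
        report.findings.append(
            Finding("10", "trivial" if is_trivial else "non_trivial", (u1, u2),
                    {"relation": corr.relation.value})
        )
    report.summary_counts["trivial"] = trivial
    report.summary_counts["non_trivial"] = non_trivial
    total = trivial + non_trivial
    report.summary_counts["trivial_fraction"] = trivial / total if total else 0.0
    if excluded:
        report.summary_counts["excluded_correspondences"] = excluded
    return _finish(report)


def _trivially_included(
    sub_labels: Iterable[NormalizedLabel],
    super_labels: Iterable[NormalizedLabel],
    preposition_set: frozenset[str],
) -> bool:
    """Subclass label strictly includes superclass label, same head."""
    for n_sub in sub_labels:
        for n_sup in super_labels:
            if lexical.label_inclusion(n_sub, n_sup) is not (
                lexical.Inclusion.A_INCLUDES_B
            ):
                continue
            try:
                head_sub = lexical.extract_head(n_sub, preposition_set)
                head_sup = lexical.extract_head(n_sup, preposition_set)
            except lexical.DegenerateLabelError:
                continue
            if head_sub == head_sup:
                return True
    return False


# --------------------------------------------------------------------------
# Orchestrator
# --------------------------------------------------------------------------


@dataclass
class RunOptions:
    dialect: str = "auto"
    delimited_options: DelimitedOptions | None = None
    include_subclass: bool = True
    cleanup: bool = False
    force_untyped: bool = False
    continue_untyped: bool = False
    mapping_table1: list[tuple[str, str]] | None = None
    mapping_table2: list[tuple[str, str]] | None = None
    labels_mode: str = "all"
    preposition_set: frozenset[str] = DEFAULT_PREPOSITIONS
    checks_filter: tuple[str, ...] | None = None


def run_all(
    alignment_source,
    doc1: OntologyDocument,
    doc2: OntologyDocument,
    options: RunOptions | None = None,
) -> list[CheckReport]:
    """Execute the checks in their prescribed order.

    Check 2 is skipped when check 1 passes; checks 6-10 are skipped when
    check 5 finds untyped relations (unless overridden); checks 7 and 9
    are skipped when subsumption correspondences are out of scope.
    Every skip is recorded with its reason.
    """
    opts = options or RunOptions()
    alignment = parse_alignment(
        alignment_source, opts.dialect, opts.delimited_options
    )
    if opts.force_untyped:
        alignment.correspondences = [
            replace(c, relation=Relation.UNKNOWN) for c in alignment.correspondences
        ]
    resolved = resolve_references(alignment, doc1, doc2, cleanup=opts.cleanup)

    reports: dict[str, CheckReport] = {}
    selected = set(opts.checks_filter) if opts.checks_filter else set(CHECK_ORDER)

    def want(check_id: str) -> bool:
        return check_id in selected

    reports["1"] = (
        check1_input_provenance(resolved, doc1, doc2)
        if want("1")
        else _skipped("1", "excluded by checks filter")
    )

    check1_clean = reports["1"].status == STATUS_PASS
    for check_id, runner in (
        ("2a", lambda: check2a_missing_classes(resolved, doc1, doc2)),
        ("2b", lambda: check2b_label_changes(
            opts.mapping_table1, opts.mapping_table2, doc1, doc2)),
    ):
        if not want(check_id):
            reports[check_id] = _skipped(check_id, "excluded by checks filter")
        elif check1_clean:
            reports[check_id] = _skipped(
                check_id, "check 1 passed: input ontologies verified"
            )
        else:
            reports[check_id] = runner()

    reports["3"] = (
        check3_format(alignment_source, opts.dialect, opts.delimited_options)
        if want("3")
        else _skipped("3", "excluded by checks filter")
    )
    reports["4"] = (
        check4_reference_ambiguity(resolved, doc1, doc2)
        if want("4")
        else _skipped("4", "excluded by checks filter")
    )
    reports["5"] = (
        check5_relation_types(resolved)
        if want("5")
        else _skipped("5", "excluded by checks filter")
    )

    untyped = (
        reports["5"].status == STATUS_FINDINGS and not opts.continue_untyped
    )
    typed_runners = {
        "6": lambda: check6_multiple_targets(resolved, doc1, doc2),
        "7": lambda: check7_inferred_subclass(resolved, doc1, doc2),
        "8": lambda: check8_label_identity(
            resolved, doc1, doc2, opts.labels_mode),
        "9": lambda: check9_label_inclusion(
            resolved, doc1, doc2, opts.labels_mode, opts.preposition_set),
        "10": lambda: check10_trivial(
            resolved, doc1, doc2, opts.labels_mode, opts.preposition_set),
    }
    for check_id, runner in typed_runners.items():
        if not want(check_id):
            reports[check_id] = _skipped(check_id, "excluded by checks filter")
        elif untyped:
            reports[check_id] = _skipped(
                check_id, "untyped relations present (check 5)"
            )
        elif check_id in ("7", "9") and not opts.include_subclass:
            reports[check_id] = _skipped(
                check_id, "subClassOf correspondences out of scope"
            )
        else:
            reports[check_id] = runner()
    return [reports[check_id] for check_id in CHECK_ORDER]
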
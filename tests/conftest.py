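"""Shared test helpers: in-memory document builders and closure oracles."""

from __future__ import annotations

import pytest

from alignqc.alignment_io import (
    Alignment,
    Correspondence,
    EntityRef,
    Relation,
    Resolution,
)
from alignqc.ontology_io import ClassRecord, OntologyDocument


def build_doc(
    ns: str,
    classes: dict,
    subclass=(),
    equivalence=(),
    partof=(),
    disjoint=(),
    iri: str = "",
    version: str = "1.0",
) -> OntologyDocument:
    """Build an OntologyDocument from short local names.

    ``classes`` maps local name -> label, list of (label, lang) pairs, or
    None (no labels, local-name fallback).  Edge lists use local names.
    """
    doc = OntologyDocument(
        ontology_iri=iri or ns.rstrip("#/"), version_info=version,
        source_location=ns,
    )

    def uri(name: str) -> str:
        return ns + name

    for name, labels in classes.items():
        if labels is None:
            label_list = []
        elif isinstance(labels, str):
            label_list = [(labels, "")]
        else:
            label_list = list(labels)
        doc.classes[uri(name)] = ClassRecord(uri=uri(name), labels=label_list)
    tax = doc.taxonomy
    tax.subclass_edges.update((uri(a), uri(b)) for a, b in subclass)
    tax.equivalence_edges.update((uri(a), uri(b)) for a, b in equivalence)
    tax.partof_edges.update((uri(a), uri(b)) for a, b in partof)
    tax.disjoint_edges.update((uri(a), uri(b)) for a, b in disjoint)
    return doc


def resolved_ref(uri: str) -> EntityRef:
    return EntityRef(
        raw=uri, ref_kind="uri", resolution=Resolution.RESOLVED,
        resolved_uri=uri, candidates=(uri,),
    )


def make_alignment(pairs, relation=Relation.EQUIVALENT, **kwargs) -> Alignment:
    """Alignment over already-resolved URI pairs.

    ``pairs`` may be (uri1, uri2) or (uri1, uri2, relation) tuples.
    """
    correspondences = []
    for i, pair in enumerate(pairs):
        if len(pair) == 3:
            u1, u2, rel = pair
        else:
            u1, u2 = pair
            rel = relation
        correspondences.append(
            Correspondence(
                entity1=resolved_ref(u1),
                entity2=resolved_ref(u2),
                relation=rel,
                row_provenance="row:%d" % (i + 1),
            )
        )
    return Alignment(correspondences=correspondences, **kwargs)


def reflexive_reachability(nodes, edges) -> dict:
    """Brute-force reflexive upward reachability by fixpoint iteration.

    ``edges`` are (child, parent); result maps node -> reflexive
    ancestor set.  Independent of the package's closure implementation.
    """
    reach = {n: {n} for n in nodes}
    changed = True
    while changed:
        changed = False
        for child, parent in edges:
            add = reach[parent] - reach[child]
            if add:
                reach[child] |= add
                changed = True
    return reach


def brute_force_entailed(equivs, doc1, doc2):
    """Oracle for the equivalence-entailment check.

    For every cross-ontology pair (x, y), (x, y, subClassOf) is entailed
    iff some equivalence (a, b) != (x, y) has x below-or-equal a and y
    above-or-equal b; symmetrically for superClassOf.
    """
    up1 = reflexive_reachability(doc1.classes, doc1.taxonomy.subclass_edges)
    up2 = reflexive_reachability(doc2.classes, doc2.taxonomy.subclass_edges)
    out = set()
    for x in doc1.classes:
        for y in doc2.classes:
            for a, b in equivs:
                if (a, b) == (x, y):
                    continue
                if a in up1[x] and y in up2[b]:
                    out.add((x, y, Relation.SUBCLASS))
                if x in up1[a] and b in up2[y]:
                    out.add((x, y, Relation.SUPERCLASS))
    return out


@pytest.fixture
def tmp_fixture_dir(tmp_path):
    return tmp_path / "fixture"
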
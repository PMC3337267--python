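"""Synthetic ontology pairs, alignments and defect manifests.

The generator builds two random tree taxonomies over a shared label
vocabulary, derives a correct complete alignment, then plants defects
one category at a time.  Every planted defect is recorded in a manifest
whose categories map one-to-one onto the finding categories of the
checks, so each check's finding set can be compared against ground
truth exactly.

Construction rules that keep defect categories isolated from each other:

* every label has a head noun unique to its class (or to its aligned
  pair), so no accidental label identity or inclusion exists;
* lexical defects (renames, swaps, whitespace, ambiguity, untyping) are
  planted on non-trivial pairs only, structural deletions and omissions
  on trivial pairs, so the trivial/non-trivial partition stays exact;
* extra equivalence targets point at otherwise unaligned classes, so a
  planted multi-target shows up in exactly one direction.

The ``trivial`` / ``non_trivial`` manifest entries describe the
partition as seen by a run with ``cleanup=True`` (whitespace-corrupted
references resolved, ambiguous and untyped ones excluded).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from random import Random

from .alignment_io import (
    Alignment,
    Correspondence,
    EntityRef,
    Relation,
    write_alignment,
)
from .ontology_io import ClassRecord, OntologyDocument, TaxonomyGraph, write_ontology

ONTO1_NS = "http://example.org/onto1#"
ONTO2_NS = "http://example.org/onto2#"
ONTO2_ALT_NS = "http://example.org/onto2alt#"

_SYLLABLES = (
    "ba", "ce", "di", "fo", "gu", "ha", "ki", "lo", "mu", "ne",
    "pa", "qui", "ro", "su", "ta", "ve", "wo", "xy", "za", "bri",
)

_MODIFIERS = (
    "anterior", "posterior", "dorsal", "ventral", "medial", "lateral",
    "proximal", "distal", "superior", "inferior", "primary", "secondary",
    "left", "right", "upper", "lower", "deep", "outer", "inner", "central",
)

DEFECT_CATEGORIES = (
    "deleted_class",
    "renamed_label",
    "swapped_label_pair",
    "whitespace_corruption",
    "ambiguous_local_name",
    "multi_target",
    "omitted_trivial_equiv",
    "omitted_trivial_subclass",
    "untyped_relation",
)


class FixtureSpecError(ValueError):
    """An infeasible fixture specification (message names the constraint)."""


@dataclass
class FixtureSpec:
    n_classes_per_side: int = 31  # 30 aligned pairs when no extras planted
    max_depth: int = 4
    label_vocabulary_size: int = 400
    defect_rates: dict = field(default_factory=dict)
    trivial_fraction: float = 0.5
    seed: int = 0
    alignment_dialect: str = "delimited"  # or "alignment_api"

    def rate(self, category: str) -> int:
        return int(self.defect_rates.get(category, 0))


@dataclass
class Fixture:
    spec: FixtureSpec
    doc1: OntologyDocument
    doc2: OntologyDocument
    alignment: Alignment
    manifest: dict
    mapping_table1: list[tuple[str, str]]
    mapping_table2: list[tuple[str, str]]

    def write(self, outdir) -> dict:
        """Write all artifacts to a directory; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        suffix = "csv" if self.spec.alignment_dialect == "delimited" else "rdf"
        paths = {
            "onto1": outdir / "onto1.owl",
            "onto2": outdir / "onto2.owl",
            "alignment": outdir / ("alignment.%s" % suffix),
            "mapping_table1": outdir / "mapping_table1.csv",
            "mapping_table2": outdir / "mapping_table2.csv",
            "manifest": outdir / "manifest.json",
        }
        write_ontology(self.doc1, paths["onto1"])
        write_ontology(self.doc2, paths["onto2"])
        write_alignment(
            self.alignment,
            paths["alignment"],
            dialect=self.spec.alignment_dialect,
            allow_unresolved=True,
        )
        for key, table in (
            ("mapping_table1", self.mapping_table1),
            ("mapping_table2", self.mapping_table2),
        ):
            lines = ["%s,%s" % (uri, label) for uri, label in table]
            paths[key].write_text("\n".join(lines) + "\n", encoding="utf-8")
        paths["manifest"].write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        return {k: str(v) for k, v in paths.items()}


class _Vocabulary:
    """Deterministic supply of unique head nouns."""

    def __init__(self, size: int):
        self.size = size
        self.used = 0

    def next_head(self) -> str:
        i = self.used
        if i >= self.size:
            raise FixtureSpecError(
                "label_vocabulary_size=%d exhausted; increase it" % self.size
            )
        self.used += 1
        parts = [_SYLLABLES[i % 20], _SYLLABLES[(i // 20) % 20]]
        if i >= 400:
            parts.append(_SYLLABLES[(i // 400) % 20])
        return "".join(parts)


def _local_name_of(label: str) -> str:
    return label.replace(" ", "_")


@dataclass
class _Side:
    ns: str
    doc: OntologyDocument

    def add_class(self, label: str, parent_uri: str | None) -> str:
        uri = self.ns + _local_name_of(label)
        self.doc.classes[uri] = ClassRecord(uri=uri, labels=[(label, "")])
        if parent_uri is not None:
            self.doc.taxonomy.subclass_edges.add((uri, parent_uri))
        return uri


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build a fixture per the spec; fully reproducible from the seed."""
    _validate_basic(spec)
    rng = Random(spec.seed)
    vocab = _Vocabulary(spec.label_vocabulary_size)

    d = spec.rate("deleted_class")
    r = spec.rate("renamed_label")
    s = spec.rate("swapped_label_pair")
    w = spec.rate("whitespace_corruption")
    a = spec.rate("ambiguous_local_name")
    m = spec.rate("multi_target")
    oe = spec.rate("omitted_trivial_equiv")
    os_ = spec.rate("omitted_trivial_subclass")
    u = spec.rate("untyped_relation")

    n = spec.n_classes_per_side
    n_pairs = n - 1 - m - os_
    if n_pairs < 1:
        raise FixtureSpecError(
            "n_classes_per_side=%d too small for multi_target=%d and "
            "omitted_trivial_subclass=%d (need at least %d)"
            % (n, m, os_, 2 + m + os_)
        )
    n_trivial = spec.trivial_fraction * n_pairs
    if abs(n_trivial - round(n_trivial)) > 1e-9:
        raise FixtureSpecError(
            "trivial_fraction=%r infeasible: %r * %d aligned pairs is not "
            "an integer" % (spec.trivial_fraction, spec.trivial_fraction, n_pairs)
        )
    n_trivial = round(n_trivial)
    n_nontrivial = n_pairs - n_trivial
    if d + oe + m > n_trivial:
        raise FixtureSpecError(
            "deleted_class + omitted_trivial_equiv + multi_target = %d "
            "exceeds the %d trivial pairs" % (d + oe + m, n_trivial)
        )
    if r + 2 * s + w + a + u > n_nontrivial:
        raise FixtureSpecError(
            "renamed_label + 2*swapped_label_pair + whitespace_corruption + "
            "ambiguous_local_name + untyped_relation = %d exceeds the %d "
            "non-trivial pairs" % (r + 2 * s + w + a + u, n_nontrivial)
        )

    side1 = _Side(ONTO1_NS, OntologyDocument(
        ontology_iri="http://example.org/onto1", version_info="1.0"))
    side2 = _Side(ONTO2_NS, OntologyDocument(
        ontology_iri="http://example.org/onto2", version_info="1.0"))

    def fresh_label(with_modifier: bool | None = None) -> str:
        head = vocab.next_head()
        use_mod = rng.random() < 0.5 if with_modifier is None else with_modifier
        if use_mod:
            return "%s %s" % (rng.choice(_MODIFIERS), head)
        return head

    root1 = side1.add_class(fresh_label(False), None)
    root2 = side2.add_class(fresh_label(False), None)
    parents1: list[tuple[str, int]] = [(root1, 0)]
    parents2: list[tuple[str, int]] = [(root2, 0)]

    def attach(side: _Side, parents: list[tuple[str, int]], label: str) -> str:
        candidates = [(p, depth) for p, depth in parents if depth < spec.max_depth]
        parent, depth = rng.choice(candidates)
        uri = side.add_class(label, parent)
        parents.append((uri, depth + 1))
        return uri

    # aligned pairs: trivial (identical labels) then non-trivial (synonyms)
    pairs: list[dict] = []
    for i in range(n_pairs):
        if i < n_trivial:
            label = fresh_label()
            u1 = attach(side1, parents1, label)
            u2 = attach(side2, parents2, label)
            pairs.append({"u1": u1, "u2": u2, "trivial": True,
                          "label1": label, "label2": label})
        else:
            label1, label2 = fresh_label(), fresh_label()
            u1 = attach(side1, parents1, label1)
            u2 = attach(side2, parents2, label2)
            pairs.append({"u1": u1, "u2": u2, "trivial": False,
                          "label1": label1, "label2": label2})

    # unaligned extras: multi-target targets (side 2) + side-1 fillers
    extra_targets = [attach(side2, parents2, fresh_label()) for _ in range(m)]
    for _ in range(m):
        attach(side1, parents1, fresh_label())

    # omitted-trivial-subclass bait: inclusion + shared head, no correspondence
    manifest: dict = {category: [] for category in DEFECT_CATEGORIES_TO_FINDINGS}
    for i in range(os_):
        head = vocab.next_head()
        longer = "%s %s" % (rng.choice(_MODIFIERS), head)
        if i % 2 == 0:
            u1 = attach(side1, parents1, longer)
            u2 = attach(side2, parents2, head)
            relation = Relation.SUBCLASS.value  # longer (side 1) below shorter
        else:
            u1 = attach(side1, parents1, head)
            u2 = attach(side2, parents2, longer)
            relation = Relation.SUPERCLASS.value
        manifest["inclusion_missing_subclass"].append(
            {"entities": [u1, u2], "relation": relation}
        )

    trivial_pairs = [p for p in pairs if p["trivial"]]
    nontrivial_pairs = [p for p in pairs if not p["trivial"]]
    rng.shuffle(trivial_pairs)
    rng.shuffle(nontrivial_pairs)

    deleted = trivial_pairs[:d]
    omitted = trivial_pairs[d:d + oe]
    mt_sources = trivial_pairs[d + oe:d + oe + m]
    renamed = nontrivial_pairs[:r]
    swapped = nontrivial_pairs[r:r + 2 * s]
    whitespaced = nontrivial_pairs[r + 2 * s:r + 2 * s + w]
    ambiguous = nontrivial_pairs[r + 2 * s + w:r + 2 * s + w + a]
    untyped = nontrivial_pairs[r + 2 * s + w + a:r + 2 * s + w + a + u]

    # mapping tables snapshot the original labels (deleted classes excluded)
    deleted_uris: set[str] = set()
    for i, pair in enumerate(deleted):
        side, uri_key = (side1, "u1") if i % 2 == 0 else (side2, "u2")
        uri = pair[uri_key]
        deleted_uris.add(uri)
        _delete_class(side.doc, uri)
        manifest["missing_class"].append(
            {"token": _token_for(pair[uri_key], spec), "side": "1" if i % 2 == 0 else "2"}
        )

    mapping_table1 = [
        (uri, side1.doc.classes[uri].preferred_label())
        for uri in sorted(side1.doc.classes)
    ]
    mapping_table2 = [
        (uri, side2.doc.classes[uri].preferred_label())
        for uri in sorted(side2.doc.classes)
    ]

    # lexical defects on side 2 of non-trivial pairs (after table snapshot)
    for pair in renamed:
        uri = pair["u2"]
        new_label = fresh_label()
        side2.doc.classes[uri].labels = [(new_label, "")]
        manifest["label_changed"].append(uri)
    for i in range(0, len(swapped), 2):
        pa, pb = swapped[i], swapped[i + 1]
        ca, cb = side2.doc.classes[pa["u2"]], side2.doc.classes[pb["u2"]]
        ca.labels, cb.labels = cb.labels, ca.labels
        manifest["label_changed"].extend([pa["u2"], pb["u2"]])
        manifest["swap_suspicion"].append(sorted([pa["u2"], pb["u2"]]))

    for pair in ambiguous:
        # duplicate local name in a second namespace of ontology 2
        uri = pair["u2"]
        dup_uri = ONTO2_ALT_NS + _local_name_of(pair["label2"])
        side2.doc.classes[dup_uri] = ClassRecord(
            uri=dup_uri, labels=[(fresh_label(), "")]
        )
        manifest["ambiguous_ref"].append(_token_for(uri, spec))

    # alignment assembly
    corrupted: dict[str, str] = {}
    for pair in whitespaced:
        token = _token_for(pair["u2"], spec)
        k = max(1, len(token) // 2)
        corrupted[pair["u2"]] = token[:k] + " " + token[k:]
        manifest["whitespace_corruption"].append(
            {"token": corrupted[pair["u2"]], "original": token}
        )

    omitted_set = {id(p) for p in omitted}
    untyped_set = {id(p) for p in untyped}
    correspondences: list[Correspondence] = []
    for pair in pairs:
        if id(pair) in omitted_set:
            manifest["label_identity_missing_equiv"].append([pair["u1"], pair["u2"]])
            continue
        relation = Relation.UNKNOWN if id(pair) in untyped_set else Relation.EQUIVALENT
        tok1 = _token_for(pair["u1"], spec)
        tok2 = corrupted.get(pair["u2"], _token_for(pair["u2"], spec))
        correspondences.append(
            Correspondence(
                entity1=EntityRef.from_token(tok1),
                entity2=EntityRef.from_token(tok2),
                relation=relation,
                row_provenance="row:%d" % (len(correspondences) + 1),
            )
        )
        if id(pair) in untyped_set:
            manifest["untyped_relation"].append([tok1, tok2])

    for pair, target in zip(mt_sources, extra_targets):
        correspondences.append(
            Correspondence(
                entity1=EntityRef.from_token(_token_for(pair["u1"], spec)),
                entity2=EntityRef.from_token(_token_for(target, spec)),
                relation=Relation.EQUIVALENT,
                row_provenance="row:%d" % (len(correspondences) + 1),
            )
        )
        manifest["multi_target"].append(pair["u1"])

    # trivial/non-trivial ground truth under the cleanup=True convention
    excluded_ids = {id(p) for p in ambiguous} | untyped_set | omitted_set
    excluded_uris = deleted_uris
    for pair in pairs:
        if id(pair) in excluded_ids:
            continue
        if pair["u1"] in excluded_uris or pair["u2"] in excluded_uris:
            continue
        key = "trivial" if pair["trivial"] else "non_trivial"
        manifest[key].append([pair["u1"], pair["u2"]])
    for pair, target in zip(mt_sources, extra_targets):
        manifest["non_trivial"].append([pair["u1"], target])

    for key, value in list(manifest.items()):
        manifest[key] = sorted(value, key=json.dumps)
    manifest["stats"] = {
        "n_pairs": n_pairs,
        "n_trivial": n_trivial,
        "n_nontrivial": n_nontrivial,
        "n_correspondences": len(correspondences),
        "seed": spec.seed,
    }

    alignment = Alignment(
        correspondences=correspondences,
        source_format=(
            "delimited" if spec.alignment_dialect == "delimited" else "alignment_api"
        ),
        onto1_ref=(
            side1.doc.ontology_iri if spec.alignment_dialect == "alignment_api" else ""
        ),
        onto2_ref=(
            side2.doc.ontology_iri if spec.alignment_dialect == "alignment_api" else ""
        ),
    )
    return Fixture(
        spec=spec,
        doc1=side1.doc,
        doc2=side2.doc,
        alignment=alignment,
        manifest=manifest,
        mapping_table1=mapping_table1,
        mapping_table2=mapping_table2,
    )


#: Manifest category -> (check id, finding category) correspondence.
DEFECT_CATEGORIES_TO_FINDINGS = {
    "missing_class": ("2a", "missing_class"),
    "label_changed": ("2b", "label_changed"),
    "swap_suspicion": ("2b", "swap_suspicion"),
    "whitespace_corruption": ("2a", "missing_class"),
    "ambiguous_ref": ("4", "ambiguous_ref"),
    "untyped_relation": ("5", "untyped_relation"),
    "multi_target": ("6", "multi_target"),
    "label_identity_missing_equiv": ("8", "label_identity_missing_equiv"),
    "inclusion_missing_subclass": ("9", "inclusion_missing_subclass"),
    "trivial": ("10", "trivial"),
    "non_trivial": ("10", "non_trivial"),
}


def _validate_basic(spec: FixtureSpec) -> None:
    if spec.n_classes_per_side < 2:
        raise FixtureSpecError("n_classes_per_side must be at least 2")
    if spec.max_depth < 1:
        raise FixtureSpecError("max_depth must be at least 1")
    if not 0.0 <= spec.trivial_fraction <= 1.0:
        raise FixtureSpecError("trivial_fraction must lie in [0, 1]")
    if spec.alignment_dialect not in ("delimited", "alignment_api"):
        raise FixtureSpecError(
            "alignment_dialect must be 'delimited' or 'alignment_api'"
        )
    unknown = set(spec.defect_rates) - set(DEFECT_CATEGORIES)
    if unknown:
        raise FixtureSpecError("unknown defect categories: %s" % sorted(unknown))
    negative = [c for c in DEFECT_CATEGORIES if spec.rate(c) < 0]
    if negative:
        raise FixtureSpecError("negative defect rates: %s" % negative)
    if spec.rate("ambiguous_local_name") and spec.alignment_dialect != "delimited":
        raise FixtureSpecError(
            "ambiguous_local_name requires the delimited dialect "
            "(URI references are never ambiguous)"
        )
    if spec.rate("whitespace_corruption") and spec.alignment_dialect != "delimited":
        raise FixtureSpecError(
            "whitespace_corruption requires the delimited dialect "
            "(corrupting IRIs would change their reference kind)"
        )


def _token_for(uri: str, spec: FixtureSpec) -> str:
    from .ontology_io import local_name

    if spec.alignment_dialect == "alignment_api":
        return uri
    return local_name(uri)


def _delete_class(doc: OntologyDocument, uri: str) -> None:
    """Remove a class; reattach its children to its parents."""
    tax = doc.taxonomy
    parents = {p for c, p in tax.subclass_edges if c == uri}
    children = {c for c, p in tax.subclass_edges if p == uri}
    tax.subclass_edges = {
        e for e in tax.subclass_edges if uri not in e
    } | {(c, p) for c in children for p in parents}
    tax.equivalence_edges = {e for e in tax.equivalence_edges if uri not in e}
    tax.partof_edges = {e for e in tax.partof_edges if uri not in e}
    tax.disjoint_edges = {e for e in tax.disjoint_edges if uri not in e}
    del doc.classes[uri]


def spec_from_yaml(path) -> FixtureSpec:
    """Load a FixtureSpec from a YAML file."""
    import yaml

    with open(path, encoding="utf-8") as handle:
        data = yaml.safe_load(handle) or {}
    known = {
        "n_classes_per_side", "max_depth", "label_vocabulary_size",
        "defect_rates", "trivial_fraction", "seed", "alignment_dialect",
    }
    unknown = set(data) - known
    if unknown:
        raise FixtureSpecError("unknown fixture spec keys: %s" % sorted(unknown))
    return FixtureSpec(**data)
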
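# alignqc

Quality checks for ontology alignments. `alignqc` validates a reference
alignment against its two input ontologies and reports defects across ten
checks:

| Check | Question |
|-------|----------|
| 1     | Are the exact input ontology versions bundled and identifiable? |
| 2a    | Are all referenced classes present in the loaded ontologies? |
| 2b    | Have class labels drifted relative to a URI–label mapping table? |
| 3     | Is the alignment in the standard Alignment API format? |
| 4     | Are entity references unambiguous (URIs rather than local names)? |
| 5     | Does every correspondence carry an explicit relation type? |
| 6     | Does any class map to several equivalence targets? |
| 7     | Which subsumptions follow from the equivalences plus the taxonomies? |
| 8     | Which cross-ontology pairs share a label but lack an equivalence? |
| 9     | Which pairs show label inclusion with an identical syntactic head but lack a subsumption? |
| 10    | Which correspondences are trivial (recoverable by string matching alone)? |

Checks run in the order above. Check 2 is skipped when check 1 passes;
checks 6–10 are skipped when check 5 finds untyped relations (override with
`--continue-untyped`); checks 7 and 9 are skipped when subsumption
correspondences are out of scope (`--no-subclass`).

## CLI

```sh
# run all checks; exit 0 = pass/skip only, 1 = findings, 2 = fatal
alignqc run -a reference.rdf -1 onto1.owl -2 onto2.owl --json -o report.json

# delimited (CSV-like) alignments
alignqc run -a mapping.csv -1 a.owl -2 b.owl --dialect delimited \
    --delimiter , --columns entity1,entity2,relation --cleanup

# label-drift check needs URI,label tables
alignqc run ... --mapping-table-1 nci_table.csv --mapping-table-2 ma_table.csv

# entailed subsumptions only, written as an Alignment API file
alignqc infer -a reference.rdf -1 onto1.owl -2 onto2.owl -o inferred.rdf

# trivial/non-trivial statistics only
alignqc trivial -a reference.rdf -1 onto1.owl -2 onto2.owl

# synthetic test data with planted, manifest-recorded defects
alignqc fixture --spec spec.yaml --out fixtures/
```

A YAML config mirroring all `run` flags can be passed with `--config`;
explicit flags win. JSON reports validate against the shipped
`report_schema.json`.

## Fixture generator

`alignqc.fixtures.generate_fixture` builds two random taxonomies over a
shared vocabulary, a correct alignment, and then plants defects
(`deleted_class`, `renamed_label`, `swapped_label_pair`,
`whitespace_corruption`, `ambiguous_local_name`, `multi_target`,
`omitted_trivial_equiv`, `omitted_trivial_subclass`, `untyped_relation`).
Every planted defect is recorded in `manifest.json`, whose categories map
one-to-one onto finding categories, so check output can be compared with
ground truth exactly. Generation is byte-for-byte reproducible from the
seed.

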
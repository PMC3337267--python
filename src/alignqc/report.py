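"""Report serialization (JSON + human-readable text) and validation.

The JSON layout is described by the shipped ``report_schema.json``.  A
small built-in validator covers the subset of JSON Schema the report
schema uses, so reports can be checked without extra dependencies.
"""

from __future__ import annotations

import json
from importlib import resources

from .checks import CheckReport

VERSION = "0.1.0"


def report_to_dict(
    reports: list[CheckReport],
    alignment: str = "",
    ontology1: str = "",
    ontology2: str = "",
) -> dict:
    return {
        "alignqc_version": VERSION,
        "alignment": alignment,
        "ontology1": ontology1,
        "ontology2": ontology2,
        "reports": [r.to_dict() for r in reports],
    }


def render_json(reports: list[CheckReport], **meta) -> str:
    return json.dumps(report_to_dict(reports, **meta), indent=2) + "\n"


_STATUS_LABEL = {
    "pass": "PASS",
    "findings": "FINDINGS",
    "skipped": "SKIPPED",
    "not_applicable": "N/A",
}


def render_text(reports: list[CheckReport], max_findings: int = 20) -> str:
    lines = []
    for report in reports:
        head = "Check %-3s %s" % (report.check_id, _STATUS_LABEL[report.status])
        if report.reason:
            head += "  (%s)" % report.reason
        if report.summary_counts:
            head += "  " + ", ".join(
                "%s=%s" % (k, v) for k, v in sorted(report.summary_counts.items())
            )
        lines.append(head)
        for finding in report.findings[:max_findings]:
            lines.append(
                "    [%s] %s" % (finding.category, " | ".join(finding.entities))
            )
        overflow = len(report.findings) - max_findings
        if overflow > 0:
            lines.append("    ... %d more findings" % overflow)
    return "\n".join(lines) + "\n"


def load_schema() -> dict:
    text = resources.files("alignqc").joinpath("report_schema.json").read_text()
    return json.loads(text)


class SchemaError(ValueError):
    pass


def validate_report(document: dict, schema: dict | None = None) -> None:
    """Validate a report dict against the shipped schema subset.

    Supports: type, required, properties, items, enum,
    additionalProperties-as-schema.  Raises :class:`SchemaError` with a
    JSON-pointer-ish path on first violation.
    """
    if schema is None:
        schema = load_schema()
    _validate(document, schema, "$")


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "integer": int,
    "boolean": bool,
}


def _validate(value, schema: dict, path: str) -> None:
    expected = schema.get("type")
    if expected is not None:
        pytype = _TYPES[expected]
        ok = isinstance(value, pytype)
        if expected == "number" and isinstance(value, bool):
            ok = False
        if not ok:
            raise SchemaError("%s: expected %s, got %r" % (path, expected, value))
    if "enum" in schema and value not in schema["enum"]:
        raise SchemaError("%s: %r not in %s" % (path, value, schema["enum"]))
    if isinstance(value, dict):
        for key in schema.get("required", []):
            if key not in value:
                raise SchemaError("%s: missing required key %r" % (path, key))
        properties = schema.get("properties", {})
        for key, subschema in properties.items():
            if key in value:
                _validate(value[key], subschema, "%s.%s" % (path, key))
        additional = schema.get("additionalProperties")
        if isinstance(additional, dict):
            for key, item in value.items():
                if key not in properties:
                    _validate(item, additional, "%s.%s" % (path, key))
    if isinstance(value, list) and "items" in schema:
        for i, item in enumerate(value):
            _validate(item, schema["items"], "%s[%d]" % (path, i))
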
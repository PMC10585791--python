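"""Readers and writers: OBO 1.2 (subset), a JSON ontology dialect, SSSOM TSV.

The OBO reader handles the flat-file subset needed for hierarchy-aware
mapping refinement: ``[Term]`` stanzas with ``id``, ``name``, ``synonym``,
``is_a``, ``relationship`` and ``is_obsolete`` tags.  Any other tag is
ignored with a logged warning.  Mappings travel as SSSOM TSV with a fixed
predicate table (skos match predicates plus a project CURIE for the
"unmappable" relation, which SSSOM does not standardise).
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Union

import pandas as pd

from .model import (
    Concept,
    FormatError,
    Mapping,
    MappingSet,
    Ontology,
    Relationship,
    SemanticRelation,
    ValidationError,
)

__all__ = [
    "load_ontology",
    "save_ontology",
    "load_mappings",
    "save_mappings",
    "PREDICATE_TO_RELATION",
    "RELATION_TO_PREDICATE",
]

log = logging.getLogger(__name__)

PREDICATE_TO_RELATION = {
    "skos:exactMatch": SemanticRelation.EQUIVALENT,
    "skos:broadMatch": SemanticRelation.NARROW_TO_BROAD,
    "skos:narrowMatch": SemanticRelation.BROAD_TO_NARROW,
    "skos:relatedMatch": SemanticRelation.OVERLAPPED,
    "ontoref:noMatch": SemanticRelation.UNMAPPABLE,
}
RELATION_TO_PREDICATE = {v: k for k, v in PREDICATE_TO_RELATION.items()}

_OBO_HANDLED_TAGS = {
    "id", "name", "synonym", "is_a", "relationship", "is_obsolete",
}
_SYNONYM_RE = re.compile(r'^"((?:[^"\\]|\\.)*)"')


def load_ontology(path: Union[str, Path], format: str = "obo") -> Ontology:
    """Load an ontology from ``path`` in ``obo`` or ``json`` format."""
    path = Path(path)
    if format == "obo":
        return _load_obo(path)
    if format == "json":
        return _load_json(path)
    raise ValueError(f"unsupported ontology format {format!r}")


def _load_obo(path: Path) -> Ontology:
    ontology = Ontology(version=path.stem)
    in_term = False
    stanza: dict = {}
    stanza_line = 0

    def flush() -> None:
        if not in_term or stanza.get("obsolete"):
            return
        cid = stanza.get("id")
        if cid is None:
            raise FormatError(
                f"{path}: [Term] stanza at line {stanza_line} has no id"
            )
        name = stanza.get("name")
        if name is None:
            raise FormatError(
                f"{path}: term {cid!r} (line {stanza_line}) has no name"
            )
        ontology.add_concept(Concept(cid, (name, *stanza.get("synonyms", []))))
        for parent, rtype in stanza.get("parents", []):
            ontology.add_relationship(Relationship(cid, parent, rtype))

    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("format-version:") or line.startswith(
                "data-version:"
            ):
                if line.startswith("data-version:"):
                    ontology.version = line.split(":", 1)[1].strip()
                continue
            stripped = line.strip()
            if not stripped or stripped.startswith("!"):
                continue
            if stripped.startswith("["):
                flush()
                in_term = stripped == "[Term]"
                stanza = {}
                stanza_line = lineno
                continue
            if not in_term:
                continue
            if ":" not in stripped:
                raise FormatError(f"{path}: cannot parse line {lineno}: {line!r}")
            tag, value = stripped.split(":", 1)
            tag, value = tag.strip(), value.strip()
            if tag not in _OBO_HANDLED_TAGS:
                log.warning("%s:%d: ignoring OBO tag %r", path, lineno, tag)
                continue
            if tag == "id":
                stanza["id"] = value
            elif tag == "name":
                stanza["name"] = value
            elif tag == "is_obsolete":
                stanza["obsolete"] = value.lower().startswith("true")
            elif tag == "synonym":
                match = _SYNONYM_RE.match(value)
                if not match:
                    raise FormatError(
                        f"{path}: malformed synonym at line {lineno}: {line!r}"
                    )
                stanza.setdefault("synonyms", []).append(match.group(1))
            elif tag == "is_a":
                parent = value.split("!", 1)[0].strip()
                if not parent:
                    raise FormatError(
                        f"{path}: empty is_a target at line {lineno}"
                    )
                stanza.setdefault("parents", []).append((parent, "is_a"))
            elif tag == "relationship":
                parts = value.split("!", 1)[0].split()
                if len(parts) != 2:
                    raise FormatError(
                        f"{path}: malformed relationship at line {lineno}: "
                        f"{line!r}"
                    )
                stanza.setdefault("parents", []).append((parts[1], parts[0]))
    flush()
    problems = ontology.validate()
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    return ontology


def _load_json(path: Path) -> Ontology:
    try:
        data = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    try:
        ontology = Ontology(version=data.get("version", ""))
        for entry in data["concepts"]:
            ontology.add_concept(
                Concept(entry["id"], tuple(entry["attributes"]))
            )
        for entry in data.get("relationships", []):
            ontology.add_relationship(
                Relationship(
                    entry["child"], entry["parent"], entry.get("type", "is_a")
                )
            )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: malformed ontology JSON: {exc}") from exc
    problems = ontology.validate()
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    return ontology


def save_ontology(ontology: Ontology, path: Union[str, Path]) -> None:
    """Write the JSON dialect; ``load_ontology(path, "json")`` round-trips."""
    data = {
        "version": ontology.version,
        "concepts": [
            {"id": c.id, "attributes": list(c.attributes)}
            for c in (ontology.concepts[k] for k in sorted(ontology.concepts))
        ],
        "relationships": [
            {"child": r.child, "parent": r.parent, "type": r.type}
            for r in sorted(
                ontology.relationships, key=lambda r: (r.child, r.parent, r.type)
            )
        ],
    }
    Path(path).write_text(
        json.dumps(data, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )


_SSSOM_COLUMNS = ["subject_id", "predicate_id", "object_id", "confidence"]


def load_mappings(path: Union[str, Path]) -> MappingSet:
    """Read an SSSOM TSV mapping set (subject, predicate, object, confidence)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty SSSOM file (missing header)") from None
    missing = [c for c in _SSSOM_COLUMNS[:3] if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing SSSOM columns {missing}")
    mapping_set = MappingSet(source_version="", target_version="")
    for row in frame.itertuples(index=False):
        predicate = getattr(row, "predicate_id")
        if predicate not in PREDICATE_TO_RELATION:
            raise FormatError(f"{path}: unknown predicate {predicate!r}")
        conf_raw = getattr(row, "confidence", None)
        conf = 1.0 if conf_raw is None or pd.isna(conf_raw) else float(conf_raw)
        mapping = Mapping(
            source=getattr(row, "subject_id"),
            target=getattr(row, "object_id"),
            sem_type=PREDICATE_TO_RELATION[predicate],
            conf=conf,
        )
        if mapping.pair in mapping_set:
            raise ValidationError(
                f"{path}: duplicate row for pair {mapping.pair!r}"
            )
        mapping_set.add(mapping)
    return mapping_set


def save_mappings(mapping_set: MappingSet, path: Union[str, Path]) -> None:
    """Write SSSOM TSV sorted by (subject, object) for deterministic diffs."""
    rows = [
        {
            "subject_id": m.source,
            "predicate_id": RELATION_TO_PREDICATE[m.sem_type],
            "object_id": m.target,
            "confidence": f"{m.conf:.6f}",
        }
        for m in mapping_set.sorted_mappings()
    ]
    frame = pd.DataFrame(rows, columns=_SSSOM_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
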
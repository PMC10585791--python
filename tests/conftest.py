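"""Shared fixtures: figure-derived toy ontologies and scenario helpers."""

import pytest

from ontoref import (
    Concept,
    Mapping,
    MappingSet,
    Ontology,
    RefinementConfig,
    Relationship,
    SemanticRelation,
)

OBO_FIXTURE = """\
format-version: 1.2
data-version: test-v1

[Term]
id: X:0001
name: alpha root

[Term]
id: X:0002
name: beta child
synonym: "second term" EXACT []
is_a: X:0001 ! alpha root

[Term]
id: X:0003
name: gamma part
relationship: part_of X:0001

[Term]
id: X:0004
name: obsolete thing
is_obsolete: true
"""


def _ontology(version, concepts, relationships=()):
    return Ontology(
        version=version,
        concepts=[Concept(cid, tuple(attrs)) for cid, attrs in concepts],
        relationships=[Relationship(*r) for r in relationships],
    )


@pytest.fixture
def obo_text(tmp_path):
    path = tmp_path / "mini.obo"
    path.write_text(OBO_FIXTURE, encoding="utf-8")
    return path


@pytest.fixture
def coarctation_case():
    """A new MeSH-style concept whose parent is already mapped to ICD-10.

    The added concept "Coarctation of Aorta Dominant" hangs under "Aortic
    Coarctation", which maps to "Congenital malformations of great
    arteries"; that target and its child "Coarctation of aorta" are the two
    candidates at target level 1.
    """
    source_old = _ontology(
        "mesh-2012", [("MESH:D001017", ["Aortic Coarctation"])]
    )
    source_new = _ontology(
        "mesh-2013",
        [
            ("MESH:D001017", ["Aortic Coarctation"]),
            ("MESH:D000073", ["Coarctation of Aorta Dominant"]),
        ],
        [("MESH:D000073", "MESH:D001017", "is_a")],
    )
    target = _ontology(
        "icd10-2011",
        [
            ("ICD10:Q25", ["Congenital malformations of great arteries"]),
            ("ICD10:Q25.1", ["Coarctation of aorta"]),
        ],
        [("ICD10:Q25.1", "ICD10:Q25", "is_a")],
    )
    mappings = MappingSet(
        [Mapping("MESH:D001017", "ICD10:Q25", SemanticRelation.EQUIVALENT, 1.0)],
        source_version=source_old.version,
        target_version=target.version,
    )
    config = RefinementConfig(
        source_level=1, target_level=1, threshold=0.5, measure="bigram_dice"
    )
    return source_old, source_new, target, mappings, config


@pytest.fixture
def zika_case():
    """LOINC-style addition whose own mapping has a better-fitting target parent."""
    source_old = _ontology("loinc-2.64", [("LN:zika", ["Zika virus"])])
    source_new = _ontology(
        "loinc-2.65",
        [
            ("LN:zika", ["Zika virus"]),
            ("LN:zika-igg", ["Zika virus Ab.IgG"]),
        ],
        [("LN:zika-igg", "LN:zika", "is_a")],
    )
    target = _ontology(
        "loinc-es-2.64",
        [
            ("ES:zika", ["Virus zika"]),
            ("ES:zika-igg", ["Virus Zika IgG"]),
        ],
        [("ES:zika-igg", "ES:zika", "is_a")],
    )
    mappings = MappingSet(
        [Mapping("LN:zika-igg", "ES:zika-igg", SemanticRelation.EQUIVALENT, 1.0)],
        source_version=source_new.version,
        target_version=target.version,
    )
    config = RefinementConfig(
        source_level=1,
        derivation_threshold=0.4,
        measure="levenshtein",
    )
    return source_old, source_new, target, mappings, config


@pytest.fixture
def braf_case():
    """Concept added next to an already-mapped source concept (deriveS)."""
    source_old = _ontology("loinc-2.64", [("LN:braf", ["BRAF gene"])])
    source_new = _ontology(
        "loinc-2.65",
        [
            ("LN:braf", ["BRAF gene"]),
            ("LN:braf-val", ["BRAF gene.p.Val600Lys"]),
        ],
        [("LN:braf-val", "LN:braf", "is_a")],
    )
    target = _ontology("loinc-es-2.64", [("ES:braf", ["Gen BRAF"])])
    mappings = MappingSet(
        [Mapping("LN:braf", "ES:braf", SemanticRelation.EQUIVALENT, 1.0)],
        source_version=source_new.version,
        target_version=target.version,
    )
    config = RefinementConfig(
        source_level=1,
        derivation_threshold=0.4,
        measure="levenshtein",
    )
    return source_old, source_new, target, mappings, config
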
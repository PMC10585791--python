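"""Core data model: ontologies, concepts, typed mappings.

An ontology is modelled as a set of concepts carrying ordered attribute
strings (preferred label first, synonyms after) plus typed directed
relationships between concepts.  The hierarchy (``is_a``, optionally
``part_of``) must be acyclic.  Mappings link a source-ontology concept to a
target-ontology concept with one of five semantic relations and a confidence
score in [0, 1].
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import networkx as nx

__all__ = [
    "OntoRefError",
    "FormatError",
    "ValidationError",
    "Concept",
    "Relationship",
    "Ontology",
    "SemanticRelation",
    "Mapping",
    "MappingSet",
    "HIERARCHY_TYPES",
]

#: Relationship types treated as hierarchical ("part_of" only when enabled).
HIERARCHY_TYPES = ("is_a", "part_of")


class OntoRefError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(OntoRefError):
    """An input file could not be parsed."""


class ValidationError(OntoRefError):
    """Data violates a model invariant."""


@dataclass(frozen=True)
class Concept:
    """An ontology concept: an opaque id plus ordered attribute strings.

    ``attributes[0]`` is the preferred label; the remaining entries are
    synonyms.  Similarity computations ignore the ordering.
    """

    id: str
    attributes: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("concept id must be a non-empty string")
        attrs = tuple(self.attributes)
        object.__setattr__(self, "attributes", attrs)
        if not attrs or any(not a for a in attrs):
            raise ValidationError(
                f"concept {self.id!r} needs at least one non-empty attribute"
            )

    @property
    def label(self) -> str:
        return self.attributes[0]


@dataclass(frozen=True)
class Relationship:
    """A directed typed relationship ``(child, parent, type)``."""

    child: str
    parent: str
    type: str = "is_a"

    def __post_init__(self) -> None:
        if self.child == self.parent:
            raise ValidationError(
                f"self-relationship on concept {self.child!r} is not allowed"
            )

    @property
    def is_hierarchical(self) -> bool:
        return self.type in HIERARCHY_TYPES


class Ontology:
    """A versioned ontology: concepts plus directed typed relationships."""

    def __init__(
        self,
        version: str = "",
        concepts: Optional[List[Concept]] = None,
        relationships: Optional[List[Relationship]] = None,
    ) -> None:
        self.version = version
        self.concepts: Dict[str, Concept] = {}
        self.relationships: List[Relationship] = []
        self._rel_seen: set = set()
        for c in concepts or []:
            self.add_concept(c)
        for r in relationships or []:
            self.add_relationship(r)

    def add_concept(self, concept: Concept) -> None:
        if concept.id in self.concepts:
            raise ValidationError(f"duplicate concept id {concept.id!r}")
        self.concepts[concept.id] = concept

    def add_relationship(self, rel: Relationship) -> None:
        key = (rel.child, rel.parent, rel.type)
        if key in self._rel_seen:
            raise ValidationError(f"duplicate relationship {key!r}")
        self._rel_seen.add(key)
        self.relationships.append(rel)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)

    def __getitem__(self, concept_id: str) -> Concept:
        try:
            return self.concepts[concept_id]
        except KeyError:
            raise KeyError(
                f"unknown concept id {concept_id!r} in ontology {self.version!r}"
            ) from None

    def ids(self) -> set:
        return set(self.concepts)

    def hierarchy(self, include_part_of: bool = False) -> "nx.DiGraph":
        """Directed graph of hierarchical edges, child -> parent.

        By default only ``is_a`` edges are used; ``include_part_of`` widens
        the hierarchy to ``part_of`` as well.
        """
        g = nx.DiGraph()
        g.add_nodes_from(self.concepts)
        wanted = HIERARCHY_TYPES if include_part_of else ("is_a",)
        for r in self.relationships:
            if r.type in wanted:
                g.add_edge(r.child, r.parent)
        return g

    def validate(self) -> List[str]:
        """Return human-readable invariant violations (empty list if valid)."""
        problems: List[str] = []
        for r in self.relationships:
            for endpoint in (r.child, r.parent):
                if endpoint not in self.concepts:
                    problems.append(
                        f"relationship ({r.child!r}, {r.parent!r}, {r.type!r}) "
                        f"references unknown concept {endpoint!r}"
                    )
        isa = nx.DiGraph()
        isa.add_edges_from(
            (r.child, r.parent) for r in self.relationships if r.type == "is_a"
        )
        for cycle in nx.simple_cycles(isa):
            problems.append("is_a cycle through: " + " -> ".join(sorted(cycle)))
        return problems

    def equals(self, other: "Ontology") -> bool:
        return (
            self.version == other.version
            and self.concepts == other.concepts
            and sorted(
                (r.child, r.parent, r.type) for r in self.relationships
            )
            == sorted((r.child, r.parent, r.type) for r in other.relationships)
        )


class SemanticRelation(enum.Enum):
    """The five semantic relations a mapping may carry."""

    UNMAPPABLE = "unmappable"        # ⊥
    EQUIVALENT = "equivalent"        # ≡
    NARROW_TO_BROAD = "narrow_to_broad"  # ≤  source more specific
    BROAD_TO_NARROW = "broad_to_narrow"  # ≥  source more general
    OVERLAPPED = "overlapped"        # ≈

    @property
    def symbol(self) -> str:
        return {
            SemanticRelation.UNMAPPABLE: "⊥",
            SemanticRelation.EQUIVALENT: "≡",
            SemanticRelation.NARROW_TO_BROAD: "≤",
            SemanticRelation.BROAD_TO_NARROW: "≥",
            SemanticRelation.OVERLAPPED: "≈",
        }[self]


@dataclass
class Mapping:
    """A correspondence ``(source, target, sem_type, conf)``."""

    source: str
    target: str
    sem_type: SemanticRelation = SemanticRelation.EQUIVALENT
    conf: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.conf <= 1.0):
            raise ValidationError(
                f"mapping ({self.source!r}, {self.target!r}) has confidence "
                f"{self.conf} outside [0, 1]"
            )

    @property
    def pair(self) -> Tuple[str, str]:
        return (self.source, self.target)


class MappingSet:
    """A set of mappings, at most one per (source, target) pair."""

    def __init__(
        self,
        mappings: Optional[List[Mapping]] = None,
        source_version: str = "",
        target_version: str = "",
    ) -> None:
        self.source_version = source_version
        self.target_version = target_version
        self._by_pair: Dict[Tuple[str, str], Mapping] = {}
        for m in mappings or []:
            self.add(m)

    def add(self, mapping: Mapping) -> None:
        if mapping.pair in self._by_pair:
            raise ValidationError(
                f"duplicate mapping for pair {mapping.pair!r}"
            )
        self._by_pair[mapping.pair] = mapping

    def __contains__(self, pair: Tuple[str, str]) -> bool:
        return pair in self._by_pair

    def get(self, source: str, target: str) -> Optional[Mapping]:
        return self._by_pair.get((source, target))

    def __iter__(self) -> Iterator[Mapping]:
        return iter(self._by_pair.values())

    def __len__(self) -> int:
        return len(self._by_pair)

    def sorted_mappings(self) -> List[Mapping]:
        return [self._by_pair[k] for k in sorted(self._by_pair)]

    def by_source(self, source: str) -> List[Mapping]:
        return [m for m in self.sorted_mappings() if m.source == source]

    def pairs(self) -> set:
        return set(self._by_pair)

    def sources(self) -> set:
        return {s for s, _ in self._by_pair}

    def copy(self) -> "MappingSet":
        return MappingSet(
            [Mapping(m.source, m.target, m.sem_type, m.conf) for m in self],
            source_version=self.source_version,
            target_version=self.target_version,
        )

    def equals(self, other: "MappingSet") -> bool:
        if self.pairs() != other.pairs():
            return False
        for pair, m in self._by_pair.items():
            o = other._by_pair[pair]
            if m.sem_type != o.sem_type or abs(m.conf - o.conf) > 1e-12:
                return False
        return True
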
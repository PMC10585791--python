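"""Reproducible evolving-ontology scenarios for end-to-end testing.

A scenario emulates the situation the refinement algorithms address: a
source ontology that gains concepts between two releases, a stable target
ontology, an input alignment established against the old source release,
and a gold alignment for the added concepts.

Construction: source and target are random is-a trees with labels drawn
from disjoint parts of a pronounceable synthetic lexicon
(consonant-vowel-syllable words, two words per label) so that bigram-based
similarity behaves non-degenerately.  A configurable fraction of old source
concepts is planted as true correspondences: each receives its target
partner's label as an extra synonym and an equivalence mapping.  Each added
concept is attached under one of those mapped concepts and labelled with a
noisy copy (character substitutions, length-preserving) of a target concept
in the partner's neighborhood; those planted pairs form the gold set.  The
same seed yields a byte-identical scenario.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Set, Tuple

from .diff import DiffResult, added_concepts
from .model import (
    Concept,
    Mapping,
    MappingSet,
    Ontology,
    Relationship,
    SemanticRelation,
    ValidationError,
)

__all__ = ["ScenarioParams", "Scenario", "generate_scenario", "write_scenario"]

_CONSONANTS = "bcdfghjklmnprstvz"
_VOWELS = "aeiou"


@dataclass(frozen=True)
class ScenarioParams:
    """Generator knobs; defaults give a mid-sized, mildly noisy scenario."""

    n_source: int = 80
    n_target: int = 80
    branching: int = 4
    n_added: int = 10
    label_noise: float = 0.05
    synonyms_per_concept: int = 1
    mapped_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_source, self.n_target) < 1 or self.branching < 1:
            raise ValidationError("ontology sizes and branching must be >= 1")
        if not (0.0 <= self.label_noise <= 1.0):
            raise ValidationError("label_noise must lie in [0, 1]")
        if not (0.0 <= self.mapped_fraction <= 1.0):
            raise ValidationError("mapped_fraction must lie in [0, 1]")
        if self.synonyms_per_concept < 0 or self.n_added < 0:
            raise ValidationError("counts must be non-negative")
        if self.n_added > self.n_target:
            raise ValidationError(
                "n_added exceeds n_target: cannot plant distinct gold targets"
            )
        if self.n_added > self.n_mapped:
            raise ValidationError(
                "n_added exceeds the number of mapped source concepts; "
                "raise mapped_fraction or n_source"
            )

    @property
    def n_mapped(self) -> int:
        return round(self.mapped_fraction * self.n_source)


@dataclass
class Scenario:
    """All artifacts of one generated evolution scenario."""

    source_old: Ontology
    source_new: Ontology
    target: Ontology
    input_mappings: MappingSet
    gold: MappingSet
    diff: DiffResult
    params: ScenarioParams


def _word(rng: random.Random) -> str:
    return "".join(
        rng.choice(_CONSONANTS) + rng.choice(_VOWELS)
        for _ in range(rng.randint(3, 4))
    )


def _unique_term(rng: random.Random, used: Set[str]) -> str:
    while True:
        term = f"{_word(rng)} {_word(rng)}"
        if term not in used:
            used.add(term)
            return term


def _noisy_copy(label: str, noise: float, rng: random.Random) -> str:
    """Substitute letters at rate ``noise``; keeps length and word breaks."""
    out = []
    for ch in label:
        if ch.isalpha() and rng.random() < noise:
            out.append(rng.choice(string.ascii_lowercase.replace(ch, "")))
        else:
            out.append(ch)
    return "".join(out)


def _random_tree(
    rng: random.Random,
    n: int,
    prefix: str,
    version: str,
    used_terms: Set[str],
    branching: int,
    synonyms: int,
) -> Ontology:
    ontology = Ontology(version=version)
    ids: List[str] = []
    child_count: Dict[str, int] = {}
    for i in range(n):
        cid = f"{prefix}:{i:04d}"
        attrs = [_unique_term(rng, used_terms)]
        attrs += [_unique_term(rng, used_terms) for _ in range(synonyms)]
        ontology.add_concept(Concept(cid, tuple(attrs)))
        if ids:
            eligible = [p for p in ids if child_count.get(p, 0) < branching]
            parent = rng.choice(eligible or ids)
            child_count[parent] = child_count.get(parent, 0) + 1
            ontology.add_relationship(Relationship(cid, parent, "is_a"))
        ids.append(cid)
    return ontology


def generate_scenario(params: ScenarioParams) -> Scenario:
    """Build one deterministic scenario from ``params`` (seeded)."""
    rng = random.Random(params.seed)
    used_terms: Set[str] = set()

    target = _random_tree(
        rng, params.n_target, "T", "target-v1", used_terms,
        params.branching, params.synonyms_per_concept,
    )
    source_old = _random_tree(
        rng, params.n_source, "S", "source-v1", used_terms,
        params.branching, params.synonyms_per_concept,
    )

    # plant true correspondences: mapped source concepts gain their target
    # partner's label as a cross-terminology synonym
    source_ids = sorted(source_old.ids())
    target_ids = sorted(target.ids())
    mapped_sources = sorted(rng.sample(source_ids, params.n_mapped))
    partners = rng.sample(target_ids, params.n_mapped)
    partner_of = dict(zip(mapped_sources, partners))
    for sid, tid in partner_of.items():
        c = source_old.concepts[sid]
        source_old.concepts[sid] = Concept(
            c.id, c.attributes + (target[tid].label,)
        )
    input_mappings = MappingSet(
        [
            Mapping(sid, tid, SemanticRelation.EQUIVALENT, 1.0)
            for sid, tid in sorted(partner_of.items())
        ],
        source_version=source_old.version,
        target_version=target.version,
    )

    # new release: copy plus added concepts under mapped parents, labelled
    # as noisy copies of a gold target in the partner's neighborhood
    source_new = Ontology(
        version="source-v2",
        concepts=list(source_old.concepts.values()),
        relationships=list(source_old.relationships),
    )
    target_children: Dict[str, List[str]] = {}
    for r in target.relationships:
        target_children.setdefault(r.parent, []).append(r.child)
    partner_targets = set(partners)
    used_gold: Set[str] = set()
    gold = MappingSet(
        source_version=source_new.version, target_version=target.version
    )
    parents = sorted(rng.sample(mapped_sources, params.n_added))
    for i, parent in enumerate(parents):
        t_partner = partner_of[parent]
        gold_target = t_partner
        children = [
            c
            for c in sorted(target_children.get(t_partner, []))
            if c not in partner_targets and c not in used_gold
        ]
        if children and rng.random() < 0.4:
            gold_target = rng.choice(children)
        used_gold.add(gold_target)
        new_id = f"SN:{i:04d}"
        label = _noisy_copy(
            target[gold_target].label, params.label_noise, rng
        )
        syns = tuple(
            _unique_term(rng, used_terms)
            for _ in range(params.synonyms_per_concept)
        )
        source_new.add_concept(Concept(new_id, (label, *syns)))
        source_new.add_relationship(Relationship(new_id, parent, "is_a"))
        gold.add(Mapping(new_id, gold_target, SemanticRelation.EQUIVALENT, 1.0))

    diff = added_concepts(source_old, source_new)
    return Scenario(
        source_old=source_old,
        source_new=source_new,
        target=target,
        input_mappings=input_mappings,
        gold=gold,
        diff=diff,
        params=params,
    )


def write_scenario(scenario: Scenario, out_dir) -> Dict[str, Path]:
    """Write the five artifacts (JSON ontologies, SSSOM TSVs, added-id list)."""
    from .io import save_mappings, save_ontology

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "source_old": out / "source_old.json",
        "source_new": out / "source_new.json",
        "target": out / "target.json",
        "input_mappings": out / "input_mappings.tsv",
        "gold": out / "gold.tsv",
        "added": out / "added.txt",
    }
    save_ontology(scenario.source_old, paths["source_old"])
    save_ontology(scenario.source_new, paths["source_new"])
    save_ontology(scenario.target, paths["target"])
    save_mappings(scenario.input_mappings, paths["input_mappings"])
    save_mappings(scenario.gold, paths["gold"])
    paths["added"].write_text(
        "".join(f"{cid}\n" for cid in sorted(scenario.diff.added)),
        encoding="utf-8",
    )
    return paths
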
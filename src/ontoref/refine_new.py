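"""Align newly added source concepts to the target ontology.

Two strategies are implemented:

* **Contextual** (``refine_contextual``): for each concept added in the new
  source release, look for *anchors* — concepts in its neighborhood
  CT(c, γ) that already existed in the previous release and participate in
  the input mapping set.  The targets of the anchors' mappings, together
  with their own target-side neighborhoods CT(t, λ), form the candidate
  set.  The candidate with maximal concept similarity is proposed as an
  equivalence mapping when its score reaches the threshold τ.  Because the
  candidate set is a small neighborhood rather than the whole target
  ontology, the work per added concept is bounded by the neighborhood size.

* **All-concepts baseline** (``refine_all_concepts``): compare each added
  concept against every target concept and keep the global argmax — the
  O(n·m) strategy the contextual search is designed to avoid.

Both emit at most one mapping per added concept, typed as equivalence, with
the similarity score as confidence.  Ties at the maximal score are broken
toward the lexicographically smallest target id so runs are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .context import context_set
from .diff import added_concepts
from .model import Mapping, MappingSet, Ontology, SemanticRelation, ValidationError
from .similarity import concept_similarity, get_measure

__all__ = [
    "RefinementConfig",
    "ProvenanceRecord",
    "RefinementResult",
    "refine_contextual",
    "refine_all_concepts",
]


@dataclass(frozen=True)
class RefinementConfig:
    """Tunable parameters of the refinement algorithms.

    source_level (γ) and target_level (λ) bound neighborhood exploration in
    the source and target ontologies; threshold (τ) is the minimum
    similarity for a proposed mapping; derivation_threshold (σ) gates the
    derivation actions and defaults to τ; measure names the registered
    similarity function.  ``strict_gt`` makes the all-concepts baseline use
    a strict ``> τ`` comparison instead of the unified ``≥ τ``.
    """

    source_level: int = 1
    target_level: int = 1
    threshold: float = 0.75
    derivation_threshold: Optional[float] = None
    measure: str = "bigram_dice"
    strict_gt: bool = False
    include_part_of: bool = False
    strict_siblings: bool = False

    def __post_init__(self) -> None:
        if self.source_level < 0 or self.target_level < 0:
            raise ValidationError("context levels must be non-negative")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValidationError("threshold must lie in [0, 1]")
        if self.derivation_threshold is not None and not (
            0.0 <= self.derivation_threshold <= 1.0
        ):
            raise ValidationError("derivation threshold must lie in [0, 1]")

    @property
    def sigma(self) -> float:
        return (
            self.threshold
            if self.derivation_threshold is None
            else self.derivation_threshold
        )

    def measure_fn(self):
        return get_measure(self.measure)


@dataclass(frozen=True)
class ProvenanceRecord:
    """Why an added concept did or did not receive a mapping."""

    added: str
    anchors: Tuple[str, ...]
    n_candidates: int
    winner: Optional[str]
    score: float
    emitted: bool
    note: str = ""


@dataclass
class RefinementResult:
    """Proposed mappings for added concepts plus a per-concept audit log."""

    mappings: MappingSet
    log: List[ProvenanceRecord] = field(default_factory=list)


def _best_candidate(
    new_concept, target: Ontology, candidate_ids, measure
) -> Tuple[Optional[str], float]:
    """Argmax of concept similarity; lexicographic tie-break on target id."""
    winner, best = None, -1.0
    for cid in sorted(candidate_ids):
        score = concept_similarity(new_concept, target[cid], measure)
        if score > best:
            winner, best = cid, score
    return winner, max(best, 0.0)


def refine_contextual(
    source_old: Ontology,
    source_new: Ontology,
    target: Ontology,
    mappings: MappingSet,
    config: RefinementConfig,
) -> RefinementResult:
    """Context-guided alignment of concepts added between two source releases."""
    _check_mapping_ids(mappings, source_old, target)
    measure = config.measure_fn()
    diff = added_concepts(source_old, source_new)
    mapped_sources = mappings.sources()
    result = RefinementResult(
        mappings=MappingSet(
            source_version=source_new.version, target_version=target.version
        )
    )
    for added in sorted(diff.added):
        neighborhood = context_set(
            source_new,
            added,
            config.source_level,
            include_part_of=config.include_part_of,
            strict_siblings=config.strict_siblings,
        ).members()
        # anchors must exist in the previous release: their mappings were
        # established against that version
        anchors = tuple(
            sorted(
                cid
                for cid in neighborhood
                if cid in source_old and cid in mapped_sources
            )
        )
        candidates: set = set()
        for anchor in anchors:
            for m in mappings.by_source(anchor):
                candidates.add(m.target)
                candidates.update(
                    context_set(
                        target,
                        m.target,
                        config.target_level,
                        include_part_of=config.include_part_of,
                        strict_siblings=config.strict_siblings,
                    ).members()
                )
        if not candidates:
            result.log.append(
                ProvenanceRecord(
                    added, anchors, 0, None, 0.0, False,
                    note="no mapped concept in context",
                )
            )
            continue
        winner, score = _best_candidate(
            source_new[added], target, candidates, measure
        )
        emit = score >= config.threshold
        if emit:
            result.mappings.add(
                Mapping(added, winner, SemanticRelation.EQUIVALENT, score)
            )
        result.log.append(
            ProvenanceRecord(
                added, anchors, len(candidates), winner, score, emit,
                note="" if emit else "below threshold",
            )
        )
    return result


def refine_all_concepts(
    source_old: Ontology,
    source_new: Ontology,
    target: Ontology,
    config: RefinementConfig,
) -> RefinementResult:
    """Baseline: match each added concept against the whole target ontology."""
    measure = config.measure_fn()
    diff = added_concepts(source_old, source_new)
    result = RefinementResult(
        mappings=MappingSet(
            source_version=source_new.version, target_version=target.version
        )
    )
    candidates = target.ids()
    if not candidates:
        result.log.append(
            ProvenanceRecord(
                "", (), 0, None, 0.0, False, note="empty target ontology"
            )
        )
        return result
    for added in sorted(diff.added):
        winner, score = _best_candidate(
            source_new[added], target, candidates, measure
        )
        emit = score > config.threshold if config.strict_gt else (
            score >= config.threshold
        )
        if emit:
            result.mappings.add(
                Mapping(added, winner, SemanticRelation.EQUIVALENT, score)
            )
        result.log.append(
            ProvenanceRecord(
                added, (), len(candidates), winner, score, emit,
                note="" if emit else "below threshold",
            )
        )
    return result


def _check_mapping_ids(
    mappings: MappingSet, source: Ontology, target: Ontology
) -> None:
    for m in mappings:
        if m.source not in source:
            raise ValidationError(
                f"mapping source {m.source!r} is not in the source ontology"
            )
        if m.target not in target:
            raise ValidationError(
                f"mapping target {m.target!r} is not in the target ontology"
            )
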
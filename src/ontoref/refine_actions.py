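"""Typed mapping refinement driven by concept additions: local rematch plus
the three refinement actions *deriveS*, *deriveT* and *modSemType*.

Given a candidate mapping set (equivalence/overlap mappings between the
current source release and the target) and the list of concepts added since
the previous source release, the addition procedure rematches the local
neighborhoods of each affected mapping and applies:

* **deriveS** — create a mapping with the same target and a different
  source concept, when the two source concepts are similar enough (≥ σ) and
  the pair is not already mapped;
* **deriveT** — create a mapping with the same source and a different
  target concept under the symmetric condition;
* **modSemType** — replace a mapping's semantic relation with a different
  one (endpoints and confidence untouched).

Actions never delete: the refined set always contains every input mapping.

Derived and modified relations are typed from hierarchy direction, the only
typed signal available: a new target that is an ancestor of the original
target makes the source concept comparatively narrower (≤), a descendant
makes it broader (≥); symmetrically for new source concepts; lateral
(sibling) neighbors yield the overlap relation (≈).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import networkx as nx
import numpy as np

from .context import context_set
from .diff import added_concepts
from .model import (
    Concept,
    Mapping,
    MappingSet,
    Ontology,
    SemanticRelation,
    ValidationError,
)
from .refine_new import RefinementConfig
from .similarity import concept_similarity

__all__ = [
    "SimilarityMatrix",
    "RefinementAction",
    "local_rematch",
    "derive_source",
    "derive_target",
    "modify_semtype",
    "addition_procedure",
]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Pairwise concept similarities between a source and a target set."""

    row_ids: Tuple[str, ...]
    col_ids: Tuple[str, ...]
    values: np.ndarray

    def get(self, row_id: str, col_id: str) -> float:
        return float(
            self.values[self.row_ids.index(row_id), self.col_ids.index(col_id)]
        )


@dataclass(frozen=True)
class RefinementAction:
    """One applied refinement step, sufficient to replay it.

    ``kind`` is deriveS/deriveT/modSemType; ``mapping`` is the created
    (derivations) or affected (modSemType) mapping after the action;
    ``old_type`` is set for modSemType only; ``trigger`` states the
    condition that licensed the action; ``score`` the similarity involved.
    """

    kind: str
    mapping: Mapping
    trigger: str
    score: float
    old_type: Optional[SemanticRelation] = None


def local_rematch(
    sources: Iterable[Concept],
    targets: Iterable[Concept],
    measure,
) -> SimilarityMatrix:
    """Similarity matrix over two concept sets, rows/columns sorted by id."""
    rows = sorted(sources, key=lambda c: c.id)
    cols = sorted(targets, key=lambda c: c.id)
    if not rows or not cols:
        raise ValidationError("local rematch requires non-empty concept sets")
    values = np.array(
        [[concept_similarity(r, c, measure) for c in cols] for r in rows]
    )
    return SimilarityMatrix(
        tuple(c.id for c in rows), tuple(c.id for c in cols), values
    )


def _hierarchy_relation(
    ontology: Ontology, original: str, new: str, include_part_of: bool
) -> Tuple[SemanticRelation, SemanticRelation]:
    """(relation if `new` replaces the target, relation if it replaces the source).

    ``new`` ancestor of ``original``: a broader target means the source is
    narrower (≤); a broader *source* is more general than the target (≥).
    Descendants invert; lateral neighbors give overlap for both roles.
    """
    graph = ontology.hierarchy(include_part_of)
    if nx.has_path(graph, original, new):  # new is an ancestor
        return SemanticRelation.NARROW_TO_BROAD, SemanticRelation.BROAD_TO_NARROW
    if nx.has_path(graph, new, original):  # new is a descendant
        return SemanticRelation.BROAD_TO_NARROW, SemanticRelation.NARROW_TO_BROAD
    return SemanticRelation.OVERLAPPED, SemanticRelation.OVERLAPPED


def derive_source(
    mapping_set: MappingSet,
    m: Mapping,
    ck: Concept,
    config: RefinementConfig,
    source_ontology: Ontology,
) -> Optional[RefinementAction]:
    """Derive (ck, m.target) from m when sim(m.source, ck) ≥ σ and unmapped."""
    if ck.id == m.source:
        raise ValidationError("derived source must differ from the original")
    if m.pair not in mapping_set:
        raise ValidationError("mapping to derive from is not in the set")
    score = concept_similarity(
        source_ontology[m.source], ck, config.measure_fn()
    )
    if score < config.sigma or (ck.id, m.target) in mapping_set:
        return None
    _, as_source = _hierarchy_relation(
        source_ontology, m.source, ck.id, config.include_part_of
    )
    derived = Mapping(ck.id, m.target, as_source, score)
    mapping_set.add(derived)
    return RefinementAction(
        kind="deriveS",
        mapping=derived,
        trigger=f"sim({m.source}, {ck.id}) = {score:.3f} >= sigma",
        score=score,
    )


def derive_target(
    mapping_set: MappingSet,
    m: Mapping,
    ck: Concept,
    config: RefinementConfig,
    source_ontology: Ontology,
    target_ontology: Ontology,
) -> Optional[RefinementAction]:
    """Derive (m.source, ck) from m when sim(m.source, ck) ≥ σ and unmapped."""
    if ck.id == m.target:
        raise ValidationError("derived target must differ from the original")
    if m.pair not in mapping_set:
        raise ValidationError("mapping to derive from is not in the set")
    score = concept_similarity(
        source_ontology[m.source], ck, config.measure_fn()
    )
    if score < config.sigma or (m.source, ck.id) in mapping_set:
        return None
    as_target, _ = _hierarchy_relation(
        target_ontology, m.target, ck.id, config.include_part_of
    )
    derived = Mapping(m.source, ck.id, as_target, score)
    mapping_set.add(derived)
    return RefinementAction(
        kind="deriveT",
        mapping=derived,
        trigger=f"sim({m.source}, {ck.id}) = {score:.3f} >= sigma",
        score=score,
    )


def modify_semtype(
    m: Mapping, new_type: SemanticRelation
) -> RefinementAction:
    """Replace a mapping's semantic relation in place (conf untouched)."""
    if new_type == m.sem_type:
        raise ValidationError(
            f"new semantic relation equals the current one ({new_type.value})"
        )
    old = m.sem_type
    m.sem_type = new_type
    return RefinementAction(
        kind="modSemType",
        mapping=m,
        trigger=f"{old.symbol} -> {new_type.symbol}",
        score=m.conf,
        old_type=old,
    )


def _best_by_similarity(ids, scores) -> Optional[str]:
    """Argmax id; lexicographically smallest wins ties; None when empty."""
    best_id, best = None, -1.0
    for cid in sorted(ids):
        if scores[cid] > best:
            best_id, best = cid, scores[cid]
    return best_id


def addition_procedure(
    source_old: Ontology,
    source_new: Ontology,
    target: Ontology,
    mappings: MappingSet,
    config: RefinementConfig,
) -> Tuple[MappingSet, List[RefinementAction]]:
    """Refine a candidate mapping set based on concepts added to the source.

    For every added concept c_a:

    a) for each candidate mapping m whose source is c_a, the neighborhoods
       {c_a} ∪ CT(c_a, γ) and {m.target} ∪ CT(m.target, γ) are rematched
       locally, then
       - if some ancestor p of c_a matches m.target strictly better than
         c_a does, m is retyped ≤ (the new concept is a specialization) and
         a mapping (p, m.target) is derived;
       - the best ancestor (resp. descendant) q of m.target matching c_a at
         least as well as m.target triggers a derived mapping (c_a, q);
    b) each candidate mapping m with c_a in CT(m.source, γ) may derive
       (c_a, m.target), covering concepts added near an already-mapped
       source concept.

    Returns the refined set (a superset of the input) and the action log in
    application order.
    """
    measure = config.measure_fn()
    gamma = config.source_level
    diff = added_concepts(source_old, source_new)
    refined = mappings.copy()
    actions: List[RefinementAction] = []

    for c_a in sorted(diff.added):
        ca_concept = source_new[c_a]
        ca_ctx = context_set(
            source_new, c_a, gamma,
            include_part_of=config.include_part_of,
            strict_siblings=config.strict_siblings,
        )

        # (a) mappings whose source is the added concept itself
        for m in refined.by_source(c_a):
            t_ctx = context_set(
                target, m.target, gamma,
                include_part_of=config.include_part_of,
                strict_siblings=config.strict_siblings,
            )
            source_set = {c_a} | ca_ctx.members()
            target_set = {m.target} | t_ctx.members()
            matrix = local_rematch(
                (source_new[i] for i in source_set),
                (target[i] for i in target_set),
                measure,
            )
            base = matrix.get(c_a, m.target)

            # R1: an ancestor of the added concept fits the target better
            sup_ids = {cid for cid, _ in ca_ctx.sup}
            sup_scores = {cid: matrix.get(cid, m.target) for cid in sup_ids}
            best_sup = _best_by_similarity(sup_ids, sup_scores)
            if best_sup is not None and sup_scores[best_sup] > base:
                if m.sem_type != SemanticRelation.NARROW_TO_BROAD:
                    actions.append(
                        modify_semtype(m, SemanticRelation.NARROW_TO_BROAD)
                    )
                action = derive_source(
                    refined, m, source_new[best_sup], config, source_new
                )
                if action is not None:
                    actions.append(action)

            # R2 / R3: ancestors resp. descendants of the target fit the
            # added concept at least as well as the mapped target does
            for partition, label in ((t_ctx.sup, "R2"), (t_ctx.sub, "R3")):
                ids = {cid for cid, _ in partition}
                scores = {cid: matrix.get(c_a, cid) for cid in ids}
                best = _best_by_similarity(ids, scores)
                if best is not None and scores[best] >= base:
                    action = derive_target(
                        refined, m, target[best], config, source_new, target
                    )
                    if action is not None:
                        actions.append(action)

        # (b) the added concept sits in the neighborhood of a mapped source
        for m in mappings.sorted_mappings():
            if m.source == c_a or c_a not in context_set(
                source_new, m.source, gamma,
                include_part_of=config.include_part_of,
                strict_siblings=config.strict_siblings,
            ):
                continue
            live = refined.get(m.source, m.target)
            if live is None:
                continue
            action = derive_source(
                refined, live, ca_concept, config, source_new
            )
            if action is not None:
                actions.append(action)

    return refined, actions
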
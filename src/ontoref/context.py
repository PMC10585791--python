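"""Concept neighborhoods: super-, sub- and sibling concepts within a hop limit.

The context CT(c, λ) of a concept c is the union of three partitions of its
hierarchical neighborhood:

* ``sup`` — ancestors reachable by ascending at most λ hierarchy edges,
* ``sub`` — descendants reachable by descending at most λ edges,
* ``sib`` — concepts sharing a direct parent or a direct child with c.

λ bounds the shortest hierarchy distance between c and a neighbor.  Siblings
sit at hierarchy distance 2 (via the shared neighbor), so a literal reading
of the distance bound would leave ``sib`` empty at λ = 1 while neighborhood
levels of 1 are the common operating point; by default siblings are
therefore admitted whenever λ ≥ 1 (distance bound max(λ, 2)), and
``strict_siblings=True`` restores the literal bound.  In multi-parent DAGs
the partitions can overlap; each neighbor is reported once, with ``sup``
taking precedence over ``sub`` over ``sib``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Set, Tuple

import networkx as nx

from .model import Ontology

__all__ = ["ContextSet", "hierarchy_length", "context_set"]


@dataclass(frozen=True)
class ContextSet:
    """The three neighborhood partitions of a concept, with hop distances."""

    center: str
    level: int
    sup: FrozenSet[Tuple[str, int]]
    sub: FrozenSet[Tuple[str, int]]
    sib: FrozenSet[Tuple[str, int]]

    def members(self) -> Set[str]:
        """All neighbor ids, partitions merged."""
        return {cid for cid, _ in self.sup | self.sub | self.sib}

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.members()

    def __len__(self) -> int:
        return len(self.members())


def hierarchy_length(
    ontology: Ontology,
    a: str,
    b: str,
    include_part_of: bool = False,
) -> float:
    """Shortest undirected path length over hierarchy edges; inf if disconnected."""
    ontology[a], ontology[b]  # raise KeyError on unknown ids
    if a == b:
        return 0
    graph = ontology.hierarchy(include_part_of).to_undirected(as_view=True)
    try:
        return nx.shortest_path_length(graph, a, b)
    except nx.NetworkXNoPath:
        return math.inf


def _within_hops(graph: nx.DiGraph, start: str, hops: int) -> Dict[str, int]:
    """Nodes reachable from ``start`` in at most ``hops`` directed steps."""
    if hops <= 0:
        return {}
    dist = nx.single_source_shortest_path_length(graph, start, cutoff=hops)
    dist.pop(start, None)
    return dist


def context_set(
    ontology: Ontology,
    c: str,
    level: int,
    include_part_of: bool = False,
    strict_siblings: bool = False,
) -> ContextSet:
    """Compute CT(c, level) over the concept hierarchy of ``ontology``."""
    if level < 0:
        raise ValueError(f"context level must be non-negative, got {level}")
    ontology[c]  # raise KeyError on unknown id
    graph = ontology.hierarchy(include_part_of)

    sup = _within_hops(graph, c, level)                  # ascend child->parent
    sub = _within_hops(graph.reverse(copy=False), c, level)

    sib: Dict[str, int] = {}
    bound = level if strict_siblings else (max(level, 2) if level >= 1 else 0)
    if bound >= 1:
        direct_parents = set(graph.successors(c))
        direct_children = set(graph.predecessors(c))
        candidates: Set[str] = set()
        for p in direct_parents:
            candidates.update(graph.predecessors(p))
        for ch in direct_children:
            candidates.update(graph.successors(ch))
        candidates.discard(c)
        for cand in candidates:
            d = hierarchy_length(ontology, c, cand, include_part_of)
            if d <= bound:
                sib[cand] = int(d)

    # sup > sub > sib precedence so each neighbor is reported once
    for cid in list(sub):
        if cid in sup:
            del sub[cid]
    for cid in list(sib):
        if cid in sup or cid in sub:
            del sib[cid]

    return ContextSet(
        center=c,
        level=level,
        sup=frozenset(sup.items()),
        sub=frozenset(sub.items()),
        sib=frozenset(sib.items()),
    )
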
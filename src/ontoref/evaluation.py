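"""Score proposed mappings against a gold alignment.

Precision is the fraction of proposed mappings found in the gold set,
recall the fraction of gold mappings recovered, and F-measure their
harmonic mean.  Following the usual evaluation protocol for refinement
under ontology evolution, the gold set is first restricted to mappings
whose source is a newly added concept.  Correctness is judged on the
(source, target) pair; ``strict_type`` additionally requires the semantic
relation to agree.  All zero denominators yield 0 rather than an error.
"""

from __future__ import annotations

from dataclasses import dataclass

from .diff import DiffResult
from .model import MappingSet

__all__ = ["EvaluationReport", "restrict_to_added", "score"]


@dataclass(frozen=True)
class EvaluationReport:
    identified: int
    correct_identified: int
    gold: int
    precision: float
    recall: float
    f_measure: float

    def summary(self) -> str:
        return (
            f"identified={self.identified} correct={self.correct_identified} "
            f"gold={self.gold} P={self.precision:.3f} R={self.recall:.3f} "
            f"F={self.f_measure:.3f}"
        )


def restrict_to_added(gold: MappingSet, added: DiffResult) -> MappingSet:
    """Keep only gold mappings whose source concept was newly added."""
    return MappingSet(
        [m for m in gold.sorted_mappings() if m.source in added.added],
        source_version=gold.source_version,
        target_version=gold.target_version,
    )


def score(
    proposed: MappingSet, gold: MappingSet, strict_type: bool = False
) -> EvaluationReport:
    """Precision/recall/F-measure of ``proposed`` against ``gold``."""
    correct = 0
    for m in proposed:
        g = gold.get(m.source, m.target)
        if g is None:
            continue
        if strict_type and g.sem_type != m.sem_type:
            continue
        correct += 1
    identified, expected = len(proposed), len(gold)
    precision = correct / identified if identified else 0.0
    recall = correct / expected if expected else 0.0
    f_measure = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return EvaluationReport(
        identified=identified,
        correct_identified=correct,
        gold=expected,
        precision=precision,
        recall=recall,
        f_measure=f_measure,
    )
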
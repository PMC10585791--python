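"""String and concept similarity measures.

Two lexical measures are provided behind a by-name registry:

* ``bigram_dice`` — Dice coefficient over distinct character bigrams of the
  normalized strings: 2·|B(x) ∩ B(y)| / (|B(x)| + |B(y)|).  Normalization
  lowercases and strips whitespace/punctuation, so bigrams span word
  boundaries ("of ear" yields "fe").
* ``levenshtein`` — 1 − editDistance / max length over the normalized
  strings (edit distance computed with edlib).

Concept similarity is the maximum pairwise attribute similarity: each
attribute string of one concept is compared with each attribute of the
other and the best value wins.
"""

from __future__ import annotations

from typing import Callable, Dict, Set

import edlib

from .model import Concept, ValidationError

__all__ = [
    "normalize_label",
    "bigram_set",
    "dice_similarity",
    "levenshtein_similarity",
    "concept_similarity",
    "get_measure",
    "register_measure",
    "MEASURES",
]

SimilarityFn = Callable[[str, str], float]


def normalize_label(s: str) -> str:
    """Lowercase and keep only letters and digits (whitespace/punctuation out)."""
    return "".join(ch for ch in s.lower() if ch.isalnum())


def bigram_set(s: str) -> Set[str]:
    """Distinct adjacent character pairs of the normalized string."""
    n = normalize_label(s)
    return {n[i : i + 2] for i in range(len(n) - 1)}


def dice_similarity(x: str, y: str) -> float:
    """Dice coefficient over distinct bigram sets; 0 when both sets are empty."""
    bx, by = bigram_set(x), bigram_set(y)
    denom = len(bx) + len(by)
    if denom == 0:
        return 0.0
    return 2.0 * len(bx & by) / denom


def levenshtein_similarity(x: str, y: str) -> float:
    """Normalized edit-distance similarity; 1 when both normalize to empty."""
    nx_, ny = normalize_label(x), normalize_label(y)
    longest = max(len(nx_), len(ny))
    if longest == 0:
        return 1.0
    if not nx_ or not ny:
        return 0.0
    distance = edlib.align(nx_, ny, task="distance")["editDistance"]
    return 1.0 - distance / longest


MEASURES: Dict[str, SimilarityFn] = {
    "bigram_dice": dice_similarity,
    "levenshtein": levenshtein_similarity,
}


def register_measure(name: str, fn: SimilarityFn) -> None:
    """Register a user-supplied measure under ``name`` (overwrites allowed)."""
    MEASURES[name] = fn


def get_measure(name: str) -> SimilarityFn:
    try:
        return MEASURES[name]
    except KeyError:
        raise ValueError(
            f"unknown similarity measure {name!r}; "
            f"available: {sorted(MEASURES)}"
        ) from None


def concept_similarity(
    ci: Concept, cj: Concept, measure: SimilarityFn = dice_similarity
) -> float:
    """Maximum attribute-pair similarity between two concepts (symmetric)."""
    if not ci.attributes or not cj.attributes:
        raise ValidationError("concept similarity needs non-empty attributes")
    return max(measure(a, b) for a in ci.attributes for b in cj.attributes)
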
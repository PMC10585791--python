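"""Detect concept additions between two releases of the same ontology.

Of the ontology change operations that occur during terminology evolution
(additions, removals, revisions, complex changes), only the addition of
concepts is considered here: a concept is "added" when its identifier is
present in the new release and absent from the old one.  Identifiers are
assumed permanent (LOINC-code style), so id set difference is sufficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet

from .model import Ontology

__all__ = ["DiffResult", "added_concepts"]


@dataclass(frozen=True)
class DiffResult:
    """Identifiers of concepts added between two releases."""

    added: FrozenSet[str]
    old_version: str
    new_version: str


def added_concepts(old: Ontology, new: Ontology) -> DiffResult:
    """Ids present in ``new`` and absent from ``old``; removals are ignored."""
    return DiffResult(
        added=frozenset(new.ids() - old.ids()),
        old_version=old.version,
        new_version=new.version,
    )
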
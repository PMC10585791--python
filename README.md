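# ontoref

Context-based refinement of mappings between evolving biomedical ontologies.

Large clinical terminologies (SNOMED CT, MeSH, ICD, NCI Thesaurus, LOINC,
…) are interlinked by *mappings* — typed correspondences between concepts
of a source and a target ontology.  Every new release of the source
ontology adds concepts that the existing alignment does not cover, and
re-matching two ontologies of 10⁵ concepts from scratch is costly and
noisy.  `ontoref` is for terminology maintainers who need to keep an
alignment current across releases: it proposes mappings for the newly
added concepts by exploiting the alignment that already exists, and it
enriches a candidate mapping set with semantic relations beyond
equivalence.

## The method

An ontology is O = (C, R, A): concepts C with attribute strings A(c)
(label and synonyms) and directed typed relationships R.  The *context*
of a concept is its hierarchical neighborhood

    CT(c, λ) = sup(c, λ) ∪ sub(c, λ) ∪ sib(c, λ),

super-/sub-concepts within λ hops plus siblings (shared direct parent or
child).  Concept similarity is the maximum attribute-pair similarity
sim(cᵢ, cⱼ) = max sim(a_ix, a_jy); the default string measure is the
bigram Dice coefficient

    sim(X, Y) = 2·|B(X) ∩ B(Y)| / (|B(X)| + |B(Y)|)

over distinct character bigrams of the lowercased, whitespace-stripped
strings, with normalized Levenshtein similarity as the alternative.
A mapping is m = (c_s, c_t, semType, conf) with
semType ∈ {⊥, ≡, ≤, ≥, ≈}.

Given two source releases, a target ontology, and the mapping set
established against the old release:

* **Contextual alignment** (`refine_contextual`): for each added concept,
  concepts in its context CT(c, γ) that already carry a mapping act as
  *anchors*; the anchors' targets and their contexts CT(t, λ) form the
  candidate set, and the best candidate is proposed as an equivalence
  mapping when its similarity reaches the threshold τ.  Work per concept
  is bounded by the neighborhood size instead of |target|.
* **All-concepts baseline** (`refine_all_concepts`): global argmax over
  the whole target ontology — the O(n·m) comparison point.
* **Refinement actions** (`addition_procedure`): a local rematch of the
  source and target neighborhoods of each mapping affected by an added
  concept drives three actions — *deriveS* (same target, new source),
  *deriveT* (same source, new target), both gated by a derivation
  threshold σ, and *modSemType* (retype a relation).  Derived relations
  are typed by hierarchy direction (ancestor target ⇒ ≤, descendant ⇒ ≥,
  lateral ⇒ ≈).  Actions never delete mappings.
* **Evaluation** (`score`): precision, recall and F-measure against a
  gold alignment restricted to the newly added concepts.
* **Synthetic scenarios** (`generate_scenario`): seeded evolving-ontology
  benchmarks with a planted gold alignment, so the whole pipeline is
  testable without licensed terminology distributions.

## Worked example

A new MeSH-style concept *Coarctation of Aorta Dominant* appears under
*Aortic Coarctation*, which is already mapped to the ICD-10 branch
*Congenital malformations of great arteries*:

```python
from ontoref import *

source_old = Ontology("mesh-2012", [Concept("MESH:D001017", ("Aortic Coarctation",))])
source_new = Ontology(
    "mesh-2013",
    [Concept("MESH:D001017", ("Aortic Coarctation",)),
     Concept("MESH:D000073", ("Coarctation of Aorta Dominant",))],
    [Relationship("MESH:D000073", "MESH:D001017", "is_a")],
)
target = Ontology(
    "icd10-2011",
    [Concept("ICD10:Q25", ("Congenital malformations of great arteries",)),
     Concept("ICD10:Q25.1", ("Coarctation of aorta",))],
    [Relationship("ICD10:Q25.1", "ICD10:Q25", "is_a")],
)
mappings = MappingSet([Mapping("MESH:D001017", "ICD10:Q25")])
config = RefinementConfig(source_level=1, target_level=1, threshold=0.5)
result = refine_contextual(source_old, source_new, target, mappings, config)
for m in result.mappings:
    print(f"{m.source} {m.sem_type.symbol} {m.target}  conf={m.conf:.3f}")
rec = result.log[0]
print(f"anchors={rec.anchors} candidates={rec.n_candidates}")
```

prints

```
MESH:D000073 ≡ ICD10:Q25.1  conf=0.800
anchors=('MESH:D001017',) candidates=2
```

The mapped parent anchors the search; the two candidates are the anchor's
target and its child; *Coarctation of aorta* wins with bigram-Dice
similarity 0.800 ≥ τ = 0.5, so one equivalence mapping is proposed for
the added concept.

The same pipeline is available from a shell — `ontoref simulate`,
`ontoref diff`, `ontoref refine-context`, `ontoref refine-all`,
`ontoref refine-actions`, `ontoref evaluate` — reading OBO 1.2 or JSON
ontologies and SSSOM TSV mapping sets.

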
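# Methods

## Problem setting

Two releases of a source ontology, O_S^j and O_S^{j+1}, a target ontology
O_T, and a mapping set M established between O_S^j and O_T are given.
Only one change operation between releases is considered: **concept
addition**, detected as an identifier present in the new release and
absent from the old.  Identifiers are assumed permanent across releases
(the LOINC-code convention), so removals, label revisions and concept
moves never masquerade as additions.  Adapting mappings to removals or
revisions is out of scope.

## Model

**Ontology.** Concepts carry an ordered tuple of attribute strings
(preferred label first, synonyms after); relationships are directed typed
triples (child, parent, type).  The hierarchy used for all neighborhood
computations consists of `is_a` edges; `part_of` can be added with
`include_part_of=True` (CLI `--context-edges is_a+part_of`).  The `is_a`
graph must be acyclic; multi-parent DAGs are supported.

**Context.** CT(c, λ) partitions the hierarchical neighborhood of c into
`sup` (ancestors within λ ascending hops), `sub` (descendants within λ),
and `sib` (concepts sharing a direct parent or direct child with c).  λ
bounds the shortest hierarchy distance.  Read literally, that bound
leaves `sib` empty at λ = 1 — a sibling's distance is 2, via the shared
neighbor — while level 1 is the normal operating point and lateral
candidates are wanted there.  Default behaviour therefore admits
siblings whenever λ ≥ 1 (distance bound max(λ, 2)); `strict_siblings=True`
restores the literal bound.  When partitions overlap in a multi-parent
DAG, each neighbor is reported once with precedence sup > sub > sib.

**Similarity.** Strings are normalized by lowercasing and dropping every
character that is not a letter or digit, so bigrams span word boundaries
("Abscess **of** external" contributes "so" and "fe").  `bigram_dice` is
the Dice coefficient over *distinct* bigram sets (multiplicity ignored);
two strings that both normalize to fewer than 2 characters score 0,
since bigram comparison of sub-bigram strings is meaningless.
`levenshtein` is 1 − editDistance/maxLength on the normalized strings
(edit distance via edlib), defined as 1 when both normalize to empty.
Concept similarity is the maximum over all attribute pairs — symmetric,
in [0, 1], and equal to 1 whenever any attribute matches exactly after
normalization.  Custom measures can be registered by name; label
normalization is the hook for cross-language use (e.g. plugging in a
translation-backed measure), which is otherwise out of scope.

## Parameters

| name | meaning | default | why |
|------|---------|---------|-----|
| γ (`source_level`) | hop limit around the added concept when searching for mapped anchors | 1 | direct parents/children are the strongest semantic signal; larger γ admits weaker anchors |
| λ (`target_level`) | hop limit around an anchor's target when collecting candidates | 1 | one hop already captures the parent/child targets that account for most correct refinements |
| τ (`threshold`) | minimum similarity for a proposed mapping | 0.75 | a mid-range operating point balancing precision and recall for bigram Dice |
| σ (`derivation_threshold`) | minimum similarity for deriveS/deriveT | τ | the two thresholds play the same gating role; they decouple when derivation should be stricter or looser than proposal |
| `measure` | registered string measure | `bigram_dice` | context-sensitive and cheap; `levenshtein` fits ID-like labels with shared prefixes |

Both alignment strategies emit at most one mapping per added concept
(the argmax candidate), typed ≡, with the similarity as confidence.  The
threshold comparison is ≥ τ; `strict_gt=True` switches the all-concepts
baseline to a strict >.  Ties at the maximal score go to the
lexicographically smallest target id, and added concepts are processed
in sorted order, so identical inputs and parameters give byte-identical
outputs.

## Refinement actions

`addition_procedure` refines a candidate mapping set (equivalence or
overlap mappings of the current release) using the added-concept list.
For each added concept c_a and each mapping m = (c_a, c_t):

1. the neighborhoods {c_a} ∪ CT(c_a, γ) and {c_t} ∪ CT(c_t, γ) are
   rematched into a similarity matrix (`local_rematch`);
2. **R1** — if the best ancestor p of c_a satisfies
   sim(p, c_t) > sim(c_a, c_t), m is retyped ≤ (the added concept is a
   specialization) and (p, c_t) is derived via deriveS;
3. **R2/R3** — the best ancestor (resp. descendant) q of c_t with
   sim(c_a, q) ≥ sim(c_a, c_t) derives (c_a, q) via deriveT.

Additionally, any mapping m with c_a in CT(source(m), γ) may derive
(c_a, target(m)) — the case of a concept added next to an already-mapped
concept.  Every derivation also requires the defining absolute
condition: the similarity between the original source concept and the
new endpoint must reach σ, and the derived pair must not already be
mapped.  One derivation per rule per mapping (argmax neighbor,
lexicographic tie-break) bounds growth.  Actions never remove mappings,
so the output is a superset of the input; replaying the action log on
the input reproduces the output exactly.

Derived and retyped relations need a direction, which no comparative
similarity test supplies; the hierarchy is the only typed signal
available.  Convention: a new *target* that is an ancestor of the
original target makes the source comparatively narrower (≤), a
descendant broader (≥); symmetrically for new *source* concepts; lateral
neighbors yield ≈.  Confidence is never altered by retyping.

## Evaluation protocol

Proposals are scored only against gold mappings whose source is a newly
added concept (`restrict_to_added`).  A proposal is correct when its
(source, target) pair occurs in the gold set; `strict_type=True` also
compares the semantic relation, for action outputs.  Precision =
correct/identified, recall = correct/gold, F = harmonic mean; all zero
denominators give 0.

## Synthetic scenarios

Real refinement studies run on licensed terminology releases that cannot
be redistributed, so the generator builds seeded stand-ins: random is-a
trees for source and target with labels drawn from a pronounceable
synthetic lexicon (two consonant-vowel-syllable words per label, ≥ 6
characters each — short uniform-random strings would make bigram Dice
uninformative).  A `mapped_fraction` of old source concepts is planted
as true correspondences (equivalence mappings; the source concept gains
its partner's label as a cross-terminology synonym).  Each of `n_added`
new concepts attaches under a mapped parent and is labelled with a noisy
copy — character substitutions at rate `label_noise`, length-preserving,
so the bigram arithmetic stays analyzable — of a gold target drawn from
the partner's neighborhood (the partner itself or one of its children);
the planted pairs form the gold alignment, one distinct target per added
concept.

Defaults (n_source = n_target = 80, branching ≤ 4, n_added = 10,
label_noise = 0.05, one synonym per concept, mapped_fraction = 0.6) give
a mid-sized, mildly noisy scenario in which both alignment strategies
are exercised non-trivially while a full test run stays in seconds;
test-specific sizes are chosen per property (e.g. 40-concept ontologies
where a target-diameter λ is needed).

What the generator does *not* emulate: compositional clinical naming
("...with complication, unspecified"), shared substrings between
unrelated concepts, cross-language labels, removals/merges/moves, and
gold alignments curated under editorial rules rather than lexical
similarity.  Passing the planted-recovery and degradation properties
therefore shows the machinery is correct and well-behaved under
controlled conditions — not that any particular precision/recall level
carries over to real terminology pairs, where results are known to be
strongly dataset-dependent.

## Numerical and degenerate-input choices

* Thresholds compare with ≥ (τ and σ); confidence values are raw
  similarities, never renormalized.
* Empty candidate sets (no mapped anchor in context) emit nothing and
  are logged per added concept; an empty target ontology yields an empty
  result with a warning record.
* `hierarchy_length` is ∞ across disconnected components; context at
  λ = 0 is empty by definition.
* Dice of two sub-2-character normalized strings is 0; Levenshtein of
  two empty normalized strings is 1.
* Duplicate (source, target) pairs, out-of-range confidences, dangling
  relationship endpoints and is_a cycles are rejected at load time.

## Known limitations

* Only concept addition drives refinement; a stale mapping whose source
  was removed or renamed is left untouched.
* The direction-typing convention for derived relations is a heuristic;
  a lateral ≈ may understate a true subsumption the hierarchy does not
  witness.
* Sibling semantics at λ = 1 follow the permissive default; analyses
  that need the literal distance bound must opt into strict mode.
* String similarity is purely lexical: compositional or negated clinical
  labels ("without mention of...") can outscore the semantically correct
  candidate, and no semantic-network measure is provided.
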
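"""Local rematch and the deriveS / deriveT / modSemType refinement actions."""

import pytest

from ontoref import (
    Concept,
    Mapping,
    MappingSet,
    Ontology,
    RefinementConfig,
    Relationship,
    ScenarioParams,
    SemanticRelation,
    ValidationError,
    addition_procedure,
    derive_source,
    derive_target,
    dice_similarity,
    generate_scenario,
    local_rematch,
    modify_semtype,
)


def _oracle_sim(ci, cj):
    return max(dice_similarity(a, b) for a in ci.attributes for b in cj.attributes)


class TestLocalRematch:
    def test_identical_singletons(self):
        matrix = local_rematch(
            [Concept("a", ("heart",))], [Concept("b", ("heart",))],
            dice_similarity,
        )
        assert matrix.values.tolist() == [[1.0]]

    def test_two_by_two_hand_fixture(self):
        s1, s2 = Concept("s1", ("aorta",)), Concept("s2", ("vena cava",))
        t1, t2 = Concept("t1", ("aortic arch",)), Concept("t2", ("vein",))
        matrix = local_rematch([s1, s2], [t1, t2], dice_similarity)
        for concept_s in (s1, s2):
            for concept_t in (t1, t2):
                assert matrix.get(concept_s.id, concept_t.id) == pytest.approx(
                    dice_similarity(concept_s.label, concept_t.label)
                )

    def test_input_order_is_irrelevant(self):
        s1, s2 = Concept("s1", ("aorta",)), Concept("s2", ("vena cava",))
        t1 = Concept("t1", ("aortic arch",))
        a = local_rematch([s1, s2], [t1], dice_similarity)
        b = local_rematch([s2, s1], [t1], dice_similarity)
        assert a.row_ids == b.row_ids and (a.values == b.values).all()

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            local_rematch([], [Concept("t", ("x",))], dice_similarity)


class TestDeriveActions:
    def test_derive_source_below_sigma_is_no_action(self, braf_case):
        _, source_new, target, mappings, _ = braf_case
        config = RefinementConfig(
            derivation_threshold=0.99, measure="levenshtein"
        )
        ms = mappings.copy()
        (m,) = list(ms)
        action = derive_source(
            ms, m, source_new["LN:braf-val"], config, source_new
        )
        assert action is None and ms.equals(mappings)

    def test_derive_source_existing_pair_is_no_action(self, braf_case):
        _, source_new, target, mappings, config = braf_case
        ms = mappings.copy()
        ms.add(Mapping("LN:braf-val", "ES:braf", SemanticRelation.OVERLAPPED, 0.5))
        m = ms.get("LN:braf", "ES:braf")
        assert derive_source(
            ms, m, source_new["LN:braf-val"], config, source_new
        ) is None

    def test_derive_source_same_concept_rejected(self, braf_case):
        _, source_new, _, mappings, config = braf_case
        ms = mappings.copy()
        (m,) = list(ms)
        with pytest.raises(ValidationError):
            derive_source(ms, m, source_new["LN:braf"], config, source_new)

    def test_derive_target_adds_mapping_and_keeps_original(self, zika_case):
        _, source_new, target, mappings, config = zika_case
        ms = mappings.copy()
        (m,) = list(ms)
        action = derive_target(
            ms, m, target["ES:zika"], config, source_new, target
        )
        assert action is not None and action.kind == "deriveT"
        assert ("LN:zika-igg", "ES:zika") in ms
        assert m.pair in ms  # original retained
        # the derived target is an ancestor of the original target
        assert action.mapping.sem_type is SemanticRelation.NARROW_TO_BROAD

    def test_derive_target_below_sigma_and_existing_pair(self, zika_case):
        _, source_new, target, mappings, _ = zika_case
        ms = mappings.copy()
        (m,) = list(ms)
        strict = RefinementConfig(derivation_threshold=0.95, measure="levenshtein")
        assert derive_target(ms, m, target["ES:zika"], strict, source_new, target) is None
        loose = RefinementConfig(derivation_threshold=0.1, measure="levenshtein")
        ms.add(Mapping("LN:zika-igg", "ES:zika", SemanticRelation.OVERLAPPED, 0.3))
        assert derive_target(ms, m, target["ES:zika"], loose, source_new, target) is None


class TestModifySemtype:
    def test_retype_changes_only_the_relation(self):
        m = Mapping("a", "b", SemanticRelation.EQUIVALENT, 0.9)
        action = modify_semtype(m, SemanticRelation.NARROW_TO_BROAD)
        assert m.sem_type is SemanticRelation.NARROW_TO_BROAD
        assert (m.source, m.target, m.conf) == ("a", "b", 0.9)
        assert action.old_type is SemanticRelation.EQUIVALENT

    def test_same_relation_rejected(self):
        m = Mapping("a", "b", SemanticRelation.OVERLAPPED)
        with pytest.raises(ValidationError):
            modify_semtype(m, SemanticRelation.OVERLAPPED)

    def test_unmappable_is_an_allowed_new_relation(self):
        m = Mapping("a", "b", SemanticRelation.EQUIVALENT)
        modify_semtype(m, SemanticRelation.UNMAPPABLE)
        assert m.sem_type is SemanticRelation.UNMAPPABLE


def replay(input_set, actions):
    """Re-apply the action log to the input set; must rebuild the output."""
    current = input_set.copy()
    for action in actions:
        if action.kind in ("deriveS", "deriveT"):
            m = action.mapping
            current.add(Mapping(m.source, m.target, m.sem_type, m.conf))
        elif action.kind == "modSemType":
            live = current.get(action.mapping.source, action.mapping.target)
            live.sem_type = action.mapping.sem_type
    return current


class TestAdditionProcedure:
    def test_zika_addition_derives_the_parent_target(self, zika_case):
        source_old, source_new, target, mappings, config = zika_case
        refined, actions = addition_procedure(
            source_old, source_new, target, mappings, config
        )
        assert ("LN:zika-igg", "ES:zika") in refined
        assert mappings.pairs() <= refined.pairs()
        assert any(a.kind == "deriveT" for a in actions)

    def test_braf_addition_derives_the_shared_target(self, braf_case):
        source_old, source_new, target, mappings, config = braf_case
        refined, actions = addition_procedure(
            source_old, source_new, target, mappings, config
        )
        assert ("LN:braf-val", "ES:braf") in refined
        assert mappings.pairs() <= refined.pairs()
        derive = next(a for a in actions if a.kind == "deriveS")
        # the added concept is a descendant of the mapped source
        assert derive.mapping.sem_type is SemanticRelation.NARROW_TO_BROAD

    def test_no_added_concepts_is_identity(self, braf_case):
        source_old, _, target, mappings, config = braf_case
        refined, actions = addition_procedure(
            source_old, source_old, target, mappings, config
        )
        assert refined.equals(mappings) and actions == []

    def test_target_neighbor_match_triggers_derivation(self):
        # an added source concept mapped to a target whose sibling-free
        # parent matches at least as well derives a second mapping
        source_old = Ontology("v1", [Concept("S:root", ("circulatory disease",))])
        source_new = Ontology(
            "v2",
            [
                Concept("S:root", ("circulatory disease",)),
                Concept("S:angina", ("angina",)),
            ],
            [Relationship("S:angina", "S:root")],
        )
        target = Ontology(
            "t",
            [
                Concept("T:cardiopathy", ("cardiopathy",)),
                Concept("T:angina-pectoris", ("angina pectoris",)),
            ],
            [Relationship("T:angina-pectoris", "T:cardiopathy")],
        )
        mappings = MappingSet(
            [Mapping("S:angina", "T:cardiopathy", SemanticRelation.OVERLAPPED, 0.4)]
        )
        refined, actions = addition_procedure(
            source_old, source_new, target, mappings,
            RefinementConfig(derivation_threshold=0.5, measure="bigram_dice"),
        )
        assert ("S:angina", "T:angina-pectoris") in refined
        assert ("S:angina", "T:cardiopathy") in refined
        derived = refined.get("S:angina", "T:angina-pectoris")
        assert derived.sem_type is SemanticRelation.BROAD_TO_NARROW

    def _scenario_candidate_set(self, scenario):
        combined = scenario.input_mappings.copy()
        for m in scenario.gold:
            combined.add(Mapping(m.source, m.target, m.sem_type, 0.9))
        return combined

    def test_scenario_derivations_satisfy_their_conditions(self):
        scenario = generate_scenario(
            ScenarioParams(seed=21, n_added=5, label_noise=0.1)
        )
        candidate = self._scenario_candidate_set(scenario)
        config = RefinementConfig(derivation_threshold=0.5)
        refined, actions = addition_procedure(
            scenario.source_old, scenario.source_new, scenario.target,
            candidate, config,
        )
        # non-destructive and growing
        assert candidate.pairs() <= refined.pairs()
        assert len(refined) >= len(candidate)
        input_pairs = candidate.pairs()
        for action in actions:
            if action.kind == "modSemType":
                continue
            derived = action.mapping
            assert derived.conf >= config.sigma
            assert derived.pair not in input_pairs
            if action.kind == "deriveS":
                # some input mapping shares the target; the two source
                # concepts must be at least sigma-similar (the trigger)
                partners = [
                    m.source for m in candidate
                    if m.target == derived.target and m.source != derived.source
                ]
                assert any(
                    _oracle_sim(
                        scenario.source_new[s],
                        scenario.source_new[derived.source],
                    ) == pytest.approx(derived.conf)
                    for s in partners
                )
            else:
                assert (derived.source, derived.target) not in input_pairs
                assert _oracle_sim(
                    scenario.source_new[derived.source],
                    scenario.target[derived.target],
                ) == pytest.approx(derived.conf)

    def test_action_log_replays_to_the_output(self):
        scenario = generate_scenario(
            ScenarioParams(seed=33, n_added=6, label_noise=0.1)
        )
        candidate = self._scenario_candidate_set(scenario)
        refined, actions = addition_procedure(
            scenario.source_old, scenario.source_new, scenario.target,
            candidate, RefinementConfig(derivation_threshold=0.4),
        )
        assert replay(candidate, actions).equals(refined)
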
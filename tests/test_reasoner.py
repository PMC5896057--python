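"""Propagation rules, reasoning modes, incremental insertion."""

import random

import pytest

from conftest import ALL_CONFIGS, make_observation
from oracle import oracle_run, state_as_oracle

from pathconsist import (
    ConceptGraph, Observation, ObservationType, PriorKnowledge,
    ReasoningConfig, ReasoningError, UnknownConceptError, case_study,
    insert_observation, run,
)
from pathconsist.reasoner import propagate_expectations
from pathconsist.synth import ScenarioSpec, generate
from pathconsist.truth_values import (
    EMPTY, FALSE_ONLY, TRUE_ONLY, UNKNOWN_ONLY, ConclusionState, Otvs, Tvps,
)

TF = Tvps.of(Otvs.TRUE, Otvs.FALSE)


def build(concepts, relations):
    g = ConceptGraph()
    for entry in concepts:
        g.add_concept(entry if isinstance(entry, PriorKnowledge)
                      else PriorKnowledge(entry))
    for parent, child, kind in relations:
        g.add_relation(parent, child, kind)
    return g


class TestPredictionRules:
    def test_single_concept_one_true_computation(self):
        g = build(["P"], [])
        state = run(g, [make_observation("O1", "P")])
        assert state.predictions["P"] is TRUE_ONLY

    def test_rule1_unions_part_children(self):
        g = build(["P", "A", "B"], [("P", "A", "part"), ("P", "B", "part")])
        state = run(g, [make_observation("O1", "A", present=True),
                        make_observation("O2", "B", present=False)])
        assert state.predictions["P"] is TF

    def test_rule2_keeps_only_best_believed_subtype_children(self):
        g = build(["P", "A", "B"], [("P", "A", "subtype"), ("P", "B", "subtype")])
        state = run(g, [make_observation("O1", "A", present=True),
                        make_observation("O2", "B", present=False)])
        # {{t}} (rank 1) beats {{f}} (rank 16): only A contributes
        assert state.predictions["P"] is TRUE_ONLY

    def test_rule2_rank_ties_all_contribute(self):
        g = build(["P", "A", "B"], [("P", "A", "subtype"), ("P", "B", "subtype")])
        state = run(g, [])
        # both children {{∅}} (rank 14): tie, union
        assert state.predictions["P"] is UNKNOWN_ONLY

    def test_unobserved_leaf_unknown_without_falsehood(self):
        g = build(["P"], [])
        assert run(g, []).predictions["P"] is UNKNOWN_ONLY

    def test_unobserved_leaf_false_with_falsehood(self):
        g = build(["P"], [])
        state = run(g, [], ReasoningConfig(falsehood_mode=True))
        assert state.predictions["P"] is FALSE_ONLY
        assert state.conclusions["P"] is ConclusionState.UNCONFIRMED_ABSENCE

    def test_all_true_leaves_part_only_gives_true_ancestors(self):
        g = build(["R", "M", "L1", "L2"],
                  [("R", "M", "part"), ("M", "L1", "part"), ("M", "L2", "part")])
        state = run(g, [make_observation("O1", "L1"), make_observation("O2", "L2")])
        assert state.predictions["M"] is TRUE_ONLY
        assert state.predictions["R"] is TRUE_ONLY

    def test_direct_otvs_unions_with_children(self):
        g = build(["P", "A"], [("P", "A", "part")])
        state = run(g, [make_observation("O1", "A", present=True),
                        make_observation("O2", "P", present=False)])
        assert state.predictions["P"] is TF


class TestExpectationRules:
    def test_rule3_part_parents_flow_to_all_children(self):
        g = build(["P", "A", "B"], [("P", "A", "part"), ("P", "B", "part")])
        state = run(g, [make_observation(
            "E1", "P", ObservationType.EXPERIMENTATION)])
        assert state.expectations["A"] is TRUE_ONLY
        assert state.expectations["B"] is TRUE_ONLY

    def test_rule4_routes_to_best_predicted_child_only(self):
        g = build(["P", "A", "B"], [("P", "A", "subtype"), ("P", "B", "subtype")])
        state = run(g, [make_observation("E1", "P", ObservationType.EXPERIMENTATION),
                        make_observation("O1", "A", present=True),
                        make_observation("O2", "B", present=False)])
        assert state.expectations["A"] is TRUE_ONLY
        assert state.expectations["B"] is EMPTY

    def test_rule4_false_only_floods_all_children(self):
        g = build(["P", "A", "B"], [("P", "A", "subtype"), ("P", "B", "subtype")])
        state = run(g, [make_observation("E1", "P", ObservationType.EXPERIMENTATION,
                                         present=False),
                        make_observation("O1", "A", present=True),
                        make_observation("O2", "B", present=False)])
        assert Otvs.FALSE in state.expectations["A"].members
        assert Otvs.FALSE in state.expectations["B"].members

    def test_unreached_concepts_keep_empty_expectation(self):
        g = build(["P", "A"], [("P", "A", "part")])
        state = run(g, [])
        assert state.expectations["A"] is EMPTY

    def test_expectations_require_predictions_first(self):
        from pathconsist.reasoner import ReasoningState
        state = ReasoningState(graph=build(["P"], []))
        with pytest.raises(ReasoningError):
            propagate_expectations(state, ReasoningConfig())


class TestModes:
    def test_dispensable_excluded_as_rule1_source(self):
        g = build(["P", PriorKnowledge("A", is_dispensable=True), "B"],
                  [("P", "A", "part"), ("P", "B", "part")])
        obs = [make_observation("O1", "B", present=True)]
        plain = run(g, obs, ReasoningConfig(falsehood_mode=True))
        assert plain.predictions["P"] is TF  # A's falsehood {{f}} counts
        skipping = run(g, obs, ReasoningConfig(falsehood_mode=True,
                                               dispensable_mode=True))
        assert skipping.predictions["P"] is TRUE_ONLY

    def test_dispensable_excluded_as_expectation_target(self):
        g = build(["P", PriorKnowledge("A", is_dispensable=True), "B"],
                  [("P", "A", "part"), ("P", "B", "part")])
        obs = [make_observation("E1", "P", ObservationType.EXPERIMENTATION)]
        state = run(g, obs, ReasoningConfig(dispensable_mode=True))
        assert state.expectations["A"] is EMPTY
        assert state.expectations["B"] is TRUE_ONLY

    def test_dispensable_leaf_not_falsified_by_falsehood_mode(self):
        g = build([PriorKnowledge("A", is_dispensable=True)], [])
        state = run(g, [], ReasoningConfig(falsehood_mode=True,
                                           dispensable_mode=True))
        assert state.predictions["A"] is UNKNOWN_ONLY

    def test_falsehood_never_alters_observed_or_internal_concepts(self):
        g = build(["P", "A", "B"], [("P", "A", "part"), ("P", "B", "part")])
        obs = [make_observation("O1", "A", present=True)]
        state = run(g, obs, ReasoningConfig(falsehood_mode=True))
        assert state.predictions["A"] is TRUE_ONLY  # observed leaf untouched
        assert state.predictions["P"] is TF         # internal = union only

    def test_specific_mode_drops_unknown_siblings(self):
        g = build(["V", "R1", "R2"], [("V", "R1", "part"), ("V", "R2", "part")])
        obs = [make_observation("O1", "R1", present=True)]
        assert run(g, obs).predictions["V"] is Tvps.of(Otvs.TRUE, Otvs.UNKNOWN)
        state = run(g, obs, ReasoningConfig(specific_mode=True))
        assert state.predictions["V"] is TRUE_ONLY

    def test_specific_trigger_requires_specific_child(self):
        # R1 has two part-parents, so it is not specific: no exclusion
        g = build(["V", "W", "R1", "R2"],
                  [("V", "R1", "part"), ("W", "R1", "part"), ("V", "R2", "part")])
        obs = [make_observation("O1", "R1", present=True)]
        state = run(g, obs, ReasoningConfig(specific_mode=True))
        assert state.predictions["V"] is Tvps.of(Otvs.TRUE, Otvs.UNKNOWN)

    def test_specific_exclusion_inert_without_true_specific_child(self):
        # with no prediction observations no child can reach {{t}}, so
        # specific mode must change nothing
        for seed in range(10):
            graph, obs = generate(ScenarioSpec(seed=seed, n_nodes=25,
                                               prediction_density=0.0))
            off = run(graph, obs, ReasoningConfig())
            on = run(graph, obs, ReasoningConfig(specific_mode=True))
            assert state_as_oracle(off) == state_as_oracle(on)


class TestCaseStudies:
    def test_cysteine_narrative(self, cysteine_state):
        s = cysteine_state
        assert s.predictions["GenProp0304"] is FALSE_ONLY
        assert s.predictions["GenProp0218"] is TF
        assert s.conclusions["GenProp0305"] is ConclusionState.CONTRADICTORY_ABSENCE
        assert s.conclusions["Evidence_61339"] is ConclusionState.CONFIRMED_PRESENCE
        assert s.conclusions["Evidence_61340"] is ConclusionState.UNEXPECTED_ABSENCE

    def test_cysteine_expectation_routes_through_best_variant(self, cysteine_state):
        s = cysteine_state
        assert s.expectations["GenProp0218"] is TRUE_ONLY
        assert s.expectations["GenProp0304"] is EMPTY
        assert s.expectations["Evidence_61340"] is TRUE_ONLY

    def test_asparagine_two_variants_all_missing(self, asparagine_two_state):
        s = asparagine_two_state
        for nid in ("UER00194", "UER00195", "VAR00134-1", "VAR00134-2",
                    "UPA00134"):
            assert s.conclusions[nid] is ConclusionState.MISSING

    def test_asparagine_third_variant_selected(self, asparagine_three_state):
        s = asparagine_three_state
        assert s.conclusions["VAR00134-3"] is ConclusionState.CONFIRMED_PRESENCE
        assert s.conclusions["UER01035"] is ConclusionState.MISSING
        assert s.conclusions["UPA00134"] is ConclusionState.CONFIRMED_PRESENCE
        assert s.conclusions["VAR00134-1"] is ConclusionState.UNEXPLAINED


class TestRunBasics:
    def test_no_observations_everything_unexplained(self):
        graph, _ = generate(ScenarioSpec(seed=5, n_nodes=20))
        state = run(graph, [])
        assert all(c is ConclusionState.UNEXPLAINED
                   for c in state.conclusions.values())

    def test_isolated_unobserved_concept_unexplained(self):
        state = run(build(["X"], []), [])
        assert state.conclusions["X"] is ConclusionState.UNEXPLAINED

    def test_deterministic_across_repeats(self):
        for seed in range(8):
            graph, obs = generate(ScenarioSpec(seed=seed, n_nodes=20))
            reference = state_as_oracle(run(graph, obs))
            for _ in range(3):
                assert state_as_oracle(run(graph, obs)) == reference

    def test_duplicate_observation_names_rejected(self):
        g = build(["P"], [])
        obs = [make_observation("O1", "P"), make_observation("O1", "P")]
        with pytest.raises(ReasoningError, match="O1"):
            run(g, obs)

    def test_invalid_graph_rejected(self):
        g = build(["A", "B"], [("A", "B", "part")])
        del g._concepts["B"]
        with pytest.raises(ReasoningError):
            run(g, [])


class TestOracleAgreement:
    @pytest.mark.parametrize("config", ALL_CONFIGS,
                             ids=lambda c: "d%d_f%d_s%d" % (
                                 c.dispensable_mode, c.falsehood_mode,
                                 c.specific_mode))
    def test_matches_naive_fixpoint_on_random_dags(self, config):
        for seed in range(30):
            graph, obs = generate(ScenarioSpec(
                seed=seed, n_nodes=25, contradiction_rate=0.2,
                dispensable_rate=0.15))
            state = run(graph, obs, config)
            expected = oracle_run(graph, obs,
                                  dispensable=config.dispensable_mode,
                                  falsehood=config.falsehood_mode,
                                  specific=config.specific_mode)
            assert state_as_oracle(state) == expected


class TestIncrementalInsertion:
    def test_single_insert_equals_batch(self):
        graph, obs = generate(ScenarioSpec(seed=2, n_nodes=25))
        state = run(graph, obs[:-1])
        insert_observation(state, obs[-1])
        batch = run(graph, obs)
        assert state_as_oracle(state) == state_as_oracle(batch)

    def test_insert_into_empty_state_touches_only_affected_cone(self):
        g = build(["R", "M", "L", "OTHER"],
                  [("R", "M", "part"), ("M", "L", "part")])
        state = run(g, [])
        insert_observation(state, make_observation("O1", "L"))
        report = state.last_insertion
        assert set(report.recomputed_predictions) == {"L", "M", "R"}
        assert "OTHER" not in (set(report.recomputed_predictions)
                               | set(report.recomputed_expectations))
        assert state_as_oracle(state) == state_as_oracle(
            run(g, [make_observation("O1", "L")]))

    def test_redundant_insert_recomputes_nothing(self):
        g = build(["P"], [])
        state = run(g, [make_observation("O1", "P")])
        insert_observation(state, make_observation("O2", "P"))
        assert state.last_insertion.recomputed_total == 0

    def test_unknown_target_rejected(self):
        state = run(build(["P"], []), [])
        with pytest.raises(UnknownConceptError):
            insert_observation(state, make_observation("O1", "NOPE"))

    @pytest.mark.parametrize("config", [ReasoningConfig(),
                                        ReasoningConfig(falsehood_mode=True,
                                                        specific_mode=True)],
                             ids=["plain", "falsehood+specific"])
    def test_confluence_insertion_order_irrelevant(self, config):
        rng = random.Random(99)
        for seed in range(25):
            graph, obs = generate(ScenarioSpec(
                seed=seed, n_nodes=20, contradiction_rate=0.2,
                expectation_density=0.8))
            batch = state_as_oracle(run(graph, obs, config))
            for _ in range(2):
                shuffled = list(obs)
                rng.shuffle(shuffled)
                state = run(graph, [], config)
                for observation in shuffled:
                    insert_observation(state, observation, config)
                assert state_as_oracle(state) == batch
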
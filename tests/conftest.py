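import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from pathconsist import (ConceptGraph, Observation, ObservationType,
                         PriorKnowledge, ReasoningConfig, case_study, run)


@pytest.fixture(scope="session")
def cysteine_state():
    graph, observations, config = case_study("cysteine_kytococcus")
    return run(graph, observations, config)


@pytest.fixture(scope="session")
def asparagine_two_state():
    graph, observations, config = case_study("asparagine_two_variants")
    return run(graph, observations, config)


@pytest.fixture(scope="session")
def asparagine_three_state():
    graph, observations, config = case_study("asparagine_three_variants")
    return run(graph, observations, config)


@pytest.fixture
def chain_graph():
    """A -part-> B -part-> C chain."""
    g = ConceptGraph()
    for cid in "ABC":
        g.add_concept(PriorKnowledge(cid))
    g.add_relation("A", "B", "part")
    g.add_relation("B", "C", "part")
    return g


def make_observation(name, target, obs_type=ObservationType.COMPUTATION,
                     present=True):
    return Observation(name=name, evidence_for=target, obs_type=obs_type,
                       is_present=present)


ALL_CONFIGS = [
    ReasoningConfig(dispensable_mode=d, falsehood_mode=f, specific_mode=s)
    for d in (False, True) for f in (False, True) for s in (False, True)
]
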
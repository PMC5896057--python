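"""Synthetic reasoning scenarios and the bundled case studies.

:func:`generate` builds random pathway-like DAGs with controlled observation
placement (densities, contradictions, dispensable flags) for property
testing: graphs are grown over a fixed node order with edges only from
earlier to later nodes, so acyclicity holds by construction, and everything
is driven by a single seed for reproducibility.

:func:`case_study` loads the two worked biological examples shipped with the
package (generic JSON + observation CSV under ``data/cases/``):

* ``cysteine_kytococcus`` — cysteine biosynthesis in *Kytococcus
  sedentarius*: two pathway variants (tRNA-dependent vs from-serine), one
  protein-family hit, falsehood mode; exposes a contradictory absence.
* ``asparagine_two_variants`` — asparagine biosynthesis in *Acinetobacter
  baylyi* with the two single-reaction variants and no annotation hits,
  specific mode; both reactions come out missing.
* ``asparagine_three_variants`` — the same pathway after adding the
  three-reaction tRNA-dependent transamidation variant with two of its
  reactions annotated; the reasoner selects it and pinpoints the one
  missing reaction.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Tuple

from .graph import ConceptGraph, PriorKnowledge
from .observations import Observation, ObservationType, read_observations
from .reasoner import ReasoningConfig
from .sources import load_generic

CASE_NAMES = ("cysteine_kytococcus", "asparagine_two_variants",
              "asparagine_three_variants")

_CASE_CONFIGS = {
    "cysteine_kytococcus": ReasoningConfig(falsehood_mode=True),
    "asparagine_two_variants": ReasoningConfig(specific_mode=True),
    "asparagine_three_variants": ReasoningConfig(specific_mode=True),
}


class InfeasibleScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one random scenario.

    ``subtype_prob`` is the chance a node's primary parent relation is a
    subtype (variant-like) rather than a part (composition) edge;
    ``extra_part_prob`` the chance of one additional part-parent.
    Observation densities are per eligible concept and per role:
    predictions are placed on leaves, expectations on roots.
    ``contradiction_rate`` is the chance an observed (concept, role) pair
    also receives an opposing claim, yielding a {t,f} group.
    """

    seed: int
    n_nodes: int = 30
    subtype_prob: float = 0.3
    extra_part_prob: float = 0.25
    max_depth: int = 4
    prediction_density: float = 0.7
    expectation_density: float = 0.5
    contradiction_rate: float = 0.1
    dispensable_rate: float = 0.0
    true_bias: float = 0.7  # P(an observation claims presence)

    def __post_init__(self):
        for name in ("subtype_prob", "extra_part_prob", "prediction_density",
                     "expectation_density", "contradiction_rate",
                     "dispensable_rate", "true_bias"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError("%s must lie in [0,1], got %r" % (name, value))
        if self.n_nodes < 0:
            raise ValueError("n_nodes must be non-negative")


def generate(spec: ScenarioSpec) -> Tuple[ConceptGraph, List[Observation]]:
    """Build a random concept DAG and its observation list, deterministically.

    Node 0 is always a root; each later node attaches to one earlier node
    (kept within the depth bound) and optionally to a second part-parent.
    Leaves draw Computation observations, roots draw Experimentation
    observations; contradictions add an opposing row for the same target.
    """
    if spec.n_nodes > 0 and spec.max_depth < 1:
        raise InfeasibleScenarioError("max_depth must be >= 1 for any node")
    if (spec.n_nodes > 1 and spec.max_depth < 2
            and (spec.subtype_prob > 0 or spec.extra_part_prob > 0)):
        raise InfeasibleScenarioError(
            "max_depth < 2 leaves no room for the requested edges")

    rng = random.Random(spec.seed)
    graph = ConceptGraph()
    width = max(3, len(str(max(spec.n_nodes - 1, 0))))
    ids = ["C%0*d" % (width, i) for i in range(spec.n_nodes)]
    depth: Dict[str, int] = {}

    for i, nid in enumerate(ids):
        graph.add_concept(PriorKnowledge(nid))
        if i == 0:
            depth[nid] = 0
            continue
        candidates = [p for p in ids[:i] if depth[p] < spec.max_depth - 1]
        if not candidates:
            depth[nid] = 0  # another root
            continue
        primary = rng.choice(candidates)
        kind = "subtype" if rng.random() < spec.subtype_prob else "part"
        graph.add_relation(primary, nid, kind)
        depth[nid] = depth[primary] + 1
        others = [p for p in candidates if p != primary]
        if others and rng.random() < spec.extra_part_prob:
            second = rng.choice(others)
            graph.add_relation(second, nid, "part")
            depth[nid] = max(depth[nid], depth[second] + 1)

    # category tags (advisory): roots are pathways, leaves functional units
    rebuilt = ConceptGraph()
    roots, leaves = set(graph.roots()), set(graph.leaves())
    for nid in ids:
        if nid in roots:
            category = "pathway" if nid not in leaves else "other"
        elif nid in leaves:
            category = "functional-unit"
        else:
            category = "component"
        dispensable = (nid not in roots and rng.random() < spec.dispensable_rate)
        rebuilt.add_concept(PriorKnowledge(nid, category=category,
                                           is_dispensable=dispensable))
    for rel in graph.relations():
        rebuilt.add_relation(rel.parent, rel.child, rel.kind)
    graph = rebuilt

    observations: List[Observation] = []

    def place(nid: str, obs_type: ObservationType, tag: str) -> None:
        claim = rng.random() < spec.true_bias
        observations.append(Observation(
            name="%s_%s" % (tag, nid), evidence_for=nid, obs_type=obs_type,
            is_present=claim, source="synthetic"))
        if rng.random() < spec.contradiction_rate:
            observations.append(Observation(
                name="%s_%s_contra" % (tag, nid), evidence_for=nid,
                obs_type=obs_type, is_present=not claim, source="synthetic"))

    for nid in sorted(leaves):
        if rng.random() < spec.prediction_density:
            place(nid, ObservationType.COMPUTATION, "Comp")
    for nid in sorted(roots):
        if rng.random() < spec.expectation_density:
            place(nid, ObservationType.EXPERIMENTATION, "Exp")
    return graph, observations


def case_study(name: str) -> Tuple[ConceptGraph, List[Observation],
                                   ReasoningConfig]:
    """Load one of the bundled case studies (graph, observations, config)."""
    if name not in CASE_NAMES:
        raise KeyError("unknown case study %r (available: %s)"
                       % (name, ", ".join(CASE_NAMES)))
    base = resources.files("pathconsist").joinpath("data", "cases")
    with resources.as_file(base.joinpath(name + ".graph.json")) as path:
        graph = load_generic(path)
    with resources.as_file(base.joinpath(name + ".observations.csv")) as path:
        observations = read_observations(path)
    return graph, observations, _CASE_CONFIGS[name]
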
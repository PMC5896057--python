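"""The propagation engine: rules, reasoning modes and incremental updates.

Reasoning runs in three steps over a validated concept DAG:

1. **Prediction propagation** (leaves → roots).  A concept's prediction is
   the union of (a) its own grouped prediction observations, (b) the
   predictions of its part-children (Rule 1: a composition is present to the
   extent its parts are), and (c) the predictions of the best-believed
   subtype-children (Rule 2: a generalization is present through its most
   credible variant; all rank-tied variants contribute).  Leaves with no
   direct prediction observation get ``{{∅}}`` — or ``{{f}}`` in falsehood
   mode, which assumes every leaf is detectable so silence means absence.

2. **Expectation propagation** (roots → leaves).  A concept's expectation is
   the union of (a) its own grouped expectation observations, (b) every
   part-parent's expectation (Rule 3: if a whole is expected, so are its
   parts), and (c) each subtype-parent's expectation when this child has the
   best prediction belief rank among that parent's subtype-children, rank
   ties included — except that a false-only parent expectation ``{{f}}``
   flows to *all* subtype-children (Rule 4: if a pathway is absent, every
   variant is).

3. **Conclusion assignment.**  Each concept's expectation and prediction are
   approximated to TRUE/FALSE/BOTH/NONE and crossed into one of the 16
   conclusion states.

Three optional modes alter the rules:

* *dispensable* — concepts flagged non-essential neither feed Rule 1 nor
  receive expectations; their own subtree is still evaluated locally.
* *falsehood* — unobserved leaves are assumed false-predicted, so missing
  annotations surface as contradictions at pathway level.
* *specific* — in Rule 1, unknown ``{{∅}}`` children are ignored when a
  sibling that is *specific* (exactly one part-parent) is predicted
  true-only ``{{t}}``: partial evidence on a variant's own reactions is
  enough to call the variant predicted.

Observations may also be inserted one at a time into a finished state; only
the affected region of the graph is recomputed, and the result is guaranteed
to equal a batch run on the full observation list (confluence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

from .graph import ConceptGraph, GraphError, UnknownConceptError
from .observations import Observation, group_to_otvs
from .truth_values import (
    EMPTY, FALSE_ONLY, TRUE_ONLY, UNKNOWN_ONLY,
    Approx, ConclusionState, Otvs, Role, Tvps, conclude, otvs_of, union,
)

# Rule-1 specific-mode trigger: when True (default), only a true-only child
# that is itself specific (single part-parent) licenses dropping unknown
# siblings; set False to let any true-only child do so.
SPECIFIC_TRIGGER_REQUIRES_SPECIFIC_CHILD = True


@dataclass(frozen=True)
class ReasoningConfig:
    """Mode flags; all eight combinations are legal."""

    dispensable_mode: bool = False
    falsehood_mode: bool = False
    specific_mode: bool = False


@dataclass
class InsertionReport:
    """What an incremental insertion actually touched."""

    recomputed_predictions: List[str] = field(default_factory=list)
    recomputed_expectations: List[str] = field(default_factory=list)
    changed_conclusions: List[str] = field(default_factory=list)

    @property
    def recomputed_total(self) -> int:
        return len(set(self.recomputed_predictions)
                   | set(self.recomputed_expectations))


@dataclass
class ReasoningState:
    """A concept graph plus the reasoner's working memory over it."""

    graph: ConceptGraph
    observations: List[Observation] = field(default_factory=list)
    direct_otvs: Dict[Tuple[str, Role], Otvs] = field(default_factory=dict)
    predictions: Dict[str, Tvps] = field(default_factory=dict)
    expectations: Dict[str, Tvps] = field(default_factory=dict)
    conclusions: Dict[str, ConclusionState] = field(default_factory=dict)
    # raw truth claims per (concept, role); kept so insertions can regroup
    claims: Dict[Tuple[str, Role], List[bool]] = field(default_factory=dict)
    last_insertion: Optional[InsertionReport] = None
    predictions_done: bool = False

    def initialize(self) -> None:
        for nid in self.graph.identifiers():
            self.predictions[nid] = EMPTY
            self.expectations[nid] = EMPTY


class ReasoningError(RuntimeError):
    pass


def _is_skipped_dispensable(graph: ConceptGraph, nid: str,
                            config: ReasoningConfig) -> bool:
    return config.dispensable_mode and graph.concept(nid).is_dispensable


def _node_prediction(state: ReasoningState, nid: str,
                     config: ReasoningConfig) -> Tvps:
    """The rule equation for one concept's prediction, given its children."""
    graph = state.graph
    direct = state.direct_otvs.get((nid, Role.PREDICTION))
    part_children = graph.children(nid, "part")
    subtype_children = graph.children(nid, "subtype")

    if not part_children and not subtype_children:
        if direct is not None:
            return Tvps.of(direct)
        if config.falsehood_mode and not _is_skipped_dispensable(graph, nid, config):
            return FALSE_ONLY
        return UNKNOWN_ONLY

    members: Set[Otvs] = set()
    if direct is not None:
        members.add(direct)

    # Rule 1: part-children (dispensable ones skipped in dispensable mode)
    parts = [c for c in part_children
             if not _is_skipped_dispensable(graph, c, config)]
    if config.specific_mode and parts:
        trigger = any(
            state.predictions[c] is TRUE_ONLY
            and (graph.is_specific(c)
                 or not SPECIFIC_TRIGGER_REQUIRES_SPECIFIC_CHILD)
            for c in parts)
        if trigger:
            parts = [c for c in parts
                     if state.predictions[c] is not UNKNOWN_ONLY]
    for c in parts:
        members |= state.predictions[c].members

    # Rule 2: best-believed subtype-children (all rank ties contribute)
    if subtype_children:
        best = min(state.predictions[c].belief_rank for c in subtype_children)
        for c in subtype_children:
            if state.predictions[c].belief_rank == best:
                members |= state.predictions[c].members

    return Tvps.of(members)


def _node_expectation(state: ReasoningState, nid: str,
                      config: ReasoningConfig) -> Tvps:
    """The rule equation for one concept's expectation, given its parents."""
    graph = state.graph
    members: Set[Otvs] = set()
    direct = state.direct_otvs.get((nid, Role.EXPECTATION))
    if direct is not None:
        members.add(direct)

    if not _is_skipped_dispensable(graph, nid, config):
        # Rule 3: every part-parent's expectation flows down
        for p in graph.parents(nid, "part"):
            members |= state.expectations[p].members
        # Rule 4: subtype-parents route to best-predicted children,
        # except {{f}} which floods all children
        for p in graph.parents(nid, "subtype"):
            parent_exp = state.expectations[p]
            if parent_exp is EMPTY:
                continue
            if parent_exp is FALSE_ONLY:
                members |= parent_exp.members
                continue
            siblings = [c for c in graph.children(p, "subtype")
                        if not _is_skipped_dispensable(graph, c, config)]
            if not siblings:
                continue
            best = min(state.predictions[c].belief_rank for c in siblings)
            if state.predictions[nid].belief_rank == best:
                members |= parent_exp.members

    return Tvps.of(members)


def _require_valid(graph: ConceptGraph) -> None:
    violations = graph.validate()
    if violations:
        raise ReasoningError(
            "graph failed validation: " + "; ".join(violations))


def propagate_predictions(state: ReasoningState,
                          config: ReasoningConfig) -> ReasoningState:
    """Single leaf-to-root pass applying Rules 1–2 (plus mode adjustments)."""
    _require_valid(state.graph)
    for nid in state.graph.topological_order("leaf-to-root"):
        state.predictions[nid] = _node_prediction(state, nid, config)
    state.predictions_done = True
    return state


def propagate_expectations(state: ReasoningState,
                           config: ReasoningConfig) -> ReasoningState:
    """Single root-to-leaf pass applying Rules 3–4 (plus mode adjustments)."""
    if not state.predictions_done:
        raise ReasoningError("predictions must be propagated first")
    for nid in state.graph.topological_order("root-to-leaf"):
        state.expectations[nid] = _node_expectation(state, nid, config)
    return state


def assign_conclusions(state: ReasoningState) -> ReasoningState:
    for nid in state.graph.identifiers():
        state.conclusions[nid] = conclude(
            state.expectations[nid].approximate(Role.EXPECTATION),
            state.predictions[nid].approximate(Role.PREDICTION))
    return state


def run(graph: ConceptGraph, observations: Iterable[Observation],
        config: ReasoningConfig = ReasoningConfig()) -> ReasoningState:
    """Batch evaluation: group → predictions → expectations → conclusions.

    Deterministic for fixed inputs: iteration follows sorted identifiers.
    """
    _require_valid(graph)
    state = ReasoningState(graph=graph)
    state.initialize()
    names: Set[str] = set()
    for obs in observations:
        if obs.name in names:
            raise ReasoningError("duplicate observation name %r" % (obs.name,))
        names.add(obs.name)
        state.observations.append(obs)
        if obs.evidence_for in graph:
            for role in obs.roles:
                state.claims.setdefault(
                    (obs.evidence_for, role), []).append(obs.is_present)
    state.direct_otvs = group_to_otvs(state.observations, graph)
    propagate_predictions(state, config)
    propagate_expectations(state, config)
    assign_conclusions(state)
    return state


def insert_observation(state: ReasoningState, observation: Observation,
                       config: ReasoningConfig = ReasoningConfig()
                       ) -> ReasoningState:
    """Insert one observation into a finished state, recomputing locally.

    Only the target's prediction ancestors and the expectation cone of every
    concept whose value changed are revisited; the final state equals
    :func:`run` on the extended observation list regardless of insertion
    order (confluence).  ``state.last_insertion`` records what was touched.
    """
    graph = state.graph
    if observation.evidence_for not in graph:
        raise UnknownConceptError(
            "unknown concept %r" % (observation.evidence_for,))
    if any(o.name == observation.name for o in state.observations):
        raise ReasoningError(
            "duplicate observation name %r" % (observation.name,))

    report = InsertionReport()
    state.last_insertion = report
    state.observations.append(observation)

    target = observation.evidence_for
    changed_roles: List[Role] = []
    for role in observation.roles:
        key = (target, role)
        state.claims.setdefault(key, []).append(observation.is_present)
        new_otvs = otvs_of(state.claims[key])
        if state.direct_otvs.get(key) is not new_otvs:
            state.direct_otvs[key] = new_otvs
            changed_roles.append(role)
    if not changed_roles:
        return state  # grouped value unchanged: nothing to recompute

    # --- prediction pass over the target's ancestor cone -----------------
    pred_changed: Set[str] = set()
    if Role.PREDICTION in changed_roles:
        worklist: Set[str] = {target}
        for nid in graph.topological_order("leaf-to-root"):
            if nid not in worklist:
                continue
            report.recomputed_predictions.append(nid)
            new = _node_prediction(state, nid, config)
            if new is not state.predictions[nid]:
                state.predictions[nid] = new
                pred_changed.add(nid)
                worklist.update(graph.parents(nid))

    # --- expectation pass over the affected cone --------------------------
    seeds: Set[str] = set()
    if Role.EXPECTATION in changed_roles:
        seeds.add(target)
    for nid in pred_changed:
        # a prediction change can reroute Rule 4 at every subtype-parent:
        # the node itself and all its subtype-siblings must be revisited
        seeds.add(nid)
        for p in graph.parents(nid, "subtype"):
            seeds.update(graph.children(p, "subtype"))

    exp_changed: Set[str] = set()
    if seeds:
        worklist = set(seeds)
        for nid in graph.topological_order("root-to-leaf"):
            if nid not in worklist:
                continue
            report.recomputed_expectations.append(nid)
            new = _node_expectation(state, nid, config)
            if new is not state.expectations[nid]:
                state.expectations[nid] = new
                exp_changed.add(nid)
                worklist.update(graph.children(nid))

    for nid in sorted(pred_changed | exp_changed):
        new_conclusion = conclude(
            state.expectations[nid].approximate(Role.EXPECTATION),
            state.predictions[nid].approximate(Role.PREDICTION))
        if state.conclusions.get(nid) is not new_conclusion:
            state.conclusions[nid] = new_conclusion
            report.changed_conclusions.append(nid)
    return state


def conclusion_counts(state: ReasoningState) -> Dict[ConclusionState, int]:
    """How many concepts ended in each conclusion state."""
    counts: Dict[ConclusionState, int] = {s: 0 for s in ConclusionState}
    for c in state.conclusions.values():
        counts[c] += 1
    return counts
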
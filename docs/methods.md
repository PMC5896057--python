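# Methods

## Knowledge representation

Biological processes are modelled as a directed acyclic graph of
prior-knowledge concepts. Two edge kinds carry all structure: `part`
(composition — a pathway has reactions, a component belongs to a variant)
and `subtype` (generalization — a pathway has variants, a function has
alternative protein families). Edges are stored parent → child; acyclicity
is enforced at insertion time, so the reasoner can always assume a DAG and
propagate in one topological pass per direction. A node may mix part- and
subtype-children; each group is handled by its own rule and the results are
unioned. At most one relation is allowed per ordered pair: a pair related
both by composition and specialization would be a modelling error.

Concepts carry advisory `category` tags (pathway, variant, component,
functional-unit, other) used only to group report statistics, a
`dispensable` flag (non-essential component), and a derived *specific*
property: a concept is specific iff it has exactly one part-parent. Being
derived, specificity is recomputed from the edges on demand and cannot go
stale under mutation.

## The sixteen-valued logic

Grouped observations for one concept and role form an Otvs: `{t}`, `{f}`,
`{t,f}` or `{∅}`, with truth degrees 1, 0, ½, 0 and falsehood degrees
0, 1, ½, 0. Propagation accumulates Otvs into subsets of these four states
(16 possible values). For a set S, the truth (falsehood) degree is the sum
of member degrees divided by |S|, and the information degree is |S|; the
empty set has all degrees zero. Belief ranks 1–16 order the values by
decreasing truth degree, then increasing falsehood degree, then increasing
information degree. All degree arithmetic uses `fractions.Fraction`:
adjacent ranks are separated by differences as small as 1/6 and must not be
blurred by floating point. The 16 values are interned singletons, so
equality is identity and rank lookups are O(1).

The empty powerset `∅` and the singleton `{{∅}}` are distinct values
(ranks 13 and 14). Operationally, `∅` is the initial value of every
concept's prediction and expectation and survives only where propagation
delivers nothing; `{{∅}}` arises at observation-less leaves during
prediction propagation. A concept's own observations contribute to the rule
unions only when at least one observation exists — absence contributes
nothing rather than injecting `{∅}` everywhere, which is what lets fully
annotated pathways reach a pure `{{t}}` and conclude Confirmed Presence.

Approximation to TRUE/FALSE/BOTH/NONE differs by role. Both roles return
BOTH whenever true and false are both present anywhere in the set. For
predictions, an `{∅}` member (or the empty set) dominates otherwise:
some part of the concept is unknown, so the approximation is NONE. For
expectations, unknown members are ignored — they reflect missing
information about sibling branches, not a missing part — so `{{∅},{t}}`
approximates TRUE and `{{∅},{f}}` FALSE. The conclusion is an exact 4×4
lookup on (approximated expectation, approximated prediction) yielding the
16 named states.

## Propagation

Predictions propagate leaves → roots in a single pass over a deterministic
(lexicographic) topological order:

* a leaf takes its direct prediction Otvs; with no observation it takes
  `{{∅}}`, or `{{f}}` in falsehood mode;
* an internal node unions its direct prediction Otvs (if any), its
  part-children's predictions (Rule 1), and the predictions of the
  subtype-children attaining the minimal belief rank (Rule 2; all tied
  children contribute — with no subtype-children the term is absent, and
  when all subtype-children are unknown the rank-14 tie includes them all).

Expectations propagate roots → leaves: each node unions its direct
expectation Otvs, every part-parent's expectation (Rule 3), and, per
subtype-parent, that parent's expectation if the node attains the minimal
prediction belief rank among the parent's subtype-children (ties: all
receive it) or if the parent's expectation is exactly `{{f}}`, which floods
all children (Rule 4). Best-belief selection is re-evaluated at every
parent→child step of a subtype chain. Nodes reached by nothing keep `∅`.

### Modes

* **Dispensable** — a dispensable concept is excluded as a *source* in
  Rule 1 and as a *target* in Rules 3–4 (including the Rule-4 rank
  competition); its own subtree is still evaluated locally, so it receives
  a conclusion without dragging the parent into Missing/Contradictory
  states. Falsehood mode does not falsify a dispensable leaf: it stands
  outside propagation. Flags are inert unless the mode is on.
* **Falsehood** — only leaves without direct prediction observations are
  touched; observed leaves and internal nodes are never altered.
* **Specific** — in Rule 1, children predicted exactly `{{∅}}` are dropped
  from the union when at least one sibling that is specific is predicted
  exactly `{{t}}`. Requiring the triggering child to be specific is the
  package's reading of variant selection ("one specific reaction
  suffices"); the alternative trigger (any true-only child) can be enabled
  via the internal constant
  `reasoner.SPECIFIC_TRIGGER_REQUIRES_SPECIFIC_CHILD` for experimentation.
  Falsehood assignment happens before specific-mode filtering, so a
  falsified leaf is a `{{f}}` (never an excludable `{{∅}}`) sibling.

Dispensable and specific flags are stored independently; no interaction
between them is assumed.

## Incremental insertion

`insert_observation` updates a finished state without full re-evaluation:
the target's (concept, role) group is re-derived from the accumulated
claims; if it changed, predictions are recomputed along the target's
ancestor cone (stopping where a value is unchanged), then expectations over
the affected cone — seeded by the target (for expectation-role changes) and
by every prediction-changed node together with all subtype-siblings of such
nodes, since a prediction change can re-route Rule 4 at their shared
parents — and finally conclusions for every node whose value moved. Because
each local recomputation applies the same rule equations used by the batch
pass, the incremental result equals the batch result for any insertion
order; this confluence is exercised over hundreds of randomized scenarios
and mode combinations in the test suite, alongside an independent
naive-fixpoint oracle that recomputes every node until stable.

A note on monotonicity: a concept's *grouped claims* only widen as
observations accumulate ({t} can become {t,f} but never shrink), and that
is the level at which information grows monotonically. Propagated sets are
not monotone in general — a newly observed leaf replaces its `{{∅}}` by
`{{t}}`, which can *shrink* an ancestor's union or re-select Rule 2's
best-believed child — so no graph-level monotone-information property is
claimed or tested.

## Evaluation statistics

Only concepts with univocal expectations (exactly `{{t}}` or `{{f}}`) are
classified: TP = Confirmed Presence; TN = Confirmed Absence, Absent;
FP = Unexpected Presence, Contradictory Presence; FN = Missing, Unexpected
Absence, Contradictory Absence. A univocal expectation forces the
conclusion into these eight states; the classifier asserts this rather than
silently skipping. Accuracy = (TP+TN)/total, precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 = 2PR/(P+R) ≡ 2TP/(2TP+FP+FN), all as exact
rationals; any 0/0 is reported as *undefined*, distinct from 0. Percent
rendering rounds half-up to two decimals.

## Synthetic scenarios

The generator (`synth.generate`) emulates pathway/variant/functional-unit
hierarchies: nodes are laid down in a fixed order and each non-root
attaches to one earlier node — a subtype edge with probability
`subtype_prob` (default 0.3), else part — plus an optional second
part-parent (`extra_part_prob`, default 0.25), within a depth bound
(default 4, matching a pathway → variant → component → functional-unit
layering). Acyclicity holds by construction. Computation observations land
on leaves (density 0.7), Experimentation observations on roots (density
0.5), claims are true with probability 0.7, and an observed pair gains an
opposing claim with probability `contradiction_rate` (default 0.1,
emulating ambiguous growth-phenotype discretizations encoded as a true+
false pair). All draws come from one seeded generator, so scenarios are
exactly reproducible.

What this does *not* emulate: real ontology topologies (shared components
across many pathways, deep subtype chains), realistic observation biases
(annotation quality varying by family), or organism-level correlation
between prediction and expectation — synthetic predictions and expectations
are independent, so synthetic confusion statistics say nothing about real
annotation accuracy. Passing property tests therefore demonstrate engine
correctness (rule semantics, confluence, determinism), not biological
performance. The two bundled case studies are minimal hand-built topologies
consistent with their published narratives, labelled with the real concept
identifiers; the cysteine case includes the intermediate component layer
(property → component → evidence), the asparagine case links variants
directly to reactions.

## Numerical and design choices

* Exact rationals everywhere degrees or metrics are computed; no tolerances
  are needed anywhere in the engine.
* Deterministic iteration (sorted identifiers, lexicographic topological
  order) makes every report byte-stable across runs.
* Rule 2/4 ties include *all* children at the minimal rank — required for a
  pathway with two equally unknown variants to flag both as missing.
* Degenerate inputs: an empty graph is legal everywhere (header-only
  reports); an internal node whose rule terms all vanish (e.g. all
  part-children dispensable under dispensable mode) keeps `∅` and concludes
  in the Unconfirmed/Unexplained row.
* Observation names are unique; re-inserting a claim that does not change
  the grouped Otvs recomputes nothing.
* Reports render sets canonically (elements ordered t < f < t,f < ∅;
  empty set as `∅`) so CSV outputs can be compared bit-for-bit.

## Problem sizes used in tests

The acceptance-level property suite runs 500 randomized confluence
scenarios and 125 random DAGs × 8 mode combinations (1000 engine/oracle
comparisons) at 5–25 nodes, plus the exhaustive 16³ union-law check;
module tests use smaller counts. These sizes give full coverage of the
rule interactions while keeping the whole suite fast.

## Known limitations

* Observation retraction is not supported (insertion only).
* Quantitative evidence (scores, optical densities) must be discretized to
  true/false upstream.
* Only `part` and `subtype` semantics exist; processes needing regulatory
  ("avoid"-style) relations cannot be expressed.
* The OBO loader handles a term/is_a/relationship/is_obsolete subset and
  does not synthesize variant concepts from shared pathway inputs/outputs;
  variants must be declared explicitly in the generic format.
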
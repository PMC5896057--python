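# pathconsist

Paraconsistent reasoning over biological-process graphs to evaluate the
**completeness and consistency of genome functional annotations**.

Genome annotation pipelines predict protein functions one sequence at a
time; whether those predictions add up to working metabolic pathways — and
whether they agree with what is known about the organism, such as growth
phenotypes or prototrophy — is a separate question. `pathconsist` answers it
by modelling biological processes as a hierarchical concept graph and
confronting, for every pathway, variant, component and functional unit, what
is *predicted* in the annotation with what is *expected* in the organism.
It is aimed at biocurators and annotation-pipeline developers who want a
ranked list of confirmed, missing and contradictory process components
rather than a flat presence/absence call.

## The model

Concepts are linked by `part` relations (composition: a pathway has
reactions) and `subtype` relations (specialization: a pathway has variants).
Evidence comes as observations typed `Computation` (feeds the concept's
**prediction**), `Experimentation` (feeds its **expectation**) or `Curation`
(feeds both), each asserting (`true`) or rejecting (`false`) a concept.

Observations for one concept and role are grouped into an observation truth
value set Otvs ∈ { {t}, {f}, {t,f}, {∅} }. Propagation accumulates these, so
each concept's prediction and expectation is a *subset of the four Otvs
states* — one of 16 values with exact truth, falsehood and information
degrees (a construction related to the trilattice SIXTEEN₃ of generalized
truth values). Contradictions are first-class citizens instead of errors:
the logic is paraconsistent. A total **belief rank** (1–16) orders the 16
values by decreasing truth, then increasing falsehood and information.

Four rules propagate evidence over the DAG:

1. predictions flow leaves → roots through `part` edges by union;
2. through `subtype` edges only the best-believed children contribute;
3. expectations flow roots → leaves through `part` edges by union;
4. through `subtype` edges expectations route to the best-predicted
   children — except false-only expectations, which reach every variant.

Finally each concept's prediction and expectation are approximated to
TRUE/FALSE/BOTH/NONE and crossed into one of 16 conclusion states
(Confirmed Presence, Missing, Contradictory Absence, Ambiguous, ...).
Three optional modes refine the reasoning: *dispensable* (non-essential
components stay out of propagation), *falsehood* (unannotated leaves count
as false predictions, surfacing contradictions at pathway level) and
*specific* (partial evidence on a variant's own reactions suffices to call
the variant). Observations can also be inserted one at a time into a
finished state; only the affected region is recomputed and the result
provably equals a batch run.

Against expectations that are univocally true or false, conclusions map to a
confusion matrix (TP = Confirmed Presence; TN = Confirmed Absence, Absent;
FP = Unexpected/Contradictory Presence; FN = Missing, Unexpected/
Contradictory Absence) from which accuracy, precision, recall and F1 are
computed with exact rational arithmetic.

## Worked example

`examples/cysteine_contradiction.py` evaluates cysteine biosynthesis in
*Kytococcus sedentarius* (two variants, one protein-family hit, pathway
expected from prototrophy) under falsehood mode:

```
concept                  prediction   expectation  conclusion
Component_CysSynthase    {{t}}        {{t}}        Confirmed Presence
Component_SerAcetyl      {{f}}        {{t}}        Unexpected Absence
Evidence_61339           {{t}}        {{t}}        Confirmed Presence
Evidence_61340           {{f}}        {{t}}        Unexpected Absence
GenProp0218              {{t},{f}}    {{t}}        Contradictory Absence
GenProp0304              {{f}}        ∅            Unconfirmed Absence
GenProp0305              {{t},{f}}    {{t}}        Contradictory Absence
```

Reading it: the from-serine variant GenProp0218 unions a true and a false
prediction from its two components, so its prediction `{{t},{f}}`
approximates to BOTH; the pathway is expected (`{{t}}`) and therefore
concludes **Contradictory Absence** — it should be there but its evidence
disagrees with itself. The expectation routes through GenProp0218 (belief
rank 6 beats the false-only variant's rank 16), turning the unmatched
protein family Evidence_61340 into an **Unexpected Absence**: the exact spot
where curation effort should go. The other examples show specific-mode
pathway-variant selection (`variant_selection.py`) and batch-vs-incremental
equivalence plus confusion statistics on random scenarios
(`synthetic_benchmark.py`).

A thin CLI wraps the same pipeline:

```sh
pathconsist reason --graph graph.json --observations obs.csv \
    --falsehood --out results/ --dot-root GenProp0305
pathconsist synth --seed 1 --nodes 30 --out scenario/
```

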
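"""Specific-mode variant selection for asparagine biosynthesis.

With only two empty single-reaction variants the reasoner cannot choose:
everything is "Missing".  After adding the three-reaction tRNA-dependent
transamidation variant, two of whose reactions are annotated, specific mode
lets the partial evidence carry the variant: it is confirmed and the one
unannotated reaction is pinpointed as the gap to close.
"""

from pathconsist import case_study, run

for name in ("asparagine_two_variants", "asparagine_three_variants"):
    graph, observations, config = case_study(name)
    state = run(graph, observations, config)
    print(f"== {name} (specific mode)")
    for nid in graph.identifiers():
        print(f"  {nid:12} {state.conclusions[nid].value}")
    print()

# First run: UPA00134, both variants and both reactions are Missing —
# the expectation reaches everything, no prediction supports anything.
# Second run: VAR00134-3 and UPA00134 are Confirmed Presence; only
# UER01035 (the GatABC transamidation step) remains Missing.
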
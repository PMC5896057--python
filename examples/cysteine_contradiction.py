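"""Detecting a contradictory pathway with falsehood-mode reasoning.

Cysteine biosynthesis in *Kytococcus sedentarius*: the pathway is expected
(the organism is a cysteine prototroph) and has two variants.  Only one
protein-family model hit exists, so under falsehood mode — unannotated
functional units count as false predictions — the from-serine variant mixes
true and false evidence and the pathway is flagged contradictory, while the
unmatched family comes out as an unexpected absence worth curating.
"""

from pathconsist import case_study, run
from pathconsist.truth_values import Role

graph, observations, config = case_study("cysteine_kytococcus")
state = run(graph, observations, config)

print(f"{'concept':24} {'prediction':12} {'expectation':12} conclusion")
for nid in graph.identifiers():
    pred = state.predictions[nid]
    exp = state.expectations[nid]
    print(f"{nid:24} {pred.render():12} {exp.render():12} "
          f"{state.conclusions[nid].value}")

# The {{t},{f}} prediction on GenProp0305/GenProp0218 approximates to BOTH:
# with a TRUE expectation this concludes "Contradictory Absence" — the
# pathway should be there, but its evidence disagrees with itself.
# "Unexpected Absence" on Evidence_61340 points at the protein family to
# re-examine (a near-threshold model hit, in the original analysis).
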
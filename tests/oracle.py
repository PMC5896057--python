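"""Independent naive-fixpoint evaluator used as a test oracle.

Deliberately shares no code with the package's engine: truth value
powersets are plain frozensets of the strings ``t``, ``f``, ``tf``, ``u``;
the belief ranking is a hardcoded transcription of the printed 16-row
table rather than a computed sort; and propagation repeatedly sweeps *all*
nodes applying the rule equations until nothing changes, instead of a
single ordered pass.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, List, Tuple

fs = frozenset

# belief ranks transcribed from the printed table (1 = most believed)
RANK = {
    fs(): 13, fs("u"): 14, fs("f"): 16, fs("t"): 1, fs(["tf"]): 5,
    fs(["u", "f"]): 15, fs(["u", "t"]): 3, fs(["u", "tf"]): 10,
    fs(["f", "t"]): 6, fs(["f", "tf"]): 11, fs(["t", "tf"]): 2,
    fs(["f", "t", "tf"]): 7, fs(["u", "f", "t"]): 9,
    fs(["u", "f", "tf"]): 12, fs(["u", "t", "tf"]): 4,
    fs(["u", "f", "t", "tf"]): 8,
}

_ROLES = {
    "Computation": ("prediction",),
    "Experimentation": ("expectation",),
    "Curation": ("prediction", "expectation"),
}


def group(observations) -> Dict[Tuple[str, str], FrozenSet[str]]:
    claims: Dict[Tuple[str, str], List[bool]] = {}
    for obs in observations:
        for role in _ROLES[obs.obs_type.value]:
            claims.setdefault((obs.evidence_for, role), []).append(obs.is_present)
    out = {}
    for key, values in claims.items():
        if any(values) and not all(values):
            out[key] = "tf"
        elif any(values):
            out[key] = "t"
        else:
            out[key] = "f"
    return out


def approx(members: FrozenSet[str], role: str) -> str:
    has_t = "t" in members or "tf" in members
    has_f = "f" in members or "tf" in members
    has_u = "u" in members or not members
    if has_t and has_f:
        return "Both"
    if role == "prediction" and has_u:
        return "None"
    if has_t:
        return "True"
    if has_f:
        return "False"
    return "None"


CONCLUSIONS = {
    ("True", "True"): "Confirmed Presence",
    ("True", "False"): "Unexpected Absence",
    ("True", "Both"): "Contradictory Absence",
    ("True", "None"): "Missing",
    ("False", "True"): "Unexpected Presence",
    ("False", "False"): "Confirmed Absence",
    ("False", "Both"): "Contradictory Presence",
    ("False", "None"): "Absent",
    ("Both", "True"): "Ambiguous Presence",
    ("Both", "False"): "Ambiguous Absence",
    ("Both", "Both"): "Ambiguous Contradiction",
    ("Both", "None"): "Ambiguous",
    ("None", "True"): "Unconfirmed Presence",
    ("None", "False"): "Unconfirmed Absence",
    ("None", "Both"): "Unconfirmed Contradiction",
    ("None", "None"): "Unexplained",
}


def oracle_run(graph, observations, dispensable=False, falsehood=False,
               specific=False):
    """Evaluate by unordered sweeps to a fixpoint; returns per-node
    (prediction members, expectation members, conclusion label)."""
    nodes = graph.identifiers()
    otvs = group(o for o in observations if o.evidence_for in graph)
    skip = {n: dispensable and graph.concept(n).is_dispensable for n in nodes}

    def part_kids(n):
        return [c for c in graph.children(n, "part") if not skip[c]]

    pred: Dict[str, FrozenSet[str]] = {n: fs() for n in nodes}
    changed = True
    while changed:
        changed = False
        for n in nodes:
            part_c = graph.children(n, "part")
            sub_c = graph.children(n, "subtype")
            if not part_c and not sub_c:
                if (n, "prediction") in otvs:
                    new = fs([otvs[(n, "prediction")]])
                elif falsehood and not skip[n]:
                    new = fs("f")
                else:
                    new = fs("u")
            else:
                members = set()
                if (n, "prediction") in otvs:
                    members.add(otvs[(n, "prediction")])
                kids = part_kids(n)
                if specific and any(pred[c] == fs("t") and graph.is_specific(c)
                                    for c in kids):
                    kids = [c for c in kids if pred[c] != fs("u")]
                for c in kids:
                    members |= pred[c]
                if sub_c:
                    best = min(RANK[pred[c]] for c in sub_c)
                    for c in sub_c:
                        if RANK[pred[c]] == best:
                            members |= pred[c]
                new = fs(members)
            if new != pred[n]:
                pred[n] = new
                changed = True

    exp: Dict[str, FrozenSet[str]] = {n: fs() for n in nodes}
    changed = True
    while changed:
        changed = False
        for n in nodes:
            members = set()
            if (n, "expectation") in otvs:
                members.add(otvs[(n, "expectation")])
            if not skip[n]:
                for p in graph.parents(n, "part"):
                    members |= exp[p]
                for p in graph.parents(n, "subtype"):
                    pexp = exp[p]
                    if not pexp:
                        continue
                    if pexp == fs("f"):
                        members |= pexp
                        continue
                    sibs = [c for c in graph.children(p, "subtype")
                            if not skip[c]]
                    if sibs and RANK[pred[n]] == min(RANK[pred[c]] for c in sibs):
                        members |= pexp
            new = fs(members)
            if new != exp[n]:
                exp[n] = new
                changed = True

    return {n: (pred[n], exp[n],
                CONCLUSIONS[(approx(exp[n], "expectation"),
                             approx(pred[n], "prediction"))])
            for n in nodes}


def tvps_as_strings(tvps) -> FrozenSet[str]:
    """Map a package Tvps to the oracle's string-set representation."""
    mapping = {"t": "t", "f": "f", "t,f": "tf", "∅": "u"}
    return fs(mapping[m.value] for m in tvps.members)


def state_as_oracle(state):
    return {n: (tvps_as_strings(state.predictions[n]),
                tvps_as_strings(state.expectations[n]),
                state.conclusions[n].value)
            for n in state.graph.identifiers()}
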
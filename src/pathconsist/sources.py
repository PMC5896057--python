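"""Loading concept graphs and writing reports.

Two graph sources are supported:

* a generic JSON document with top-level ``concepts`` and ``relations``
  arrays — the canonical interchange format (a JSON Schema describing it
  ships at ``pathconsist/data/graph-schema.json``);
* an OBO 1.2 ontology subset: terms become concepts, ``is_a`` becomes a
  subtype relation, every other relationship tag maps (configurably) to
  part; obsolete terms are skipped.

Outputs: a conclusions CSV (one row per concept, sorted, byte-stable), a
per-category statistics CSV, and DOT text colouring each node by its
approximated expectation (left half) and prediction (right half):
TRUE green, FALSE red, BOTH purple, NONE white.
"""

from __future__ import annotations

import csv
import io
import json
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple, Union

from .graph import (
    CATEGORIES, RELATION_KINDS, ConceptGraph, GraphError, PriorKnowledge,
)
from .reasoner import ReasoningState
from .truth_values import Approx, Role

CONCLUSION_COLUMNS = ("Concept", "Label", "Category", "Prediction",
                      "Expectation", "PredictionApprox", "ExpectationApprox",
                      "Conclusion")

APPROX_COLORS = {
    Approx.TRUE: "green",
    Approx.FALSE: "red",
    Approx.BOTH: "purple",
    Approx.NONE: "white",
}


class DocumentError(GraphError):
    """The generic graph document violates its schema."""


# ---------------------------------------------------------------------------
# generic JSON documents

def _check(condition: bool, message: str) -> None:
    if not condition:
        raise DocumentError(message)


def load_generic(document: Union[Mapping, str, Path, io.TextIOBase]
                 ) -> ConceptGraph:
    """Build a validated :class:`ConceptGraph` from a generic graph document.

    Accepts a mapping, a JSON file path, or an open text stream.  The
    document is schema-checked before construction; unresolvable relation
    endpoints, bad kinds/categories and cycles all raise with the offending
    identifier.
    """
    if isinstance(document, (str, Path)):
        with open(document, encoding="utf-8") as handle:
            document = json.load(handle)
    elif isinstance(document, io.TextIOBase):
        document = json.load(document)

    _check(isinstance(document, Mapping), "document must be a JSON object")
    unknown = set(document) - {"concepts", "relations"}
    _check(not unknown, "unknown top-level keys: %s" % sorted(unknown))
    concepts = document.get("concepts", [])
    relations = document.get("relations", [])
    _check(isinstance(concepts, list), "'concepts' must be an array")
    _check(isinstance(relations, list), "'relations' must be an array")

    graph = ConceptGraph()
    for i, entry in enumerate(concepts):
        _check(isinstance(entry, Mapping), "concepts[%d] must be an object" % i)
        _check("id" in entry, "concepts[%d] missing 'id'" % i)
        cid = entry["id"]
        _check(isinstance(cid, str) and cid, "concepts[%d] 'id' must be a "
               "non-empty string" % i)
        category = entry.get("category", "other")
        _check(category in CATEGORIES,
               "concept %r has unknown category %r" % (cid, category))
        graph.add_concept(PriorKnowledge(
            identifier=cid,
            label=str(entry.get("label", "")),
            category=category,
            is_dispensable=bool(entry.get("dispensable", False)),
        ))
    for i, entry in enumerate(relations):
        _check(isinstance(entry, Mapping), "relations[%d] must be an object" % i)
        for key in ("parent", "child", "kind"):
            _check(key in entry, "relations[%d] missing %r" % (i, key))
        kind = entry["kind"]
        _check(kind in RELATION_KINDS,
               "relations[%d] has unknown kind %r" % (i, kind))
        graph.add_relation(entry["parent"], entry["child"], kind)
    return graph


def write_generic(graph: ConceptGraph,
                  destination: Union[str, Path, io.TextIOBase, None] = None
                  ) -> Dict:
    """Serialize a graph back to the generic document form.

    Round-trips with :func:`load_generic` on concepts and relations.  When
    ``destination`` is given the JSON is also written there.
    """
    document = {
        "concepts": [
            {"id": c.identifier, "label": c.label, "category": c.category,
             "dispensable": c.is_dispensable}
            for c in (graph.concept(i) for i in graph.identifiers())
        ],
        "relations": [
            {"parent": r.parent, "child": r.child, "kind": r.kind}
            for r in graph.relations()
        ],
    }
    if isinstance(destination, (str, Path)):
        with open(destination, "w", encoding="utf-8") as handle:
            json.dump(document, handle, indent=2, ensure_ascii=False)
            handle.write("\n")
    elif destination is not None:
        json.dump(document, destination, indent=2, ensure_ascii=False)
        destination.write("\n")
    return document


# ---------------------------------------------------------------------------
# OBO

def load_obo(source: Union[str, Path, io.TextIOBase],
             relation_kinds: Optional[Mapping[str, str]] = None,
             default_kind: str = "part",
             category: str = "other") -> ConceptGraph:
    """Load an OBO 1.2 term hierarchy as a concept graph.

    ``is_a`` edges become subtype relations (the referenced term is the
    generalization, i.e. the parent); every other relationship tag maps via
    ``relation_kinds`` and falls back to ``default_kind`` (part), with the
    referenced term stored as the parent — OBO edges point child → parent.
    Obsolete terms are skipped.
    """
    import networkx as nx
    import obonet

    mapping = {"is_a": "subtype"}
    if relation_kinds:
        mapping.update(relation_kinds)

    try:
        ont = obonet.read_obo(source, ignore_obsolete=True)
    except Exception as exc:  # obonet raises assorted parse errors
        raise DocumentError("malformed OBO source: %s" % (exc,)) from exc

    graph = ConceptGraph()
    for term, data in sorted(ont.nodes(data=True)):
        graph.add_concept(PriorKnowledge(
            identifier=term,
            label=data.get("name", ""),
            category=category,
        ))
    for child, parent, tag in sorted(ont.edges(keys=True)):
        if parent not in graph:
            continue  # dangling reference (e.g. to an obsolete term)
        kind = mapping.get(tag, default_kind)
        if kind not in RELATION_KINDS:
            raise DocumentError(
                "relationship tag %r maps to unknown kind %r" % (tag, kind))
        graph.add_relation(parent, child, kind)
    return graph


# ---------------------------------------------------------------------------
# report writers

def conclusion_rows(state: ReasoningState) -> List[Tuple[str, ...]]:
    rows = []
    for nid in state.graph.identifiers():
        concept = state.graph.concept(nid)
        pred = state.predictions[nid]
        exp = state.expectations[nid]
        rows.append((
            nid, concept.label, concept.category,
            pred.render(), exp.render(),
            pred.approximate(Role.PREDICTION).value,
            exp.approximate(Role.EXPECTATION).value,
            state.conclusions[nid].value,
        ))
    return rows


def write_conclusions(state: ReasoningState,
                      destination: Union[str, Path, io.TextIOBase]) -> None:
    """Write the conclusions CSV: one sorted row per concept, byte-stable."""
    if isinstance(destination, (str, Path)):
        try:
            with open(destination, "w", newline="", encoding="utf-8") as handle:
                write_conclusions(state, handle)
        except OSError as exc:
            raise OSError("cannot write conclusions to %s: %s"
                          % (destination, exc)) from exc
        return
    writer = csv.writer(destination, lineterminator="\n")
    writer.writerow(CONCLUSION_COLUMNS)
    writer.writerows(conclusion_rows(state))


def read_conclusions(source: Union[str, Path, io.TextIOBase]
                     ) -> List[Tuple[str, ...]]:
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as handle:
            return read_conclusions(handle)
    reader = csv.reader(source)
    header = next(reader)
    if tuple(header) != CONCLUSION_COLUMNS:
        raise DocumentError("unexpected conclusions header: %s" % (header,))
    return [tuple(row) for row in reader]


def _dot_quote(text: str) -> str:
    # escapes quotes only; "\n" sequences are intentional DOT line breaks
    return '"%s"' % text.replace('"', '\\"')


def export_dot(state: ReasoningState, root: Optional[str] = None) -> str:
    """Render the (sub)graph as DOT text with the reasoning colour code.

    Each node is split-filled: left half the expectation approximation,
    right half the prediction approximation (green/red/purple/white for
    TRUE/FALSE/BOTH/NONE).  ``root`` restricts output to that concept's
    descendant cone.
    """
    graph = state.graph
    if root is not None:
        nodes = set(graph.descendants(root)) | {root}
    else:
        nodes = set(graph.identifiers())

    lines = ["digraph conclusions {",
             "  rankdir=TB;",
             '  node [shape=box, style="filled", gradientangle=0];']
    for nid in sorted(nodes):
        exp_color = APPROX_COLORS[state.expectations[nid].approximate(Role.EXPECTATION)]
        pred_color = APPROX_COLORS[state.predictions[nid].approximate(Role.PREDICTION)]
        label = "%s\\n%s" % (nid, state.conclusions[nid].value)
        lines.append('  %s [label=%s, fillcolor="%s;0.5:%s"];' % (
            _dot_quote(nid), _dot_quote(label), exp_color, pred_color))
    for rel in state.graph.relations():
        if rel.parent in nodes and rel.child in nodes:
            lines.append("  %s -> %s [label=%s];" % (
                _dot_quote(rel.parent), _dot_quote(rel.child),
                _dot_quote(rel.kind)))
    lines.append("}")
    return "\n".join(lines) + "\n"
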
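"""Observation records and their 7-column CSV interchange format.

An observation is one piece of organism-specific evidence about a concept:

* ``Computation`` — a bioinformatics prediction (protein-family hit, EC
  annotation); contributes to the concept's *prediction* only.
* ``Experimentation`` — an empirical result (e.g. a growth phenotype);
  contributes to the *expectation* only.
* ``Curation`` — human expertise; counts as both prediction and expectation.

The CSV columns are Name, EvidenceFor, Type, isPresent, Source, Label,
Description (comma separated, double-quote quoting, UTF-8).
"""

from __future__ import annotations

import csv
import enum
import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Tuple, Union

from .graph import ConceptGraph
from .truth_values import Otvs, Role, otvs_of

CSV_COLUMNS = ("Name", "EvidenceFor", "Type", "isPresent",
               "Source", "Label", "Description")


class ObservationType(enum.Enum):
    COMPUTATION = "Computation"
    CURATION = "Curation"
    EXPERIMENTATION = "Experimentation"

    @property
    def roles(self) -> Tuple[Role, ...]:
        if self is ObservationType.COMPUTATION:
            return (Role.PREDICTION,)
        if self is ObservationType.EXPERIMENTATION:
            return (Role.EXPECTATION,)
        return (Role.PREDICTION, Role.EXPECTATION)


@dataclass(frozen=True)
class Observation:
    name: str
    evidence_for: str
    obs_type: ObservationType
    is_present: bool
    source: str = ""
    label: str = ""
    description: str = ""

    @property
    def roles(self) -> Tuple[Role, ...]:
        return self.obs_type.roles


class ObservationParseError(ValueError):
    pass


class UnknownTargetWarning(UserWarning):
    """An observation referenced a concept absent from the graph."""


def _parse_bool(text: str, line_no: int) -> bool:
    lowered = text.strip().lower()
    if lowered == "true":
        return True
    if lowered == "false":
        return False
    raise ObservationParseError(
        "line %d: isPresent must be true or false, got %r" % (line_no, text))


def read_observations(source: Union[str, Path, io.TextIOBase]) -> List[Observation]:
    """Read observations from a 7-column CSV file, path or text stream.

    Errors (wrong header, bad Type/isPresent, duplicate Name) cite the
    offending line number.
    """
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as handle:
            return read_observations(handle)

    reader = csv.reader(source)
    try:
        header = next(reader)
    except StopIteration:
        raise ObservationParseError("line 1: missing header row")
    if tuple(h.strip() for h in header) != CSV_COLUMNS:
        raise ObservationParseError(
            "line 1: expected columns %s, got %s"
            % (",".join(CSV_COLUMNS), ",".join(header)))

    by_value = {t.value: t for t in ObservationType}
    out: List[Observation] = []
    seen: Dict[str, int] = {}
    for line_no, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != len(CSV_COLUMNS):
            raise ObservationParseError(
                "line %d: expected %d fields, got %d"
                % (line_no, len(CSV_COLUMNS), len(row)))
        name, target, type_text, present_text, src, label, desc = row
        if type_text.strip() not in by_value:
            raise ObservationParseError(
                "line %d: unknown observation Type %r" % (line_no, type_text))
        if name in seen:
            raise ObservationParseError(
                "line %d: duplicate observation Name %r (first on line %d)"
                % (line_no, name, seen[name]))
        seen[name] = line_no
        out.append(Observation(
            name=name,
            evidence_for=target,
            obs_type=by_value[type_text.strip()],
            is_present=_parse_bool(present_text, line_no),
            source=src,
            label=label,
            description=desc,
        ))
    return out


def write_observations(observations: Iterable[Observation],
                       destination: Union[str, Path, io.TextIOBase]) -> None:
    if isinstance(destination, (str, Path)):
        with open(destination, "w", newline="", encoding="utf-8") as handle:
            write_observations(observations, handle)
            return
    writer = csv.writer(destination, lineterminator="\n")
    writer.writerow(CSV_COLUMNS)
    for obs in observations:
        writer.writerow([
            obs.name, obs.evidence_for, obs.obs_type.value,
            "true" if obs.is_present else "false",
            obs.source, obs.label, obs.description,
        ])


def group_to_otvs(observations: Iterable[Observation],
                  graph: ConceptGraph) -> Dict[Tuple[str, Role], Otvs]:
    """Group observations by (target concept, role) into Otvs values.

    Pairs with no observation are simply absent from the mapping.
    Observations whose target is not in the graph raise an
    :class:`UnknownTargetWarning` and are excluded (annotation dumps often
    reference concepts missing from a particular process-definition
    release); they are never silently dropped.
    """
    claims: Dict[Tuple[str, Role], List[bool]] = {}
    for obs in observations:
        if obs.evidence_for not in graph:
            warnings.warn(
                "observation %r targets unknown concept %r"
                % (obs.name, obs.evidence_for), UnknownTargetWarning,
                stacklevel=2)
            continue
        for role in obs.roles:
            claims.setdefault((obs.evidence_for, role), []).append(obs.is_present)
    return {key: otvs_of(values) for key, values in claims.items()}
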
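"""The sixteen-valued truth algebra underlying the reasoner.

Evidence about a biological-process concept is grouped into an *observation
truth value set* (:class:`Otvs`): after grouping, the claims about one concept
and one role (prediction or expectation) are either all true ``{t}``, all
false ``{f}``, contradictory ``{t,f}``, or absent ``{∅}``.

Propagation over the concept graph accumulates such sets, so a concept's
prediction or expectation is a *subset of the four Otvs states* — one of 16
possible values (:class:`Tvps`), a powerset-of-powerset construction related
to the SIXTEEN₃ trilattice of generalized truth values.  Each of the 16
values carries an exact truth degree, falsehood degree and information degree
(all rational), from which a total *belief rank* (1 = most believed, 16 =
least) is derived: decreasing truth, then increasing falsehood, then
increasing information.

For human interpretation the 16 values are approximated to four labels
(TRUE / FALSE / BOTH / NONE); crossing the approximated expectation with the
approximated prediction yields one of 16 named conclusion states
("Confirmed Presence", "Missing", "Contradictory Absence", ...).

All degree arithmetic is exact (:class:`fractions.Fraction`): several ranks
are separated by differences like 1/6, which floating point would blur.
"""

from __future__ import annotations

import enum
from fractions import Fraction
from functools import total_ordering
from typing import FrozenSet, Iterable, Optional, Tuple


class Otvs(enum.Enum):
    """One grouped observation truth value set: {t}, {f}, {t,f} or {∅}."""

    TRUE = "t"
    FALSE = "f"
    CONTRADICTORY = "t,f"
    UNKNOWN = "∅"

    @property
    def truth_degree(self) -> Fraction:
        return _OTVS_DEGREES[self][0]

    @property
    def falsehood_degree(self) -> Fraction:
        return _OTVS_DEGREES[self][1]

    def render(self) -> str:
        return "{%s}" % self.value

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return "Otvs(%s)" % self.render()


# truth / falsehood degrees of the four grouped states, in the order
# {t}, {f}, {t,f}, {∅}: 1,0,1/2,0 and 0,1,1/2,0.
_OTVS_DEGREES = {
    Otvs.TRUE: (Fraction(1), Fraction(0)),
    Otvs.FALSE: (Fraction(0), Fraction(1)),
    Otvs.CONTRADICTORY: (Fraction(1, 2), Fraction(1, 2)),
    Otvs.UNKNOWN: (Fraction(0), Fraction(0)),
}

# canonical element order for rendering: t < f < t,f < ∅
_ELEMENT_ORDER = {Otvs.TRUE: 0, Otvs.FALSE: 1, Otvs.CONTRADICTORY: 2, Otvs.UNKNOWN: 3}


class Role(enum.Enum):
    """The two evidence roles attached to a concept."""

    PREDICTION = "prediction"
    EXPECTATION = "expectation"


class Approx(enum.Enum):
    """Four-valued approximation of a truth value powerset."""

    TRUE = "True"
    FALSE = "False"
    BOTH = "Both"
    NONE = "None"


def otvs_of(assertions: Iterable[bool]) -> Otvs:
    """Group boolean truth claims into a single observation truth value set.

    Only true claims → ``{t}``; only false → ``{f}``; both → ``{t,f}``;
    no claims at all → ``{∅}``.
    """
    has_t = has_f = False
    for claim in assertions:
        if claim:
            has_t = True
        else:
            has_f = True
    if has_t and has_f:
        return Otvs.CONTRADICTORY
    if has_t:
        return Otvs.TRUE
    if has_f:
        return Otvs.FALSE
    return Otvs.UNKNOWN


@total_ordering
class Tvps:
    """A truth value powerset: one of the 16 subsets of the four Otvs states.

    Instances are interned — exactly 16 exist per interpreter — so identity,
    equality and hashing are cheap and ``Tvps.of(...)`` always returns the
    canonical object.  Ordering compares belief ranks (smaller rank = greater
    belief).
    """

    __slots__ = ("members", "truth_degree", "falsehood_degree",
                 "information_degree", "_rank")

    _registry: dict = {}

    def __new__(cls, members: FrozenSet[Otvs]):
        members = frozenset(members)
        try:
            return cls._registry[members]
        except KeyError:
            pass
        self = object.__new__(cls)
        self.members = members
        n = len(members)
        self.information_degree = n
        if n == 0:
            self.truth_degree = Fraction(0)
            self.falsehood_degree = Fraction(0)
        else:
            self.truth_degree = sum(
                (m.truth_degree for m in members), Fraction(0)) / n
            self.falsehood_degree = sum(
                (m.falsehood_degree for m in members), Fraction(0)) / n
        self._rank = None
        cls._registry[members] = self
        return self

    @classmethod
    def of(cls, *members: Otvs) -> "Tvps":
        if len(members) == 1 and not isinstance(members[0], Otvs):
            members = tuple(members[0])
        return cls(frozenset(members))

    @classmethod
    def universe(cls) -> Tuple["Tvps", ...]:
        """All 16 values, in belief-rank order."""
        return _UNIVERSE_BY_RANK

    @property
    def belief_rank(self) -> int:
        """Total-order position 1..16: most believed value ranks first."""
        return self._rank

    def approximate(self, role: Role) -> Approx:
        """Collapse to TRUE / FALSE / BOTH / NONE.

        Contradiction (both t and f present somewhere in the set) always
        yields BOTH.  The roles differ on unknowns: for a *prediction* an
        ``{∅}`` member means part of the concept is unknown, so the whole
        approximation is NONE; for an *expectation* unknown members are
        ignored (they reflect missing information higher up, not a missing
        part), so {{∅},{t}} → TRUE and {{∅},{f}} → FALSE.
        """
        has_t = any(m in (Otvs.TRUE, Otvs.CONTRADICTORY) for m in self.members)
        has_f = any(m in (Otvs.FALSE, Otvs.CONTRADICTORY) for m in self.members)
        has_u = Otvs.UNKNOWN in self.members or not self.members
        if has_t and has_f:
            return Approx.BOTH
        if role is Role.PREDICTION and has_u:
            return Approx.NONE
        if has_t:
            return Approx.TRUE
        if has_f:
            return Approx.FALSE
        return Approx.NONE

    def render(self) -> str:
        """Canonical text form, elements ordered t < f < t,f < ∅.

        The empty powerset renders as ``∅``; e.g. ``{{t},{t,f}}``.
        """
        if not self.members:
            return "∅"
        inner = ",".join(
            m.render() for m in sorted(self.members, key=_ELEMENT_ORDER.get))
        return "{%s}" % inner

    def __eq__(self, other):
        return self is other

    def __lt__(self, other):
        if not isinstance(other, Tvps):
            return NotImplemented
        return self.belief_rank < other.belief_rank

    def __hash__(self):
        return hash(self.members)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return "Tvps(%s)" % self.render()


def parse_tvps(text: str) -> Tvps:
    """Inverse of :meth:`Tvps.render` (accepts any element order)."""
    text = text.strip()
    if text in ("∅", "{}"):
        return EMPTY
    if not (text.startswith("{{") and text.endswith("}}")):
        raise ValueError("not a truth value powerset: %r" % text)
    by_value = {o.value: o for o in Otvs}
    members = []
    for chunk in text[1:-1].replace("},{", "}|{").split("|"):
        inner = chunk.strip()[1:-1]
        if inner not in by_value:
            raise ValueError("unknown truth value element %r in %r" % (inner, text))
        members.append(by_value[inner])
    return Tvps.of(*members)


def union(sets: Iterable[Tvps], extra: Optional[Otvs] = None) -> Tvps:
    """Set-union of truth value powersets, optionally adding one Otvs element.

    This is the accumulation step of the propagation rules; it is closed on
    the 16-value universe and is commutative, associative and idempotent.
    """
    members = set()
    for s in sets:
        members |= s.members
    if extra is not None:
        members.add(extra)
    return Tvps.of(*members)


# ---------------------------------------------------------------------------
# the interned universe and the belief ranking

def _build_universe():
    import itertools

    all_sets = [Tvps(frozenset(combo))
                for r in range(5)
                for combo in itertools.combinations(list(Otvs), r)]
    # decreasing truth degree, then increasing falsehood, then information
    ordered = sorted(all_sets, key=lambda s: (-s.truth_degree,
                                              s.falsehood_degree,
                                              s.information_degree))
    for rank, s in enumerate(ordered, start=1):
        s._rank = rank
    return tuple(ordered)


_UNIVERSE_BY_RANK = _build_universe()

#: the four most common values, named
EMPTY = Tvps.of()
UNKNOWN_ONLY = Tvps.of(Otvs.UNKNOWN)
TRUE_ONLY = Tvps.of(Otvs.TRUE)
FALSE_ONLY = Tvps.of(Otvs.FALSE)
CONTRADICTORY_ONLY = Tvps.of(Otvs.CONTRADICTORY)


class ConclusionState(enum.Enum):
    """One of the 16 conclusion labels from crossing expectation × prediction."""

    CONFIRMED_PRESENCE = "Confirmed Presence"
    UNEXPECTED_ABSENCE = "Unexpected Absence"
    CONTRADICTORY_ABSENCE = "Contradictory Absence"
    MISSING = "Missing"
    UNEXPECTED_PRESENCE = "Unexpected Presence"
    CONFIRMED_ABSENCE = "Confirmed Absence"
    CONTRADICTORY_PRESENCE = "Contradictory Presence"
    ABSENT = "Absent"
    AMBIGUOUS_PRESENCE = "Ambiguous Presence"
    AMBIGUOUS_ABSENCE = "Ambiguous Absence"
    AMBIGUOUS_CONTRADICTION = "Ambiguous Contradiction"
    AMBIGUOUS = "Ambiguous"
    UNCONFIRMED_PRESENCE = "Unconfirmed Presence"
    UNCONFIRMED_ABSENCE = "Unconfirmed Absence"
    UNCONFIRMED_CONTRADICTION = "Unconfirmed Contradiction"
    UNEXPLAINED = "Unexplained"


# rows: approximated expectation; columns: approximated prediction
_CONCLUSION_TABLE = {
    (Approx.TRUE, Approx.TRUE): ConclusionState.CONFIRMED_PRESENCE,
    (Approx.TRUE, Approx.FALSE): ConclusionState.UNEXPECTED_ABSENCE,
    (Approx.TRUE, Approx.BOTH): ConclusionState.CONTRADICTORY_ABSENCE,
    (Approx.TRUE, Approx.NONE): ConclusionState.MISSING,
    (Approx.FALSE, Approx.TRUE): ConclusionState.UNEXPECTED_PRESENCE,
    (Approx.FALSE, Approx.FALSE): ConclusionState.CONFIRMED_ABSENCE,
    (Approx.FALSE, Approx.BOTH): ConclusionState.CONTRADICTORY_PRESENCE,
    (Approx.FALSE, Approx.NONE): ConclusionState.ABSENT,
    (Approx.BOTH, Approx.TRUE): ConclusionState.AMBIGUOUS_PRESENCE,
    (Approx.BOTH, Approx.FALSE): ConclusionState.AMBIGUOUS_ABSENCE,
    (Approx.BOTH, Approx.BOTH): ConclusionState.AMBIGUOUS_CONTRADICTION,
    (Approx.BOTH, Approx.NONE): ConclusionState.AMBIGUOUS,
    (Approx.NONE, Approx.TRUE): ConclusionState.UNCONFIRMED_PRESENCE,
    (Approx.NONE, Approx.FALSE): ConclusionState.UNCONFIRMED_ABSENCE,
    (Approx.NONE, Approx.BOTH): ConclusionState.UNCONFIRMED_CONTRADICTION,
    (Approx.NONE, Approx.NONE): ConclusionState.UNEXPLAINED,
}


def conclude(expectation: Approx, prediction: Approx) -> ConclusionState:
    """Look up the conclusion state for an (expectation, prediction) pair."""
    return _CONCLUSION_TABLE[(expectation, prediction)]
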
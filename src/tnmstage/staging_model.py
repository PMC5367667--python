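"""Domain model for TNM anatomic staging tables.

The TNM system classifies a cancer along three principal axes — primary
tumor extent (T), regional lymph-node spread (N), and distant metastasis
(M) — plus, for some cancers, additional prognostic-factor axes.  A
*staging table* maps combinations of classifications (TNM groupings,
possibly containing "Any T"-style wildcards) to anatomic stage labels
ordered by declining prognosis.

These types are deliberately plain dataclasses: the exclusion engine and
the codec both operate on them, and all invariants that span more than one
object are enforced by :mod:`tnmstage.table_codec` at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

#: Sentinel requirement matching every classification on its axis
#: (rendered as "Any T" / "Any N" in stage arrays).
WILDCARD = "*"


class VocabularyError(KeyError):
    """An axis or classification code not defined in the staging table."""


@dataclass(frozen=True)
class Axis:
    """One classification axis of a staging table.

    Parameters
    ----------
    code:
        Axis code: ``"T"``, ``"N"``, ``"M"``, or a declared
        prognostic-factor axis code.
    name:
        Human-readable axis name (e.g. ``"Primary tumor"``).
    rank:
        Extent-of-spread priority used as a ranking tie-break; higher
        outranks lower (M > N > T > prognostic axes).
    """

    code: str
    name: str
    rank: int


@dataclass(frozen=True)
class Question:
    """Yes/no decomposition of a classification's defining criteria.

    ``clauses`` are atomic yes/no items joined by ``connective`` (``"OR"``
    or ``"AND"``; single-clause questions use ``"OR"`` by convention).
    ``affirmative`` records polarity: when True, an overall "yes" answer
    means the classification applies.  Criteria stated as negations (e.g.
    "No distant metastasis") are rewritten affirmatively and stored with
    ``affirmative=False`` so the prompt itself never asks the user to
    confirm an absence.
    """

    clauses: tuple[str, ...]
    connective: str = "OR"
    affirmative: bool = True

    def __post_init__(self) -> None:
        if not self.clauses:
            raise ValueError("a question needs at least one clause")
        if self.connective not in ("OR", "AND"):
            raise ValueError(f"connective must be OR or AND, got {self.connective!r}")

    @property
    def text(self) -> str:
        """The rendered prompt text."""
        joiner = f"\n  {self.connective} "
        return joiner.join(self.clauses)

    def interpret(self, raw_yes: bool) -> bool:
        """Map a raw yes/no answer to "the classification applies"."""
        return raw_yes if self.affirmative else not raw_yes


@dataclass(frozen=True)
class Classification:
    """One code on one axis, with its defining criteria and question.

    ``level`` orders codes within an axis (N3 > N2 > N1 > N0); ``sublevel``
    letters order within a level (a < b < c < d).  ``parent`` links
    fine-grained codes to their coarser parent (T1a -> T1): stage arrays
    for different cancers mix granularities, so matching must understand
    both directions.  "Not assessable" codes (TX/NX) are ordinary
    classifications placed at the bottom of their axis's level order.
    """

    axis: str
    code: str
    level: int
    sublevel: Optional[str] = None
    parent: Optional[str] = None
    criteria_text: str = ""
    question: Optional[Question] = None

    @property
    def sort_level(self) -> tuple[int, str]:
        return (self.level, self.sublevel or "")


@dataclass(frozen=True)
class TNMGrouping:
    """One row of the stage array: a per-axis requirement mapped to a stage.

    ``requirements`` maps every axis code of the table to either a specific
    classification code or :data:`WILDCARD`.
    """

    stage: str
    requirements: dict[str, str] = field(hash=False)

    def requirement(self, axis: str) -> str:
        try:
            return self.requirements[axis]
        except KeyError:
            raise VocabularyError(f"grouping has no requirement for axis {axis!r}")

    def key(self) -> tuple[tuple[str, str], ...]:
        """Hashable identity of the row's requirements (axis order fixed)."""
        return tuple(sorted(self.requirements.items()))

    def __str__(self) -> str:
        parts = []
        for axis, req in self.requirements.items():
            parts.append(f"Any {axis}" if req == WILDCARD else req)
        return f"{self.stage} " + " ".join(parts)


@dataclass(frozen=True)
class StageGroup:
    """All groupings sharing one stage label.

    ``prognostic_order`` is the position in the declining-prognosis
    ordering; labels are opaque strings ("Occult", "0", "IA", ... "IV") and
    never parsed.
    """

    label: str
    prognostic_order: int
    groupings: tuple[TNMGrouping, ...]


@dataclass
class StagingTable:
    """One cancer type's complete staging specification."""

    tumor_type: str
    axes: list[Axis]
    classifications: list[Classification]
    stage_groups: list[StageGroup]
    selectors: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_code: dict[tuple[str, str], Classification] = {
            (c.axis, c.code): c for c in self.classifications
        }
        self._axis_by_code: dict[str, Axis] = {a.code: a for a in self.axes}

    # -- vocabulary lookups -------------------------------------------------

    def axis(self, code: str) -> Axis:
        try:
            return self._axis_by_code[code]
        except KeyError:
            raise VocabularyError(f"unknown axis {code!r}")

    def classification(self, axis: str, code: str) -> Classification:
        self.axis(axis)
        try:
            return self._by_code[(axis, code)]
        except KeyError:
            raise VocabularyError(f"unknown classification {code!r} on axis {axis!r}")

    def has_classification(self, axis: str, code: str) -> bool:
        return (axis, code) in self._by_code

    def axis_classifications(self, axis: str) -> list[Classification]:
        return [c for c in self.classifications if c.axis == axis]

    def children(self, axis: str, code: str) -> list[Classification]:
        return [c for c in self.classifications if c.axis == axis and c.parent == code]

    def leaf_classifications(self, axis: str) -> list[Classification]:
        """Codes with no finer-grained children (usable as concrete findings)."""
        parents = {c.parent for c in self.classifications if c.axis == axis and c.parent}
        return [c for c in self.axis_classifications(axis) if c.code not in parents]

    # -- groupings ----------------------------------------------------------

    @property
    def groupings(self) -> list[TNMGrouping]:
        """All rows in prognostic (stage, then row) order."""
        return [g for sg in self.stage_groups for g in sg.groupings]

    def grouping_ids(self) -> list[tuple[str, int]]:
        """(stage label, row index within stage) identity for every row."""
        return [
            (sg.label, i)
            for sg in self.stage_groups
            for i in range(len(sg.groupings))
        ]

    def grouping(self, gid: tuple[str, int]) -> TNMGrouping:
        label, idx = gid
        for sg in self.stage_groups:
            if sg.label == label:
                return sg.groupings[idx]
        raise KeyError(f"no stage group labelled {label!r}")


def matches(table: StagingTable, grouping: TNMGrouping, axis: str, code: str) -> bool:
    """Does ``grouping`` remain viable when ``code`` applies on ``axis``?

    True iff the grouping's requirement on that axis is the wildcard,
    equals ``code``, or is hierarchically compatible with it: the
    requirement is the code's parent (a row requiring T1 admits a T1a
    finding) or the code is the requirement's parent (selecting T1 keeps
    rows requiring T1a or T1b).

    Raises
    ------
    VocabularyError
        If the axis or code is not defined in the table.
    """
    cls = table.classification(axis, code)  # validates vocabulary
    req = grouping.requirement(axis)
    if req == WILDCARD or req == code:
        return True
    if cls.parent == req:
        return True
    req_cls = table.classification(axis, req)
    return req_cls.parent == code


def is_descendant(table: StagingTable, axis: str, code: str, ancestor: str) -> bool:
    """True iff ``code`` equals ``ancestor`` or descends from it on ``axis``."""
    current: Optional[str] = code
    while current is not None:
        if current == ancestor:
            return True
        current = table.classification(axis, current).parent
    return False


@dataclass
class CandidateSet:
    """The mutable set of still-viable groupings during a staging session.

    Members are identified by ``(stage label, row index)``.  Operations
    only ever remove members; restoration happens exclusively through the
    session's recorded history.
    """

    table: StagingTable
    members: list[tuple[str, int]]

    @classmethod
    def full(cls, table: StagingTable) -> "CandidateSet":
        return cls(table, table.grouping_ids())

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterable[tuple[str, int]]:
        return iter(self.members)

    def groupings(self) -> list[TNMGrouping]:
        return [self.table.grouping(gid) for gid in self.members]

    def stages(self) -> list[str]:
        """Distinct stage labels among members, in prognostic order."""
        seen: list[str] = []
        for label, _ in self.members:
            if label not in seen:
                seen.append(label)
        return seen

    def restrict(self, keep: Iterable[tuple[str, int]]) -> "CandidateSet":
        keep_set = set(keep)
        return CandidateSet(self.table, [m for m in self.members if m in keep_set])

    def copy(self) -> "CandidateSet":
        return CandidateSet(self.table, list(self.members))
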
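"""The exclusionary staging cycle: poll, rank, prompt, exclude.

Instead of the conventional combinatorial route (pick T, pick N, pick M,
look the triple up in the stage array), the engine repeatedly

1. polls the still-viable TNM groupings and tabulates how often each
   classification is explicitly required,
2. sorts the tabulated classifications in ascending order of frequency,
   breaking ties by extent of spread (M > N > T > prognostic axes) and by
   descending level within an axis (N3 > N2 > N1 > N0),
3. prompts selection or exclusion of the first-ranked classification via
   its yes/no question, and
4. nullifies the groupings the answer rules out,

until the candidate set has been narrowed to a single grouping
(``grouping-resolved``) or to a single anatomic stage
(``stage-resolved``).  Rare classifications are asked about first because
either answer to a rare classification is maximally decisive: a "yes"
eliminates almost everything, a "no" costs little.  On the lung table this
is why sessions open with the distant-metastasis questions (M1b, M1a each
back a single stage-IV row).

Sessions record every step with its prior candidate set, so answers can be
undone and redone losslessly, mirroring review-arrow navigation in an
interactive front end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

from .staging_model import (
    WILDCARD,
    CandidateSet,
    Classification,
    StagingTable,
    is_descendant,
    matches,
)

RankPolicy = Literal["frequency-first", "axis-first"]
StopMode = Literal["stage", "grouping"]

#: Default stop mode: run until a single grouping survives (the optional
#: "keep going past the stage" flow of the original app, made the default
#: so a report always carries fully resolved classifications).
DEFAULT_STOP_MODE: StopMode = "grouping"


class ExhaustedSessionError(RuntimeError):
    """The candidate set is empty; nothing can be polled or prompted."""


class NotResolvedError(RuntimeError):
    """resolve() was called before the session's stop condition holds."""


class StalledSessionError(RuntimeError):
    """No informative prompt exists but the stop condition is unmet.

    Unreachable on tables whose groupings partition the finding space
    (e.g. the bundled lung table); possible with authored tables that
    contain overlapping or hierarchy-ambiguous rows, which the validator
    lints as OVERLAPPING_GROUPINGS.
    """


class InconsistentAnswersError(RuntimeError):
    """An answer nullified every remaining grouping.

    The offending step is committed to history before raising, so the
    session stays recoverable: one undo returns to the last consistent
    state.
    """

    def __init__(self, step: "Step"):
        self.step = step
        super().__init__(
            f"answer {'yes' if step.answer else 'no'} to {step.axis}:{step.code} "
            "leaves no viable TNM grouping; undo to recover"
        )


class _Terminal:
    """Sentinel returned by next_prompt when the stop condition holds."""

    _instance: Optional["_Terminal"] = None

    def __new__(cls) -> "_Terminal":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "TERMINAL"


TERMINAL = _Terminal()


@dataclass(frozen=True)
class FrequencyTable:
    """Explicit-requirement counts per (axis, code) over a candidate set.

    Wildcard requirements contribute to no code's count (a wildcard row is
    consistent with every classification on that axis, so no answer about
    the axis can nullify it); they are tallied separately so that for each
    axis ``sum(counts) + wildcard_rows == total``.
    """

    counts: dict[tuple[str, str], int]
    wildcard_rows: dict[str, int]
    total: int

    def count(self, axis: str, code: str) -> int:
        return self.counts.get((axis, code), 0)


def tabulate_frequencies(candidates: CandidateSet) -> FrequencyTable:
    """Poll the viable groupings: how often is each code explicitly required?"""
    if len(candidates) == 0:
        raise ExhaustedSessionError("cannot poll an empty candidate set")
    counts: dict[tuple[str, str], int] = {}
    wildcards: dict[str, int] = {a.code: 0 for a in candidates.table.axes}
    for g in candidates.groupings():
        for axis, req in g.requirements.items():
            if req == WILDCARD:
                wildcards[axis] += 1
            else:
                counts[(axis, req)] = counts.get((axis, req), 0) + 1
    return FrequencyTable(counts=counts, wildcard_rows=wildcards, total=len(candidates))


def rank_classifications(
    freqs: FrequencyTable,
    table: StagingTable,
    policy: RankPolicy = "frequency-first",
) -> list[Classification]:
    """Sort the tabulated classifications into prompting order.

    ``frequency-first`` (default): ascending count, ties broken by axis
    rank (M before N before T), then descending level, then descending
    sublevel.  ``axis-first`` treats the extent-of-spread priority as the
    primary key instead.  Codes with no explicit occurrence are omitted:
    excluding them could never nullify a row, so prompting them cannot be
    guaranteed informative.
    """

    def sort_key(cls: Classification):
        count = freqs.count(cls.axis, cls.code)
        axis_rank = -table.axis(cls.axis).rank
        level = -cls.level
        sublevel = tuple(-ord(ch) for ch in (cls.sublevel or ""))
        if policy == "axis-first":
            return (axis_rank, count, level, sublevel)
        return (count, axis_rank, level, sublevel)

    present = [
        table.classification(axis, code)
        for (axis, code), n in freqs.counts.items()
        if n > 0
    ]
    return sorted(present, key=sort_key)


@dataclass(frozen=True)
class Prompt:
    """The next question to put to the user."""

    classification: Classification
    rank_trace: tuple[Classification, ...]

    @property
    def question(self):
        return self.classification.question

    @property
    def text(self) -> str:
        q = self.classification.question
        if q is None:  # tables straight from the codec always carry questions
            return f"Does classification {self.classification.code} apply?"
        return q.text

    def interpret(self, raw_yes: bool) -> bool:
        """Map a raw yes/no reply to "select this classification".

        Negative-polarity questions (affirmative criteria rewrites of
        negative definitions, e.g. M0's "Is there evidence of distant
        metastasis?") invert the raw reply.
        """
        q = self.classification.question
        return raw_yes if q is None else q.interpret(raw_yes)


@dataclass(frozen=True)
class Step:
    """One recorded session step with its pre/post candidate sets."""

    kind: Literal["prompt", "direct"]
    axis: str
    code: str
    answer: bool
    pre_members: tuple[tuple[str, int], ...]
    post_members: tuple[tuple[str, int], ...]


@dataclass
class Session:
    """A staging session: candidate set plus lossless answer history."""

    table: StagingTable
    stop_mode: StopMode = DEFAULT_STOP_MODE
    rank_policy: RankPolicy = "frequency-first"
    candidates: CandidateSet = None  # type: ignore[assignment]
    history: list[Step] = field(default_factory=list)
    _undone: list[Step] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.candidates is None:
            self.candidates = CandidateSet.full(self.table)

    # -- stop condition ----------------------------------------------------

    def stop_condition_holds(self) -> bool:
        n = len(self.candidates)
        if n == 0:
            return False
        if self.stop_mode == "grouping":
            return n == 1
        return len(self.candidates.stages()) == 1

    # -- answering ---------------------------------------------------------

    def _commit(self, kind: str, axis: str, code: str, answer: bool) -> None:
        self.table.classification(axis, code)  # vocabulary check
        if len(self.candidates) == 0:
            raise ExhaustedSessionError("candidate set is empty; undo to recover")
        pre = tuple(self.candidates.members)
        if answer:
            keep = [
                gid
                for gid in self.candidates
                if matches(self.table, self.table.grouping(gid), axis, code)
            ]
        else:
            keep = []
            for gid in self.candidates:
                req = self.table.grouping(gid).requirement(axis)
                if req == WILDCARD or not is_descendant(self.table, axis, req, code):
                    keep.append(gid)
        step = Step(
            kind=kind,  # type: ignore[arg-type]
            axis=axis,
            code=code,
            answer=answer,
            pre_members=pre,
            post_members=tuple(keep),
        )
        self.candidates = CandidateSet(self.table, list(keep))
        self.history.append(step)
        self._undone.clear()
        if not keep:
            raise InconsistentAnswersError(step)

    def apply_answer(self, axis: str, code: str, answer: bool) -> "Session":
        """Select (yes) or exclude (no) a classification.

        Yes retains only groupings that match the classification on its
        axis (wildcards survive); no removes groupings whose explicit
        requirement is the classification or one of its hierarchical
        descendants (wildcards survive).
        """
        self._commit("prompt", axis, code, answer)
        return self

    def select_direct(self, axis: str, code: str) -> "Session":
        """Directly select a classification known at the point of entry."""
        self._commit("direct", axis, code, True)
        return self

    # -- history navigation ------------------------------------------------

    def undo(self) -> bool:
        """Step back once; returns False (no-op) on a fresh session."""
        if not self.history:
            return False
        step = self.history.pop()
        self._undone.append(step)
        self.candidates = CandidateSet(self.table, list(step.pre_members))
        return True

    def redo(self) -> bool:
        """Re-apply the most recently undone step, if no new step intervened."""
        if not self._undone:
            return False
        step = self._undone.pop()
        self.history.append(step)
        self.candidates = CandidateSet(self.table, list(step.post_members))
        return True

    # -- prompting ---------------------------------------------------------

    def settled_classifications(self) -> list[Classification]:
        """Codes every remaining candidate matches, folded into the report."""
        if len(self.candidates) == 0:
            return []
        freqs = tabulate_frequencies(self.candidates)
        groupings = self.candidates.groupings()
        settled = []
        for cls in rank_classifications(freqs, self.table, self.rank_policy):
            if all(matches(self.table, g, cls.axis, cls.code) for g in groupings):
                settled.append(cls)
        return settled

    def next_prompt(self) -> Prompt | _Terminal:
        """The first-ranked prompt-eligible classification, or TERMINAL.

        A code is prompt-eligible unless every remaining candidate matches
        it on its axis — asking would be uninformative; such codes are
        auto-settled into the report instead.
        """
        if len(self.candidates) == 0:
            raise ExhaustedSessionError("candidate set is empty; undo to recover")
        if self.stop_condition_holds():
            return TERMINAL
        freqs = tabulate_frequencies(self.candidates)
        ranking = tuple(rank_classifications(freqs, self.table, self.rank_policy))
        groupings = self.candidates.groupings()
        for cls in ranking:
            if not all(matches(self.table, g, cls.axis, cls.code) for g in groupings):
                return Prompt(classification=cls, rank_trace=ranking)
        raise StalledSessionError(
            "no informative prompt remains but the stop condition is unmet; "
            "the table contains overlapping or hierarchy-ambiguous groupings"
        )

    def resolve(self) -> "StagingReport":
        if not self.stop_condition_holds():
            raise NotResolvedError(
                f"stop condition for mode {self.stop_mode!r} does not hold "
                f"({len(self.candidates)} candidates over stages "
                f"{self.candidates.stages()!r})"
            )
        return _build_report(self)


@dataclass(frozen=True)
class AxisResolution:
    """How one axis reads in the terminal report.

    ``codes`` lists the surviving explicit classifications (alternatives
    possible in stage-resolved mode); empty codes with ``wildcard`` True
    means only wildcard rows remain and no selection pinned the axis down
    — rendered as "any".
    """

    axis: str
    codes: tuple[str, ...]
    wildcard: bool

    def render(self) -> str:
        if not self.codes:
            return f"any {self.axis}"
        return "/".join(self.codes)


@dataclass(frozen=True)
class StagingReport:
    """Terminal display: stage, resolved classifications, criteria, trail."""

    stage: str
    resolutions: tuple[AxisResolution, ...]
    criteria: dict[str, str]
    answer_trail: tuple[Step, ...]

    def resolution(self, axis: str) -> AxisResolution:
        for r in self.resolutions:
            if r.axis == axis:
                return r
        raise KeyError(axis)

    def render(self) -> str:
        lines = [f"Anatomic stage: {self.stage}"]
        for r in self.resolutions:
            lines.append(f"  {r.axis}: {r.render()}")
            for code in r.codes:
                text = self.criteria.get(f"{r.axis}:{code}", "")
                if text:
                    lines.append(f"      {code}: {text}")
        lines.append("Answer trail:")
        if not self.answer_trail:
            lines.append("  (none)")
        for step in self.answer_trail:
            verb = "selected" if step.answer else "excluded"
            how = "direct" if step.kind == "direct" else "prompt"
            lines.append(f"  {verb} {step.axis}:{step.code} ({how})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "classifications": {
                r.axis: {"codes": list(r.codes), "wildcard": r.wildcard}
                for r in self.resolutions
            },
            "criteria": dict(self.criteria),
            "answer_trail": [
                {
                    "kind": s.kind,
                    "axis": s.axis,
                    "code": s.code,
                    "answer": "yes" if s.answer else "no",
                }
                for s in self.answer_trail
            ],
        }


def _build_report(session: Session) -> StagingReport:
    table = session.table
    survivors = session.candidates.groupings()
    stage = session.candidates.stages()[0]
    resolutions = []
    criteria: dict[str, str] = {}
    for axis in table.axes:
        explicit: list[str] = []
        for g in survivors:
            req = g.requirement(axis.code)
            if req != WILDCARD and req not in explicit:
                explicit.append(req)
        wildcard_only = not explicit
        if wildcard_only:
            # only wildcard rows remain: report the classification the user
            # actually selected on this axis, if any
            for step in reversed(session.history):
                if step.axis == axis.code and step.answer:
                    explicit = [step.code]
                    break
        for code in explicit:
            criteria[f"{axis.code}:{code}"] = table.classification(
                axis.code, code
            ).criteria_text
        resolutions.append(
            AxisResolution(
                axis=axis.code,
                codes=tuple(explicit),
                wildcard=wildcard_only,
            )
        )
    return StagingReport(
        stage=stage,
        resolutions=tuple(resolutions),
        criteria=criteria,
        answer_trail=tuple(session.history),
    )


# -- functional wrappers ----------------------------------------------------
# The session methods above are the idiomatic surface; these mirror them
# for callers that prefer free functions.


def next_prompt(session: Session) -> Prompt | _Terminal:
    return session.next_prompt()


def apply_answer(session: Session, axis: str, code: str, answer: bool) -> Session:
    return session.apply_answer(axis, code, answer)


def select_direct(session: Session, axis: str, code: str) -> Session:
    return session.select_direct(axis, code)


def undo(session: Session) -> Session:
    session.undo()
    return session


def redo(session: Session) -> Session:
    session.redo()
    return session


def resolve(session: Session) -> StagingReport:
    return session.resolve()


def replay(session: Session) -> CandidateSet:
    """Re-derive the candidate set by replaying history from the full set.

    Sessions satisfy ``replay(s).members == s.candidates.members`` — the
    history is a complete, lossless account of the narrowing.
    """
    current = CandidateSet.full(session.table)
    for step in session.history:
        shadow = Session(
            table=session.table,
            stop_mode=session.stop_mode,
            rank_policy=session.rank_policy,
            candidates=current,
        )
        try:
            shadow._commit(step.kind, step.axis, step.code, step.answer)
        except InconsistentAnswersError:
            pass
        current = shadow.candidates
    return current


def session_transcript(session: Session, report: Optional[StagingReport] = None) -> dict:
    """JSON-ready transcript: step sequence, candidate counts, report.

    Serialized with sorted keys this is byte-stable across runs for the
    same table and answer sequence.
    """
    return {
        "tumor_type": session.table.tumor_type,
        "stop_mode": session.stop_mode,
        "rank_policy": session.rank_policy,
        "steps": [
            {
                "kind": s.kind,
                "axis": s.axis,
                "code": s.code,
                "answer": "yes" if s.answer else "no",
                "candidates_before": len(s.pre_members),
                "candidates_after": len(s.post_members),
            }
            for s in session.history
        ],
        "candidates_remaining": len(session.candidates),
        "report": report.to_dict() if report is not None else None,
    }
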
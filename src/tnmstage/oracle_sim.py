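"""Brute-force staging oracle, truthful responder, and table simulator.

``lookup_stage`` is the conventional combinatorial route: take one
concrete classification per axis and scan the stage array top to bottom
for the first matching row.  It is deliberately the dumbest possible
implementation — a linear scan — so it can serve as an independent
reference for the exclusion engine.

``run_truthful_session`` drives an engine session with a responder that
answers every prompt truthfully according to a fixed scenario, and
``question_count_stats`` measures how many prompts truthful sessions need
compared with the naive baseline of reviewing every distinct
classification criterion once.

``generate_random_table`` builds small random staging tables (pairwise
non-overlapping rows, no classification hierarchies) for property
testing.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional

from .exclusion_engine import (
    TERMINAL,
    Prompt,
    Session,
    StagingReport,
    StopMode,
)
from .staging_model import (
    WILDCARD,
    Axis,
    Classification,
    Question,
    StageGroup,
    StagingTable,
    TNMGrouping,
    is_descendant,
    matches,
)


class UnstageableError(LookupError):
    """No row of the stage array matches the given concrete findings."""


def lookup_stage(table: StagingTable, concrete: dict[str, str]) -> str:
    """Conventional staging: locate the TNM grouping in the array.

    ``concrete`` maps every axis to one concrete classification code.
    Returns the stage of the first matching row in prognostic order.

    Raises
    ------
    UnstageableError
        If no row matches (e.g. lung Tis with N1: no such row exists).
    VocabularyError
        If a code is not defined in the table.
    """
    for axis in table.axes:
        table.classification(axis.code, concrete[axis.code])
    for sg in table.stage_groups:
        for g in sg.groupings:
            if all(matches(table, g, a.code, concrete[a.code]) for a in table.axes):
                return sg.label
    raise UnstageableError(f"no TNM grouping matches {concrete!r}")


@dataclass(frozen=True)
class Scenario:
    """A patient's true concrete classification per axis.

    ``true_stage`` is the stage the conventional lookup assigns; scenarios
    that match no grouping are rejected at construction.
    """

    concrete: dict[str, str]
    true_stage: str

    @classmethod
    def from_concrete(cls, table: StagingTable, concrete: dict[str, str]) -> "Scenario":
        return cls(concrete=dict(concrete), true_stage=lookup_stage(table, concrete))

    def truthful_answer(self, table: StagingTable, prompt: Prompt) -> bool:
        """Would this patient's findings select the prompted classification?

        Yes iff the prompted code equals the true concrete code on that
        axis or is one of its hierarchical ancestors (a T1a tumor answers
        yes to the T1 question).
        """
        cls = prompt.classification
        return is_descendant(table, cls.axis, self.concrete[cls.axis], cls.code)


def scenario_for_grouping(
    table: StagingTable, grouping: TNMGrouping, rng: Optional[random.Random] = None
) -> Scenario:
    """Concrete findings exercising one row; wildcards filled with a
    (seeded) random concrete leaf code on that axis."""
    rng = rng or random.Random(0)
    concrete = {}
    for axis in table.axes:
        req = grouping.requirement(axis.code)
        if req == WILDCARD:
            leaves = table.leaf_classifications(axis.code)
            concrete[axis.code] = rng.choice(leaves).code
        else:
            concrete[axis.code] = req
    return Scenario.from_concrete(table, concrete)


@dataclass(frozen=True)
class TruthfulTranscript:
    """Outcome of one truthful-responder session."""

    scenario: Scenario
    prompts: tuple[tuple[str, str, bool], ...]  # (axis, code, selected)
    report: StagingReport
    candidate_trajectory: tuple[int, ...]

    @property
    def prompt_count(self) -> int:
        return len(self.prompts)


def run_truthful_session(
    table: StagingTable,
    scenario: Scenario,
    stop_mode: StopMode = "grouping",
    rank_policy: str = "frequency-first",
) -> TruthfulTranscript:
    """Drive an engine session to completion with truthful answers.

    Deterministic given table and scenario.  For any valid scenario the
    reported stage equals ``lookup_stage`` — the engine's correctness
    property.
    """
    session = Session(table=table, stop_mode=stop_mode, rank_policy=rank_policy)  # type: ignore[arg-type]
    prompts: list[tuple[str, str, bool]] = []
    trajectory = [len(session.candidates)]
    while True:
        prompt = session.next_prompt()
        if prompt is TERMINAL:
            break
        assert isinstance(prompt, Prompt)
        selected = scenario.truthful_answer(table, prompt)
        prompts.append((prompt.classification.axis, prompt.classification.code, selected))
        session.apply_answer(prompt.classification.axis, prompt.classification.code, selected)
        trajectory.append(len(session.candidates))
    return TruthfulTranscript(
        scenario=scenario,
        prompts=tuple(prompts),
        report=session.resolve(),
        candidate_trajectory=tuple(trajectory),
    )


def distinct_explicit_classifications(table: StagingTable) -> list[tuple[str, str]]:
    """Codes explicitly required by at least one grouping (naive-review set)."""
    seen: list[tuple[str, str]] = []
    for g in table.groupings:
        for axis, req in g.requirements.items():
            if req != WILDCARD and (axis, req) not in seen:
                seen.append((axis, req))
    return seen


@dataclass(frozen=True)
class QuestionCountStats:
    """Prompt-count statistics for truthful sessions over every grouping.

    ``baseline`` is the number of distinct explicit classifications in the
    table — the criteria a conventional session must review one by one.
    """

    per_scenario: tuple[tuple[str, int], ...]  # (stage label, prompt count)
    mean: float
    max: int
    baseline: int
    stop_mode: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "stop_mode": self.stop_mode,
            "seed": self.seed,
            "n_scenarios": len(self.per_scenario),
            "per_scenario": [
                {"stage": stage, "prompts": n} for stage, n in self.per_scenario
            ],
            "mean_prompts": self.mean,
            "max_prompts": self.max,
            "naive_baseline": self.baseline,
        }


def question_count_stats(
    table: StagingTable,
    stop_mode: StopMode = "grouping",
    seed: int = 0,
    rank_policy: str = "frequency-first",
) -> QuestionCountStats:
    """Run a truthful session for every grouping and tally prompt counts.

    One scenario per grouping, wildcard requirements filled with seeded
    random concrete leaf codes; deterministic given the seed.
    """
    rng = random.Random(seed)
    counts: list[tuple[str, int]] = []
    for g in table.groupings:
        scenario = scenario_for_grouping(table, g, rng)
        transcript = run_truthful_session(table, scenario, stop_mode, rank_policy)
        counts.append((transcript.report.stage, transcript.prompt_count))
    ns = [n for _, n in counts]
    return QuestionCountStats(
        per_scenario=tuple(counts),
        mean=sum(ns) / len(ns),
        max=max(ns),
        baseline=len(distinct_explicit_classifications(table)),
        stop_mode=stop_mode,
        seed=seed,
    )


# -- random table generation ------------------------------------------------


def _rows_overlap(a: dict[str, str], b: dict[str, str]) -> bool:
    """Flat-vocabulary overlap test: requirements intersect on every axis."""
    return all(
        ra == WILDCARD or rb == WILDCARD or ra == rb
        for ra, rb in ((a[k], b[k]) for k in a)
    )


def generate_random_table(
    seed: int,
    max_stages: int = 4,
    max_levels: int = 3,
    wildcard_prob: float = 0.2,
    max_rows: int = 8,
) -> StagingTable:
    """A small random staging table for property testing.

    Three axes (T, N, M with the usual M > N > T priority), 2 to
    ``max_levels`` flat classifications per axis (no hierarchies, no
    sublevels), up to ``max_rows`` pairwise non-overlapping grouping rows
    partitioned into up to ``max_stages`` stages.  Every classification
    carries a trivial affirmative question, so generated tables pass
    validation.  Deterministic given the seed.
    """
    rng = random.Random(seed)
    axes = [Axis("T", "Primary tumor", 1), Axis("N", "Regional nodes", 2), Axis("M", "Metastasis", 3)]
    classifications: list[Classification] = []
    codes: dict[str, list[str]] = {}
    for axis in axes:
        n_levels = rng.randint(2, max_levels)
        codes[axis.code] = []
        for level in range(n_levels):
            code = f"{axis.code}{level}"
            codes[axis.code].append(code)
            classifications.append(
                Classification(
                    axis=axis.code,
                    code=code,
                    level=level,
                    criteria_text=f"criterion for {code}",
                    question=Question(clauses=(f"Does criterion {code} apply?",)),
                )
            )

    rows: list[dict[str, str]] = []
    for _ in range(rng.randint(1, max_rows)):
        candidate = {
            axis.code: (
                WILDCARD
                if rng.random() < wildcard_prob
                else rng.choice(codes[axis.code])
            )
            for axis in axes
        }
        if any(_rows_overlap(candidate, r) for r in rows):
            continue
        rows.append(candidate)
    if not rows:
        rows.append({axis.code: codes[axis.code][0] for axis in axes})

    n_stages = min(rng.randint(1, max_stages), len(rows))
    # contiguous partition of the row list into stages, all non-empty
    cut_points = sorted(rng.sample(range(1, len(rows)), n_stages - 1)) if n_stages > 1 else []
    bounds = [0, *cut_points, len(rows)]
    stage_groups = []
    for i in range(n_stages):
        label = f"S{i + 1}"
        stage_rows = tuple(
            TNMGrouping(stage=label, requirements=dict(r))
            for r in rows[bounds[i] : bounds[i + 1]]
        )
        stage_groups.append(StageGroup(label=label, prognostic_order=i, groupings=stage_rows))

    return StagingTable(
        tumor_type=f"synthetic-{seed}",
        axes=axes,
        classifications=classifications,
        stage_groups=stage_groups,
    )


def enumerate_scenarios(table: StagingTable) -> list[Scenario]:
    """Every stageable concrete combination of leaf codes, in axis order."""
    from itertools import product

    axis_codes = [
        [c.code for c in table.leaf_classifications(a.code)] for a in table.axes
    ]
    scenarios = []
    for combo in product(*axis_codes):
        concrete = {a.code: code for a, code in zip(table.axes, combo)}
        try:
            scenarios.append(Scenario.from_concrete(table, concrete))
        except UnstageableError:
            continue
    return scenarios
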
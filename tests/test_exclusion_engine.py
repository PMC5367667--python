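"""Poll/rank/prompt/exclude cycle: frequencies, ranking, session semantics."""

import json

import pytest

from tnmstage import (
    TERMINAL,
    ExhaustedSessionError,
    InconsistentAnswersError,
    NotResolvedError,
    Prompt,
    Session,
    lung_table,
    rank_classifications,
    replay,
    session_transcript,
    tabulate_frequencies,
)
from tnmstage.staging_model import CandidateSet


@pytest.fixture(scope="module")
def lung():
    return lung_table()


@pytest.fixture
def session(lung):
    return Session(table=lung)


class TestFrequencies:
    @pytest.mark.parametrize(
        "axis,code,expected",
        [
            ("M", "M1a", 1),  # single "Any T Any N M1a" row
            ("M", "M1b", 1),
            ("T", "Tis", 1),  # only the stage-0 row
            ("M", "M0", 26),
            ("N", "N0", 8),
            ("N", "N1", 6),
            ("N", "N2", 6),
            ("N", "N3", 6),
            ("T", "T1a", 4),
            ("T", "T4", 4),
            ("T", "T1", 0),  # parents are never explicit requirements here
        ],
    )
    def test_full_lung_counts(self, session, axis, code, expected):
        freqs = tabulate_frequencies(session.candidates)
        assert freqs.count(axis, code) == expected

    def test_axis_sums_to_candidate_total(self, session, lung):
        freqs = tabulate_frequencies(session.candidates)
        for axis in lung.axes:
            explicit = sum(
                n for (a, _), n in freqs.counts.items() if a == axis.code
            )
            assert explicit + freqs.wildcard_rows[axis.code] == len(session.candidates)
        assert freqs.wildcard_rows == {"T": 2, "N": 2, "M": 0}

    def test_empty_candidate_set_is_exhausted(self, lung):
        with pytest.raises(ExhaustedSessionError):
            tabulate_frequencies(CandidateSet(lung, []))


class TestRanking:
    def test_full_lung_order(self, session, lung):
        freqs = tabulate_frequencies(session.candidates)
        order = [c.code for c in rank_classifications(freqs, lung)]
        # ascending count; ties M before N before T, then descending level
        # and sublevel — so the rare metastasis codes lead
        assert order == [
            "M1b", "M1a", "Tis", "TX",
            "T4", "T3", "T2b", "T2a", "T1b", "T1a",
            "N3", "N2", "N1", "N0", "M0",
        ]

    def test_iiib_subset_puts_rare_n2_before_common_n3(self, lung):
        iiib = CandidateSet(lung, [("IIIB", i) for i in range(7)])
        freqs = tabulate_frequencies(iiib)
        assert freqs.count("N", "N2") == 1
        assert freqs.count("N", "N3") == 6
        order = [c.code for c in rank_classifications(freqs, lung)]
        assert order.index("N2") < order.index("N3")

    def test_single_row_ranking_lists_each_explicit_code_m_first(self, lung):
        one = CandidateSet(lung, [("IIB", 0)])  # T2b N1 M0
        order = [c.code for c in rank_classifications(tabulate_frequencies(one), lung)]
        assert order == ["M0", "N1", "T2b"]

    def test_axis_first_policy_still_leads_with_metastasis(self, session, lung):
        freqs = tabulate_frequencies(session.candidates)
        order = [c.code for c in rank_classifications(freqs, lung, policy="axis-first")]
        assert order[:3] == ["M1b", "M1a", "M0"]


class TestPrompting:
    def test_fresh_session_prompts_distant_metastasis(self, session):
        prompt = session.next_prompt()
        assert isinstance(prompt, Prompt)
        assert prompt.classification.axis == "M"
        assert prompt.classification.code == "M1b"
        assert prompt.rank_trace[0].code == "M1b"

    def test_two_ia_rows_stage_resolved_is_terminal(self, lung):
        s = Session(table=lung, stop_mode="stage")
        s.candidates = CandidateSet(lung, [("IA", 0), ("IA", 1)])
        assert s.next_prompt() is TERMINAL

    def test_two_ia_rows_grouping_resolved_prompts_t_axis(self, lung):
        s = Session(table=lung, stop_mode="grouping")
        s.candidates = CandidateSet(lung, [("IA", 0), ("IA", 1)])
        prompt = s.next_prompt()
        assert prompt.classification.axis == "T"
        assert prompt.classification.code in ("T1a", "T1b")

    def test_universally_matched_codes_are_settled_not_prompted(self, lung):
        s = Session(table=lung)
        s.candidates = CandidateSet(lung, [("IA", 0), ("IA", 1)])
        settled = {(c.axis, c.code) for c in s.settled_classifications()}
        assert ("N", "N0") in settled and ("M", "M0") in settled
        prompt = s.next_prompt()
        assert (prompt.classification.axis, prompt.classification.code) not in settled

    def test_exhausted_session_cannot_be_prompted(self, lung):
        s = Session(table=lung)
        s.candidates = CandidateSet(lung, [])
        with pytest.raises(ExhaustedSessionError):
            s.next_prompt()


class TestAnswers:
    def test_yes_to_m1b_resolves_stage_iv(self, session):
        session.apply_answer("M", "M1b", True)
        assert len(session.candidates) == 1
        assert session.candidates.stages() == ["IV"]

    def test_no_to_m1b_drops_exactly_one_row(self, session):
        session.apply_answer("M", "M1b", False)
        assert len(session.candidates) == 27

    def test_exclusion_sequence_narrows_to_iiib(self, session):
        session.apply_answer("M", "M1b", False)
        session.apply_answer("M", "M1a", False)
        session.apply_answer("N", "N3", True)
        assert len(session.candidates) == 6
        assert session.candidates.stages() == ["IIIB"]

    def test_excluding_a_parent_removes_all_sublevels(self, session):
        session.apply_answer("T", "T1", False)
        kept = {g.requirements["T"] for g in session.candidates.groupings()}
        assert not kept & {"T1", "T1a", "T1b"}
        assert len(session.candidates) == 20  # 28 - 8 rows requiring T1a/T1b

    def test_selecting_a_child_keeps_bare_parent_rows(self, minimal_doc):
        # minimal table's single row requires bare T1; selecting T1a keeps it
        from tnmstage import load_table

        doc = minimal_doc
        doc["classifications"].append(
            {"axis": "T", "code": "T1a", "level": 1, "sublevel": "a", "parent": "T1",
             "criteria": "small-a",
             "question": {"clauses": ["Is it T1a-sized?"], "connective": "OR",
                          "affirmative": True}}
        )
        table = load_table(doc)
        s = Session(table=table)
        s.apply_answer("T", "T1a", True)
        assert len(s.candidates) == 1

    def test_direct_selection_of_t3(self, session):
        session.select_direct("T", "T3")
        assert len(session.candidates) == 6  # 4 explicit T3 rows + 2 "Any T" rows
        assert session.history[-1].kind == "direct"

    def test_contradictory_answers_raise_but_stay_recoverable(self, session):
        session.apply_answer("M", "M1b", True)
        with pytest.raises(InconsistentAnswersError) as exc:
            session.apply_answer("M", "M0", True)
        assert exc.value.step.code == "M0"
        assert len(session.candidates) == 0
        assert session.undo()
        assert len(session.candidates) == 1  # back to the consistent state

    def test_wildcard_rows_survive_both_answers_on_their_axis(self, lung):
        for answer in (True, False):
            s = Session(table=lung)
            s.apply_answer("T", "T3", answer)
            assert {("IV", 0), ("IV", 1)} <= set(s.candidates.members)


class TestHistory:
    def test_undo_restores_the_full_set(self, session):
        session.apply_answer("M", "M1b", False)
        session.undo()
        assert len(session.candidates) == 28

    def test_select_then_undo_is_identity(self, session):
        before = list(session.candidates.members)
        session.select_direct("T", "T3")
        session.undo()
        assert session.candidates.members == before

    def test_three_answers_two_undos_one_redo(self, session):
        session.apply_answer("M", "M1b", False)
        session.apply_answer("M", "M1a", False)
        after_two = list(session.candidates.members)
        session.apply_answer("N", "N3", True)
        assert session.undo() and session.undo()
        assert session.redo()
        assert session.candidates.members == after_two

    def test_undo_on_fresh_session_is_a_signalled_noop(self, session):
        assert session.undo() is False
        assert len(session.candidates) == 28

    def test_new_step_clears_the_redo_stack(self, session):
        session.apply_answer("M", "M1b", False)
        session.undo()
        session.apply_answer("M", "M1a", False)
        assert session.redo() is False

    def test_replaying_history_reproduces_candidates(self, session):
        session.apply_answer("M", "M1b", False)
        session.apply_answer("M", "M1a", False)
        session.select_direct("T", "T3")
        assert replay(session).members == session.candidates.members


class TestResolve:
    def test_single_grouping_report(self, lung):
        s = Session(table=lung)
        s.candidates = CandidateSet(lung, [("IIB", 0)])  # T2b N1 M0
        report = s.resolve()
        assert report.stage == "IIB"
        assert report.resolution("T").codes == ("T2b",)
        assert report.resolution("N").codes == ("N1",)
        assert report.resolution("M").codes == ("M0",)
        assert "more than 5 cm but 7 cm or less" in report.criteria["T:T2b"]

    def test_stage_iv_wildcards_report_alternatives_and_any(self, lung):
        s = Session(table=lung, stop_mode="stage")
        s.candidates = CandidateSet(lung, [("IV", 0), ("IV", 1)])
        report = s.resolve()
        assert report.stage == "IV"
        assert set(report.resolution("M").codes) == {"M1a", "M1b"}
        assert report.resolution("T").codes == ()
        assert report.resolution("T").render() == "any T"

    def test_selected_code_fills_a_wildcard_only_axis(self, lung):
        s = Session(table=lung, stop_mode="stage")
        s.select_direct("T", "T3")
        s.apply_answer("M", "M1a", True)
        report = s.resolve()
        assert report.stage == "IV"
        assert report.resolution("T").codes == ("T3",)
        assert report.resolution("T").wildcard is True

    def test_fresh_session_is_not_resolved(self, session):
        with pytest.raises(NotResolvedError):
            session.resolve()

    def test_report_renders_answer_trail(self, session):
        session.apply_answer("M", "M1b", True)
        text = session.resolve().render()
        assert "Anatomic stage: IV" in text
        assert "selected M:M1b (prompt)" in text


def test_transcript_is_byte_deterministic(lung):
    def run():
        s = Session(table=lung)
        s.apply_answer("M", "M1b", False)
        s.apply_answer("M", "M1a", False)
        s.apply_answer("N", "N3", True)
        s.apply_answer("T", "T4", True)
        return json.dumps(session_transcript(s, s.resolve()), sort_keys=True)

    assert run() == run()


def test_monotone_shrinkage_across_any_answer_sequence(lung):
    s = Session(table=lung)
    sizes = [len(s.candidates)]
    for axis, code, ans in [
        ("M", "M1b", False), ("T", "T2", False), ("N", "N0", True), ("T", "T3", True),
    ]:
        s.apply_answer(axis, code, ans)
        sizes.append(len(s.candidates))
    assert all(a >= b for a, b in zip(sizes, sizes[1:]))
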
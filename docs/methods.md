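# Methods

## The exclusionary staging cycle

A staging table for one tumor type defines axes (T, N, M, optionally
prognostic-factor axes), a classification vocabulary per axis with
verbatim criteria and yes/no question decompositions, and an ordered list
of stage groups, each holding TNM grouping rows (a requirement per axis:
a specific code or a wildcard).

A session holds the set of still-viable rows (initially all of them) and
cycles:

1. **Poll.** Count, per (axis, code), the rows whose requirement on that
   axis is exactly that code. Wildcard requirements contribute to no
   code's count: a wildcard row is consistent with every classification on
   its axis, so no answer about that axis can nullify it. Per axis,
   explicit counts plus wildcard rows always sum to the candidate total.
2. **Rank.** Sort the tabulated codes by ascending count; break ties by
   axis priority (M before N before T before prognostic axes), then by
   descending level, then descending sublevel. Codes with zero explicit
   occurrences are omitted: excluding such a code removes nothing, so a
   prompt about it could not be guaranteed informative (and could repeat).
   Frequency as the primary key is what makes staging open with the
   distant-metastasis questions on the lung table — M1b and M1a each back
   a single stage-IV row. The alternative reading, axis priority as the
   primary key, is available as `rank_policy="axis-first"`.
3. **Prompt.** Walk the ranking and emit the first *eligible* code: a code
   every remaining candidate matches is skipped (asking would be
   uninformative) and auto-settled into the terminal report instead. Any
   emitted prompt is guaranteed informative: "no" removes its ≥ 1 explicit
   rows, and since it is not universally matched, "yes" removes at least
   one row too.
4. **Exclude.** "Yes" (selection) retains rows that match the code on its
   axis; "no" (exclusion) removes rows whose explicit requirement is the
   code or one of its hierarchical descendants. Wildcard rows survive
   both.

The cycle stops when exactly one row remains (`grouping` mode, the
default, so reports always carry fully resolved classifications) or when
all surviving rows share one stage label (`stage` mode, in which report
entries may list alternatives, e.g. stage IV's M as M1a/M1b with T and N
reported as "any").

### Matching and hierarchy

`matches(grouping, axis, code)` is true iff the row's requirement is the
wildcard, equals the code, is the code's parent (a row requiring T1
admits a T1a finding), or is one of the code's children (selecting T1
keeps rows requiring T1a or T1b). Selecting a child keeps rows requiring
the bare parent; excluding a parent removes the parent and all its
sublevels, while excluding one sublevel leaves the bare-parent rows in
play. "Not assessable" codes (TX/NX) are ordinary classifications at the
bottom of their axis's level order; how a genuinely unassessable finding
should interact with prompting is not modelled beyond that.

### Sessions, history, and failure modes

Every step records the pre- and post-step candidate sets, so undo/redo is
lossless and replaying the history from the full set reproduces the
current candidates exactly. An answer that empties the candidate set is
committed and then raises `InconsistentAnswersError` naming the step; one
undo returns to the last consistent state. Mutually exclusive selections
across history (reachable only via direct selection) surface the same
way. If no informative prompt remains while the stop condition is unmet —
possible only in authored tables with overlapping or hierarchy-ambiguous
rows — the session raises `StalledSessionError` rather than guessing.

### Question polarity

Criteria written as negations ("No distant metastasis") are stored with
an affirmative question rewrite ("Is there evidence of distant
metastasis?") and `affirmative: false`; the raw interactive answer is
inverted before it becomes a selection or exclusion. Batch files and the
programmatic API always speak in selection terms (yes = the
classification applies), so polarity never touches replayed transcripts.

## Parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `stop_mode` | `grouping` | stop at one row vs one stage label |
| `rank_policy` | `frequency-first` | ascending count primary key; `axis-first` makes M > N > T primary |
| `seed` (simulator) | 0 | concrete leaf codes filled under wildcard requirements |

The bundled lung table is fixed data, not a parameter: 3 axes, 20
classifications (T: TX, T0, Tis, T1, T1a, T1b, T2, T2a, T2b, T3, T4;
N: NX, N0–N3; M: M0, M1, M1a, M1b), 28 groupings over 9 stages, 15
distinct explicitly-required codes.

## The oracle and the simulator

`lookup_stage` is the conventional combinatorial route, implemented as
the dumbest possible linear scan over the stage array in prognostic
order, so it can serve as an independent reference for the engine. With
overlapping rows (lintable, never generated) it returns the first match.

The truthful responder fixes one concrete classification per axis and
answers each prompt "yes" iff the prompted code equals the true code or
is one of its ancestors. Scenarios exercising wildcard rows fill the
wildcard axes with seeded random concrete leaf codes. Correctness is the
equivalence: for every valid scenario, the session's reported stage
equals the linear-scan lookup.

`question_count_stats` runs one truthful session per grouping and reports
per-scenario prompt counts, mean, and max against the naive baseline —
the count of distinct explicit classifications, i.e. the criteria a
conventional session must review one by one. On the lung table the mean
is ≈ 8.6 prompts and the max 12, versus a baseline of 15.

## Synthetic tables

`generate_random_table(seed)` emulates small authored staging tables for
property testing: three axes with 2–3 flat classifications each, up to 8
grouping rows with 20 % wildcard requirements, partitioned into up to 4
stages. Two real-table features are deliberately absent: classification
hierarchies and overlapping rows (rows are rejected unless their
requirements are disjoint on at least one axis). Passing property tests
on these tables therefore demonstrates the core poll/rank/prompt/exclude
semantics and its oracle equivalence, not the hierarchy corner cases —
those are pinned by the lung-table tests (T1/T1a/T1b, M1/M1a/M1b) — and
not behavior on ill-formed overlapping arrays, which the validator lints
and the engine refuses to resolve by guessing. Real staging tables also
carry clinically meaningful criteria text; synthetic questions are
placeholders, so nothing about question wording is exercised there.

Problem sizes used by the test suite and the acceptance script — 28 lung
scenarios, 200 random tables (≈ 1100 scenarios), 30-table round-trip
corpora — were chosen to enumerate the relevant spaces exhaustively; all
of it completes in seconds.

## Numerical and design notes

- All ordering is total and deterministic: stage labels are opaque
  strings ordered only by document position (roman-numeral parsing would
  choke on "Occult" and "0"); within the ranking, ties beyond
  (count, axis, level, sublevel) are impossible because (axis, level,
  sublevel) is unique per code.
- Transcripts serialize with sorted keys; identical table + answer
  sequence gives byte-identical JSON.
- Documents are UTF-8; "≤"/"≥" are permitted in clause text. Criteria are
  opaque verbatim strings attached to questions — the engine never
  interprets clinical text, and question decompositions are authored
  data, not parsed output.
- The catalogue maps (tumor type, selector tags) to a document, making
  subtype/location/age/phase selection pure data; only the lung document
  ships.

## Known limitations

- Prognostic-factor axes are schema-supported but no bundled table
  exercises them.
- Untruthful or uncertain responders are out of scope; the simulator
  models perfect information.
- The question-ordering rule is fixed (frequency, then spread, then
  level); no information-gain optimization is attempted.
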
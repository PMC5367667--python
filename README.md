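# tnmstage

An exclusionary engine for TNM cancer staging.

TNM staging classifies a cancer by primary tumor extent (T), regional
lymph-node spread (N), and distant metastasis (M), then maps the resulting
TNM grouping to an anatomic stage (Occult, 0, IA … IV) through a tabular
stage array. The conventional route — pick a T, pick an N, pick an M, look
the triple up — forces a scrupulous review of every classification's
criteria, because successive T and N classifications are often neither
graded nor mutually exclusive.

`tnmstage` inverts the process. Starting from the full set of TNM
groupings, it repeatedly:

1. **polls** the still-viable groupings and tabulates how often each
   classification is explicitly required;
2. **ranks** the classifications in ascending order of frequency, breaking
   ties by extent of spread (M > N > T) and by descending level within an
   axis (N3 > N2 > N1 > N0);
3. **prompts** a yes/no question for the first-ranked classification
   (complex criteria are pre-decomposed into disambiguated clauses);
4. **excludes** the groupings the answer nullifies — a "yes" retains only
   groupings containing the classification, a "no" removes those that
   require it; "Any T"-style wildcard rows survive either answer.

Rare classifications are asked about first because either answer is
maximally decisive: a "yes" ends the session almost immediately, a "no"
costs one row. On the bundled lung table the two stage IV rows each
require a unique metastasis code, so every session opens with the
distant-metastasis questions. The cycle stops when one grouping (or,
optionally, one stage) remains, and the terminal report lists the stage,
the resolved classifications with their criteria, and the answer trail.
Sessions are fully replayable, with lossless undo/redo.

The package ships the staging table for cancer of the lung (7th-edition
vocabulary: TX–T4 with T1/T2 sublevels, NX–N3, M0–M1b; 28 groupings over
9 stages). The JSON document format, schema, and catalogue mechanism
(`docs/table-format.md`) support authoring tables for other tumor types,
including prognostic-factor axes beyond T/N/M.

## Worked example

Stage a T4 N3 M0 tumor from a batch answer file:

```sh
$ cat ans.csv
axis,code,answer
M,M1b,no
M,M1a,no
N,N3,yes
T,T4,yes
$ tnmstage stage --tumor-type lung --batch ans.csv
Anatomic stage: IIIB
  T: T4
      T4: Tumor of any size that invades any of the following: mediastinum, heart, great vessels, trachea, recurrent laryngeal nerve, esophagus, vertebral body, carina, separate tumor nodule(s) in a different ipsilateral lobe
  N: N3
      N3: Metastasis in contralateral mediastinal, contralateral hilar, ipsilateral or contralateral scalene, or supraclavicular lymph node(s)
  M: M0
      M0: No distant metastasis
Answer trail:
  excluded M:M1b (prompt)
  excluded M:M1a (prompt)
  selected N:N3 (prompt)
  selected T:T4 (prompt)
```

Four answers resolved the grouping: after the two metastasis exclusions the
26 M0 rows remain, "yes" to N3 narrows them to the six N3 rows of stage
IIIB, and "yes" to T4 pins the single grouping T4 N3 M0. Note the engine
never asked about M0 — once every surviving row requires it, the question
would be uninformative and the classification is settled into the report
automatically.

The same library surface is available programmatically:

```python
from tnmstage import Session, lung_table

session = Session(table=lung_table())
prompt = session.next_prompt()           # M1b: the rarest, most decisive code
session.apply_answer("M", "M1b", True)   # select it
print(session.resolve().stage)           # -> IV
```

`tnmstage simulate` measures how much review the exclusionary order saves.
For truthful sessions over all 28 lung groupings:

```sh
$ tnmstage simulate --tumor-type lung --seed 0
{
  "max_prompts": 12,
  "mean_prompts": 8.571428571428571,
  "naive_baseline": 15,
  ...
}
```

A mean of 8.6 prompts (worst case 12) against the 15 distinct
classification criteria a conventional session must review one by one.

`tnmstage validate table.json` checks a document: reference integrity,
duplicate rows, missing questions (errors), plus question-style and
row-overlap lints (`NEGATIVE_POLARITY`, `MIXED_BOOLEAN`,
`OVERLAPPING_GROUPINGS`).

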
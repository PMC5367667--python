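# Staging-table document format

One JSON document per (tumor type × selector combination), UTF-8,
`"format": "tnmstage-table/1"`. The bundled example is
`src/tnmstage/data/lung.json`.

## Top level

| Field | Type | Notes |
| --- | --- | --- |
| `format` | string | `"tnmstage-table/1"` (informational) |
| `tumor_type` | string | required |
| `selectors` | object | optional flat string tags (subtype, anatomic location, age limit, phase) |
| `axes` | array | required; must include T, N, M; prognostic-factor axes may be added |
| `classifications` | array | required |
| `stage_groups` | array | required; document order = declining-prognosis order |

## `axes[]`

| Field | Type | Notes |
| --- | --- | --- |
| `code` | string | unique (`"T"`, `"N"`, `"M"`, or a prognostic-factor code) |
| `name` | string | optional display name |
| `rank` | int | extent-of-spread priority, higher outranks lower (M > N > T); ranks must be distinct |

## `classifications[]`

| Field | Type | Notes |
| --- | --- | --- |
| `axis` | string | must name a declared axis |
| `code` | string | unique within the axis (e.g. `"T2a"`) |
| `level` | int | total order within the axis; put TX/NX below level 0 |
| `sublevel` | string | optional letter; orders within a level (a < b < c < d) |
| `parent` | string | optional coarser code on the same axis (T1a → T1) |
| `criteria` | string | verbatim defining criteria (opaque to the engine) |
| `question` | object | yes/no decomposition of the criteria |

### `question`

| Field | Type | Notes |
| --- | --- | --- |
| `clauses` | array of strings | ≥ 1 atomic yes/no items |
| `connective` | `"OR"` \| `"AND"` | joins the clauses (default `"OR"`) |
| `affirmative` | bool | default `true`; `false` means the question is the affirmative rewrite of a negative definition, and a raw "yes" answer *excludes* the classification |

Style rules enforced as lints, not errors: single-clause questions must
not be phrased as negations (`NEGATIVE_POLARITY` — rewrite affirmatively
and set `affirmative: false`), and clauses must not embed uppercase
`AND`/`OR` connectives (`MIXED_BOOLEAN` — decompose instead).

## `stage_groups[]`

| Field | Type | Notes |
| --- | --- | --- |
| `label` | string | unique, opaque (`"Occult"`, `"0"`, `"IA"`, … `"IV"`) |
| `groupings` | array | rows; each row maps **every** axis code to a classification code or the wildcard `"*"` ("Any T" / "Any N") |

Rows keep their document order; stage lookup scans stages and rows in
that order. Identical rows are an error (`DUPLICATE_GROUPING`); distinct
rows satisfiable by one concrete finding are linted
(`OVERLAPPING_GROUPINGS`).

## Catalogue

`catalogue.json` (`"format": "tnmstage-catalogue/1"`) maps tumor type +
selector answers to a document, relative to the catalogue file:

```json
{
  "format": "tnmstage-catalogue/1",
  "entries": [
    {"tumor_type": "lung", "selectors": {}, "document": "lung.json"}
  ]
}
```

A lookup matches an entry when the tumor type and the full selector set
are equal; anything else lists the available selector sets.
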
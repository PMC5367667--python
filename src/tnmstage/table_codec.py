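"""Read, write, and validate staging-table documents.

A staging table is stored as a single JSON document per
(tumor type x selector combination).  A catalogue file maps a tumor type
plus selector answers (subtype, anatomic location, age limit, clinical vs
pathologic phase) to the document that covers it, so the engine stays
table-agnostic.  The bundled ``lung.json`` fixture transcribes the
anatomic-stage groupings and criteria for cancer of the lung.

Document layout (see ``docs/table-format.md`` for the full schema)::

    {
      "format": "tnmstage-table/1",
      "tumor_type": "lung",
      "selectors": {},
      "axes": [{"code": "T", "name": "Primary tumor", "rank": 1}, ...],
      "classifications": [
        {"axis": "T", "code": "T1a", "level": 2, "sublevel": "a",
         "parent": "T1", "criteria": "...",
         "question": {"clauses": ["..."], "connective": "OR",
                      "affirmative": true}},
        ...
      ],
      "stage_groups": [
        {"label": "IA", "groupings": [{"T": "T1a", "N": "N0", "M": "M0"},
                                      {"T": "T1b", "N": "N0", "M": "M0"}]},
        ...
      ]
    }

A requirement value of ``"*"`` is the wildcard ("Any T" / "Any N").
Errors block loading; lints (question-style and overlap warnings) do not.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Union

from .staging_model import (
    WILDCARD,
    Axis,
    CandidateSet,
    Classification,
    Question,
    StageGroup,
    StagingTable,
    TNMGrouping,
    is_descendant,
)

FORMAT_TAG = "tnmstage-table/1"
CATALOGUE_TAG = "tnmstage-catalogue/1"

DocumentSource = Union[dict, str, Path]


class TableLoadError(ValueError):
    """A document that cannot be loaded as a staging table.

    ``path`` points at the offending location within the document.
    """

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


@dataclass(frozen=True)
class ValidationIssue:
    """One finding from :func:`validate_table`.

    ``severity`` is ``"error"`` (the table violates a hard invariant) or
    ``"lint"`` (a question-style or overlap warning that does not block
    use).  ``code`` is a stable identifier; ``path`` locates the finding.
    """

    severity: str
    code: str
    path: str
    message: str


# single-clause questions phrased as negations defeat the point of the
# affirmative rewrite; multi-clause decompositions may legitimately embed
# qualifiers like "does not involve the entire lung"
_NEGATION = re.compile(r"\b(no|not|cannot|never)\b", re.IGNORECASE)
# an uppercase Boolean connective inside a clause means the definition was
# never actually decomposed
_EMBEDDED_BOOLEAN = re.compile(r"\b(AND|OR)\b")


def _as_document(source: DocumentSource) -> dict:
    if isinstance(source, dict):
        return source
    text = Path(source).read_text(encoding="utf-8")
    return json.loads(text)


def _require(doc: dict, key: str, typ, path: str):
    if key not in doc:
        raise TableLoadError(f"{path}.{key}", "missing required field")
    value = doc[key]
    if not isinstance(value, typ):
        raise TableLoadError(
            f"{path}.{key}", f"expected {typ.__name__}, got {type(value).__name__}"
        )
    return value


def load_table(source: DocumentSource) -> StagingTable:
    """Load a staging table from a JSON document, dict, or path.

    Loading is deterministic and order-preserving: axes, classifications,
    stage labels, and grouping rows keep their document order, which fixes
    the prognostic ordering of stages.

    Raises
    ------
    TableLoadError
        On schema violations, undefined classification references,
        duplicate stage labels, or missing T/N/M axes; the error names the
        document path of the offence.
    """
    doc = _as_document(source)
    if not isinstance(doc, dict):
        raise TableLoadError("$", "document root must be an object")
    tumor_type = _require(doc, "tumor_type", str, "$")
    selectors = doc.get("selectors", {})
    if not isinstance(selectors, dict) or not all(
        isinstance(k, str) and isinstance(v, str) for k, v in selectors.items()
    ):
        raise TableLoadError("$.selectors", "selectors must map strings to strings")

    axes = []
    axis_codes: set[str] = set()
    for i, adoc in enumerate(_require(doc, "axes", list, "$")):
        path = f"$.axes[{i}]"
        code = _require(adoc, "code", str, path)
        if code in axis_codes:
            raise TableLoadError(path, f"duplicate axis code {code!r}")
        axis_codes.add(code)
        axes.append(
            Axis(code=code, name=adoc.get("name", code), rank=_require(adoc, "rank", int, path))
        )
    for principal in ("T", "N", "M"):
        if principal not in axis_codes:
            raise TableLoadError("$.axes", f"principal axis {principal!r} is missing")
    ranks = [a.rank for a in axes]
    if len(set(ranks)) != len(ranks):
        raise TableLoadError("$.axes", "axis ranks must form a total order")

    classifications = []
    class_codes: set[tuple[str, str]] = set()
    for i, cdoc in enumerate(_require(doc, "classifications", list, "$")):
        path = f"$.classifications[{i}]"
        axis = _require(cdoc, "axis", str, path)
        if axis not in axis_codes:
            raise TableLoadError(f"{path}.axis", f"undefined axis {axis!r}")
        code = _require(cdoc, "code", str, path)
        if (axis, code) in class_codes:
            raise TableLoadError(path, f"duplicate classification {code!r} on axis {axis!r}")
        class_codes.add((axis, code))
        question = None
        if "question" in cdoc and cdoc["question"] is not None:
            qdoc = cdoc["question"]
            clauses = _require(qdoc, "clauses", list, f"{path}.question")
            if not clauses or not all(isinstance(c, str) for c in clauses):
                raise TableLoadError(
                    f"{path}.question.clauses", "need at least one string clause"
                )
            connective = qdoc.get("connective", "OR")
            if connective not in ("OR", "AND"):
                raise TableLoadError(
                    f"{path}.question.connective", f"must be OR or AND, got {connective!r}"
                )
            question = Question(
                clauses=tuple(clauses),
                connective=connective,
                affirmative=bool(qdoc.get("affirmative", True)),
            )
        classifications.append(
            Classification(
                axis=axis,
                code=code,
                level=_require(cdoc, "level", int, path),
                sublevel=cdoc.get("sublevel"),
                parent=cdoc.get("parent"),
                criteria_text=cdoc.get("criteria", ""),
                question=question,
            )
        )
    # parent references must exist on the same axis
    for i, cls in enumerate(classifications):
        if cls.parent is not None and (cls.axis, cls.parent) not in class_codes:
            raise TableLoadError(
                f"$.classifications[{i}].parent",
                f"parent {cls.parent!r} undefined on axis {cls.axis!r}",
            )

    stage_groups = []
    labels: set[str] = set()
    sg_docs = _require(doc, "stage_groups", list, "$")
    for i, sdoc in enumerate(sg_docs):
        path = f"$.stage_groups[{i}]"
        label = _require(sdoc, "label", str, path)
        if label in labels:
            raise TableLoadError(f"{path}.label", f"duplicate stage label {label!r}")
        labels.add(label)
        rows = []
        gdocs = _require(sdoc, "groupings", list, path)
        for j, gdoc in enumerate(gdocs):
            gpath = f"{path}.groupings[{j}]"
            if not isinstance(gdoc, dict):
                raise TableLoadError(gpath, "grouping must be an object")
            if set(gdoc) != axis_codes:
                raise TableLoadError(
                    gpath, f"grouping must give exactly one requirement per axis {sorted(axis_codes)}"
                )
            for axis, req in gdoc.items():
                if req != WILDCARD and (axis, req) not in class_codes:
                    raise TableLoadError(
                        f"{gpath}.{axis}", f"undefined classification {req!r} on axis {axis!r}"
                    )
            # keep requirements in table axis order for stable rendering
            rows.append(TNMGrouping(stage=label, requirements={a.code: gdoc[a.code] for a in axes}))
        stage_groups.append(StageGroup(label=label, prognostic_order=i, groupings=tuple(rows)))

    if not any(sg.groupings for sg in stage_groups):
        raise TableLoadError("$.stage_groups", "the union of all groupings is empty")

    return StagingTable(
        tumor_type=tumor_type,
        selectors=dict(selectors),
        axes=axes,
        classifications=classifications,
        stage_groups=stage_groups,
    )


def write_table(table: StagingTable) -> dict:
    """Serialize a table back to its document form.

    Round-trip law: ``load_table(write_table(t))`` is structurally equal
    to ``t``, including grouping order within each stage.
    """
    return {
        "format": FORMAT_TAG,
        "tumor_type": table.tumor_type,
        "selectors": dict(table.selectors),
        "axes": [{"code": a.code, "name": a.name, "rank": a.rank} for a in table.axes],
        "classifications": [
            {
                "axis": c.axis,
                "code": c.code,
                "level": c.level,
                **({"sublevel": c.sublevel} if c.sublevel else {}),
                **({"parent": c.parent} if c.parent else {}),
                "criteria": c.criteria_text,
                **(
                    {
                        "question": {
                            "clauses": list(c.question.clauses),
                            "connective": c.question.connective,
                            "affirmative": c.question.affirmative,
                        }
                    }
                    if c.question
                    else {}
                ),
            }
            for c in table.classifications
        ],
        "stage_groups": [
            {
                "label": sg.label,
                "groupings": [dict(g.requirements) for g in sg.groupings],
            }
            for sg in table.stage_groups
        ],
    }


def dump_table(table: StagingTable, path: Union[str, Path]) -> None:
    Path(path).write_text(
        json.dumps(write_table(table), indent=2, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )


def _requirements_intersect(table: StagingTable, a: TNMGrouping, b: TNMGrouping) -> bool:
    """True iff some concrete finding could satisfy both rows on every axis."""
    for axis in a.requirements:
        ra, rb = a.requirement(axis), b.requirement(axis)
        if ra == WILDCARD or rb == WILDCARD or ra == rb:
            continue
        if is_descendant(table, axis, ra, rb) or is_descendant(table, axis, rb, ra):
            continue
        return False
    return True


def validate_table(table: StagingTable) -> list[ValidationIssue]:
    """Check a loaded table; returns issues rather than raising.

    Errors: a classification used in a grouping with no question
    (MISSING_QUESTION), two identical rows (DUPLICATE_GROUPING).
    Lints: single-clause questions phrased as negations
    (NEGATIVE_POLARITY), clauses embedding an undecomposed Boolean
    connective (MIXED_BOOLEAN), and distinct rows that a single concrete
    finding could satisfy simultaneously (OVERLAPPING_GROUPINGS).
    """
    issues: list[ValidationIssue] = []

    used: set[tuple[str, str]] = set()
    for g in table.groupings:
        for axis, req in g.requirements.items():
            if req != WILDCARD:
                used.add((axis, req))
    for axis, code in sorted(used):
        cls = table.classification(axis, code)
        if cls.question is None:
            issues.append(
                ValidationIssue(
                    "error",
                    "MISSING_QUESTION",
                    f"classification {axis}:{code}",
                    f"{code!r} is required by a grouping but has no yes/no question",
                )
            )

    seen: dict[tuple, str] = {}
    rows = [(sg.label, j, g) for sg in table.stage_groups for j, g in enumerate(sg.groupings)]
    for label, j, g in rows:
        key = g.key()
        where = f"stage {label} row {j}"
        if key in seen:
            issues.append(
                ValidationIssue(
                    "error",
                    "DUPLICATE_GROUPING",
                    where,
                    f"identical grouping already listed at {seen[key]}",
                )
            )
        else:
            seen[key] = where

    for i, (la, ja, ga) in enumerate(rows):
        for lb, jb, gb in rows[i + 1 :]:
            if ga.key() == gb.key():
                continue  # reported as DUPLICATE_GROUPING
            if _requirements_intersect(table, ga, gb):
                issues.append(
                    ValidationIssue(
                        "lint",
                        "OVERLAPPING_GROUPINGS",
                        f"stage {la} row {ja} / stage {lb} row {jb}",
                        "a single concrete finding satisfies both rows; "
                        "stage lookup takes the first in prognostic order",
                    )
                )

    for i, cls in enumerate(table.classifications):
        q = cls.question
        if q is None:
            continue
        where = f"classification {cls.axis}:{cls.code}"
        if len(q.clauses) == 1 and _NEGATION.search(q.clauses[0]):
            issues.append(
                ValidationIssue(
                    "lint",
                    "NEGATIVE_POLARITY",
                    where,
                    "single-clause question is phrased as a negation; "
                    "rewrite affirmatively and flip the question's polarity",
                )
            )
        for clause in q.clauses:
            if _EMBEDDED_BOOLEAN.search(clause):
                issues.append(
                    ValidationIssue(
                        "lint",
                        "MIXED_BOOLEAN",
                        where,
                        "clause embeds an uppercase Boolean connective; "
                        "decompose it into separate clauses",
                    )
                )
                break

    return issues


# -- bundled fixtures and the catalogue -------------------------------------


def bundled_path(name: str) -> Path:
    """Filesystem path of a bundled data file (e.g. ``"lung.json"``)."""
    return Path(str(resources.files("tnmstage").joinpath("data", name)))


def load_bundled(name: str) -> StagingTable:
    return load_table(bundled_path(name))


def lung_table() -> StagingTable:
    """The bundled staging table for cancer of the lung."""
    return load_bundled("lung.json")


class CatalogueError(LookupError):
    pass


def resolve_catalogue(
    tumor_type: str,
    selectors: dict[str, str] | None = None,
    catalogue: Union[str, Path, None] = None,
) -> Path:
    """Map a tumor type plus selector answers to a table document path.

    The catalogue is the data form of the app-style secondary-options
    screen: some tumor types need a subtype, anatomic location, age limit,
    or staging phase to pick the right table.  Paths in the catalogue are
    relative to the catalogue file itself.
    """
    cat_path = Path(catalogue) if catalogue is not None else bundled_path("catalogue.json")
    doc = json.loads(cat_path.read_text(encoding="utf-8"))
    selectors = selectors or {}
    hits = [
        e
        for e in doc.get("entries", [])
        if e["tumor_type"] == tumor_type and e.get("selectors", {}) == selectors
    ]
    if len(hits) == 1:
        return (cat_path.parent / hits[0]["document"]).resolve()
    offered = [
        (e["tumor_type"], e.get("selectors", {}))
        for e in doc.get("entries", [])
        if e["tumor_type"] == tumor_type
    ]
    if not offered:
        raise CatalogueError(f"no catalogue entry for tumor type {tumor_type!r}")
    raise CatalogueError(
        f"selectors {selectors!r} do not identify a unique table for "
        f"{tumor_type!r}; available selector sets: {offered!r}"
    )


def structurally_equal(a: StagingTable, b: StagingTable) -> bool:
    """Field-by-field equality used by round-trip tests."""
    return write_table(a) == write_table(b)
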
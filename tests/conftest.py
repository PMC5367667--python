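import copy

import pytest

from tnmstage import table_codec


@pytest.fixture(scope="session")
def lung():
    return table_codec.lung_table()


def _question(text, affirmative=True):
    return {"clauses": [text], "connective": "OR", "affirmative": affirmative}


@pytest.fixture
def minimal_doc():
    """Smallest valid table: one stage, one grouping (T1, N0, M0)."""
    return {
        "format": table_codec.FORMAT_TAG,
        "tumor_type": "minimal",
        "selectors": {},
        "axes": [
            {"code": "T", "name": "Primary tumor", "rank": 1},
            {"code": "N", "name": "Regional nodes", "rank": 2},
            {"code": "M", "name": "Metastasis", "rank": 3},
        ],
        "classifications": [
            {"axis": "T", "code": "T1", "level": 1, "criteria": "small tumor",
             "question": _question("Is the tumor small?")},
            {"axis": "N", "code": "N0", "level": 0, "criteria": "no nodes",
             "question": _question("Is there nodal spread?", affirmative=False)},
            {"axis": "M", "code": "M0", "level": 0, "criteria": "no mets",
             "question": _question("Is there distant spread?", affirmative=False)},
        ],
        "stage_groups": [
            {"label": "I", "groupings": [{"T": "T1", "N": "N0", "M": "M0"}]}
        ],
    }


@pytest.fixture
def lung_doc(lung):
    """A mutable copy of the lung document for seeding defects."""
    return copy.deepcopy(table_codec.write_table(lung))
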
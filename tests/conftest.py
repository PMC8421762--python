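"""Shared fixtures: tiny hand-built tables and small synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

from itemreduce import ItemDef, ItemTable

NA = None  # readable missing marker in hand-built fixtures


def make_table(rows, items, labels, subjects=None, tag=None) -> ItemTable:
    """Build an ItemTable from plain lists; ``None`` entries become missing."""
    n = len(rows)
    if subjects is None:
        subjects = [f"S{i:03d}" for i in range(n)]
    idx = pd.Index(subjects, name="subject_id")
    codes = pd.DataFrame(
        [[pd.NA if v is None else v for v in row] for row in rows],
        index=idx,
        columns=[it.item_id for it in items],
        dtype="Int64",
    )
    return ItemTable(
        items=tuple(items),
        codes=codes,
        labels=pd.Series(labels, index=idx, name="label"),
        subsample_tag=tag,
    )


def ados_items(ids):
    return [ItemDef(item_id=i, instrument="ADOS", in_algorithm=True) for i in ids]


@pytest.fixture
def raw_table():
    """Six subjects, four ADOS items, raw vocabulary incl. 3/7/8 and missing."""
    items = ados_items(["A", "B", "C", "D"])
    rows = [
        [0, 1, 2, 3],
        [7, 8, 0, NA],
        [3, 3, 7, 8],
        [1, NA, 2, 0],
        [2, 0, 1, 1],
        [NA, 2, 3, 7],
    ]
    labels = [1, 0, 1, 0, 1, 0]
    return make_table(rows, items, labels)


@pytest.fixture(scope="session")
def planted_cohort():
    """Small strong-signal cohort shared by forest tests (recoded)."""
    from itemreduce import generate_cohort, module_preset, recode_item_codes

    spec = module_preset("children_m3_ados", n_subjects=400, seed=3)
    table, truth = generate_cohort(spec)
    return recode_item_codes(table), truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210824)
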
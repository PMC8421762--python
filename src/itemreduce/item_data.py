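"""Domain types, recoding rules, I/O and splitting for subject-by-item tables.

The pipeline's universal input is a table of ordinal diagnostic codes: one row
per subject, one column per instrument item. ADOS items are coded 0-3 for
increasing symptom severity, with special codes 7/8 flagging peculiar or
abnormal behavior outside the severity scale; ADI-R algorithm items follow the
same vocabulary. Per the instruments' manual conventions, special codes are
remapped to 0 and severity code 3 is collapsed into 2 before modelling, so
that every analysed code lies in {0, 1, 2} or is missing.

Missingness is first-class: entries are stored in a nullable integer frame
(``pd.NA`` for missing) and are never silently imputed here; the forest
encoding downstream decides how missing values enter a model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

ADOS = "ADOS"
ADIR = "ADIR"
_INSTRUMENTS = (ADOS, ADIR)

#: Raw code vocabulary accepted on input.
ALLOWED_RAW_CODES = frozenset({0, 1, 2, 3, 7, 8})
#: Code vocabulary after recoding.
RECODED_CODES = frozenset({0, 1, 2})
#: Manual-convention remapping: special codes to 0, severity 3 collapsed to 2.
RECODE_MAP = {7: 0, 8: 0, 3: 2}

DEFAULT_LABEL_MAP: Mapping[str, int] = {"ASD": 1, "non-ASD": 0, "1": 1, "0": 0}
DEFAULT_MISSING_TOKEN = "NA"


@dataclass(frozen=True)
class ItemDef:
    """One instrument item: identifier, instrument, algorithm metadata.

    ``in_algorithm`` marks membership in the ADI-R diagnostic algorithm
    (the 37-item subset); it may be left ``None`` for ADOS items, which are
    always eligible. ``domain_tag`` carries the ADI-R domain letter (A-D);
    domain D (early developmental onset) is excluded from analysis.
    """

    item_id: str
    instrument: str
    in_algorithm: Optional[bool] = None
    domain_tag: Optional[str] = None

    def __post_init__(self):
        if self.instrument not in _INSTRUMENTS:
            raise ValueError(
                f"instrument must be one of {_INSTRUMENTS}, got {self.instrument!r}"
            )


@dataclass
class ItemTable:
    """Subjects x items matrix of ordinal codes with binary diagnostic labels.

    ``codes`` is a pandas DataFrame with nullable ``Int64`` dtype (pd.NA =
    missing), indexed by subject id with one column per item_id in the order
    of ``items``. ``labels`` is an aligned Series with 1 = ASD (positive),
    0 = non-ASD.
    """

    items: tuple[ItemDef, ...]
    codes: pd.DataFrame
    labels: pd.Series
    subsample_tag: Optional[str] = None

    def __post_init__(self):
        self.items = tuple(self.items)
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item_id in items")
        if list(self.codes.columns) != ids:
            raise ValueError("codes columns must match item order")
        if self.codes.index.has_duplicates:
            raise ValueError("duplicate subject identifiers")
        self.codes = self.codes.astype("Int64")
        if not self.labels.index.equals(self.codes.index):
            raise ValueError("labels must be indexed by the same subjects as codes")
        vals = set(pd.unique(self.labels.dropna()))
        if not vals <= {0, 1}:
            raise ValueError(f"labels must be binary 0/1, found {sorted(vals)}")
        if self.labels.isna().any():
            raise ValueError("every subject must have a label")
        self.labels = self.labels.astype(int)

    # -- convenience -----------------------------------------------------
    @property
    def subjects(self) -> list[str]:
        return list(self.codes.index)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def n_subjects(self) -> int:
        return len(self.codes.index)

    @property
    def n_items(self) -> int:
        return len(self.items)

    def item_def(self, item_id: str) -> ItemDef:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def select_items(self, item_ids: Sequence[str]) -> "ItemTable":
        keep = [it for it in self.items if it.item_id in set(item_ids)]
        return ItemTable(
            items=tuple(keep),
            codes=self.codes[[it.item_id for it in keep]].copy(),
            labels=self.labels.copy(),
            subsample_tag=self.subsample_tag,
        )

    def select_subjects(self, subject_ids: Sequence[str]) -> "ItemTable":
        idx = list(subject_ids)
        return ItemTable(
            items=self.items,
            codes=self.codes.loc[idx].copy(),
            labels=self.labels.loc[idx].copy(),
            subsample_tag=self.subsample_tag,
        )

    def equals(self, other: "ItemTable") -> bool:
        return (
            self.items == other.items
            and self.codes.equals(other.codes)
            and self.labels.equals(other.labels)
            and self.subsample_tag == other.subsample_tag
        )


@dataclass(frozen=True)
class TableSchema:
    """File-format contract for delimited item tables.

    Declares the item metadata (instrument, algorithm membership, domain tag),
    how string labels map to the binary classes, the missing-value token and
    the delimiter. Serialized as a YAML sidecar next to the data file.
    """

    items: tuple[ItemDef, ...]
    label_map: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))
    missing_token: str = DEFAULT_MISSING_TOKEN
    delimiter: str = ","
    subsample_tag: Optional[str] = None
    #: optional (negative, positive) names used when writing labels;
    #: None writes 0/1 integers.
    label_names: Optional[tuple[str, str]] = None


@dataclass
class SplitResult:
    """A stratified train/validation partition of an ItemTable."""

    train: ItemTable
    validation: ItemTable
    fraction: float
    seed: int


# ---------------------------------------------------------------------------
# recoding and item selection
# ---------------------------------------------------------------------------

def recode_item_codes(table: ItemTable) -> ItemTable:
    """Apply the manual-convention recoding 7->0, 8->0, 3->2.

    Codes 0, 1, 2 and missing entries pass through unchanged; the operation
    is idempotent. Any code outside {0,1,2,3,7,8} is rejected with the
    offending subject and item named.
    """
    codes = table.codes
    valid = codes.isin(list(ALLOWED_RAW_CODES)) | codes.isna()
    if not valid.all().all():
        bad = (~valid).to_numpy().nonzero()
        r, c = bad[0][0], bad[1][0]
        subj = codes.index[r]
        item = codes.columns[c]
        raise ValueError(
            f"invalid code {codes.iat[r, c]} for subject {subj!r}, item {item!r}; "
            f"allowed codes are {sorted(ALLOWED_RAW_CODES)} or missing"
        )
    new_codes = codes.replace(RECODE_MAP).astype("Int64")
    return dataclasses.replace(table, codes=new_codes)


def select_algorithm_items(table: ItemTable) -> ItemTable:
    """Restrict to analysable items.

    All ADOS items are retained. ADI-R items are kept only when they belong
    to the diagnostic algorithm (``in_algorithm=True``) and are not domain D
    (early developmental onset, not symptomatology). An ADI-R item lacking
    algorithm metadata is an error: the caller's schema is incomplete.
    """
    keep = []
    for it in table.items:
        if it.instrument == ADOS:
            keep.append(it.item_id)
        else:
            if it.in_algorithm is None:
                raise ValueError(
                    f"ADI-R item {it.item_id!r} is missing algorithm membership metadata"
                )
            if it.in_algorithm and it.domain_tag != "D":
                keep.append(it.item_id)
    return table.select_items(keep)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_schema(schema: TableSchema, path) -> None:
    payload = {
        "items": [
            {
                "item_id": it.item_id,
                "instrument": it.instrument,
                "in_algorithm": it.in_algorithm,
                "domain_tag": it.domain_tag,
            }
            for it in schema.items
        ],
        "label_map": dict(schema.label_map),
        "missing_token": schema.missing_token,
        "delimiter": schema.delimiter,
        "subsample_tag": schema.subsample_tag,
        "label_names": list(schema.label_names) if schema.label_names else None,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_schema(path) -> TableSchema:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    items = tuple(
        ItemDef(
            item_id=d["item_id"],
            instrument=d["instrument"],
            in_algorithm=d.get("in_algorithm"),
            domain_tag=d.get("domain_tag"),
        )
        for d in payload["items"]
    )
    label_names = payload.get("label_names")
    return TableSchema(
        items=items,
        label_map={str(k): int(v) for k, v in payload.get(
            "label_map", DEFAULT_LABEL_MAP).items()},
        missing_token=payload.get("missing_token", DEFAULT_MISSING_TOKEN),
        delimiter=payload.get("delimiter", ","),
        subsample_tag=payload.get("subsample_tag"),
        label_names=tuple(label_names) if label_names else None,
    )


def schema_for(table: ItemTable, **kwargs) -> TableSchema:
    """Build a schema describing an existing table."""
    return TableSchema(items=table.items, subsample_tag=table.subsample_tag, **kwargs)


def read_item_table(path, schema: TableSchema) -> ItemTable:
    """Read a delimited item table (header: subject_id, label, <item_id>...).

    Item columns are taken in file order; every item column must be declared
    in the schema. Labels are mapped through ``schema.label_map``.
    """
    df = pd.read_csv(path, sep=schema.delimiter, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if cols[:2] != ["subject_id", "label"]:
        raise ValueError(
            f"expected header to start with 'subject_id,label', got {cols[:2]}"
        )
    by_id = {it.item_id: it for it in schema.items}
    item_cols = cols[2:]
    unknown = [c for c in item_cols if c not in by_id]
    if unknown:
        raise ValueError(f"unknown item columns not declared in schema: {unknown}")

    label_map = {str(k): v for k, v in schema.label_map.items()}
    labels_raw = df["label"].astype(str)
    unmapped = sorted(set(labels_raw) - set(label_map))
    if unmapped:
        raise ValueError(
            f"labels {unmapped} not mapped by schema label_map {sorted(label_map)}"
        )
    labels = labels_raw.map(label_map)

    subjects = df["subject_id"].astype(str)
    codes = df[item_cols].copy()
    codes = codes.mask(codes == schema.missing_token)
    try:
        codes = codes.astype("float").astype("Int64")
    except ValueError as err:
        raise ValueError(f"non-integer code value in item columns: {err}") from err
    codes.index = pd.Index(subjects, name="subject_id")
    labels.index = codes.index

    items = tuple(by_id[c] for c in item_cols)
    return ItemTable(
        items=items, codes=codes, labels=labels, subsample_tag=schema.subsample_tag
    )


def write_item_table(table: ItemTable, path, schema: Optional[TableSchema] = None) -> None:
    """Write a table in the delimited format `read_item_table` accepts.

    With the default schema, labels are written as 0/1 and missing entries as
    "NA", so write/read round-trips are lossless including missing values.
    """
    if schema is None:
        schema = schema_for(table)
    out = table.codes.astype(object)
    out = out.where(out.notna(), schema.missing_token)
    if schema.label_names is not None:
        neg, pos = schema.label_names
        label_col = table.labels.map({0: neg, 1: pos})
    else:
        label_col = table.labels
    out.insert(0, "label", label_col)
    out.insert(0, "subject_id", table.codes.index)
    out.to_csv(path, sep=schema.delimiter, index=False)


def write_split_manifest(split: SplitResult, path) -> None:
    """Record which subjects went to which partition (two-column TSV)."""
    rows = [(s, "train") for s in split.train.subjects] + [
        (s, "validation") for s in split.validation.subjects
    ]
    pd.DataFrame(rows, columns=["subject_id", "part"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def train_validation_split(table: ItemTable, fraction: float, seed: int) -> SplitResult:
    """Stratified holdout split: `fraction` of subjects become validation.

    Stratification is by diagnostic class only, so class prevalence is
    preserved within one subject per class. Deterministic given ``seed``;
    the two parts partition the input (no subject appears in both).
    """
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    if fraction == 0:
        empty_idx: list[str] = []
        validation = table.select_subjects(empty_idx)
        return SplitResult(train=table, validation=validation,
                           fraction=fraction, seed=seed)
    y = table.labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("stratified split requires at least one subject per class")
    subjects = np.asarray(table.subjects, dtype=object)
    train_ids, val_ids = train_test_split(
        subjects, test_size=fraction, random_state=seed, stratify=y
    )
    # preserve the original subject order within each part
    train_set, val_set = set(train_ids), set(val_ids)
    train_ordered = [s for s in table.subjects if s in train_set]
    val_ordered = [s for s in table.subjects if s in val_set]
    return SplitResult(
        train=table.select_subjects(train_ordered),
        validation=table.select_subjects(val_ordered),
        fraction=fraction,
        seed=seed,
    )
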
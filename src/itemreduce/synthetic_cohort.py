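"""Synthetic ordinal item cohorts with known ground truth.

Clinical item-level ADOS/ADI-R data are restricted, so the pipeline is
exercised on generated cohorts that emulate their structure: two age-based
subsamples (28 ADOS module-3 items or 31 module-4 items, optionally combined
with the 37 ADI-R algorithm items), a ~46% positive-class prevalence,
ordinal severity codes 0-3 with special codes 7/8, and item-level
missingness.

The generative model is a graded (probit) item model: each subject draws a
latent severity per item from N(0, 1), shifted upward by delta for positive
subjects on "informative" items, and the latent value is discretized through
fixed cutpoints into codes 0-3. This gives a closed-form ground truth: the
latent two-class AUC of an item with shift delta is Phi(delta / sqrt(2)),
which oracle tests can check against Monte-Carlo estimates. Special codes
7/8 are injected independently of class (they flag peculiar behavior, not
severity, so recoding them to 0 adds class-independent noise), and
missingness is MCAR by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from ._rng import derive_seed
from .item_data import ADIR, ADOS, ItemDef, ItemTable

#: Default code mass in the negative class: {0: 50%, 1: 25%, 2: 15%, 3: 10%}.
DEFAULT_CUTPOINTS: tuple[float, float, float] = tuple(
    float(norm.ppf(q)) for q in (0.50, 0.75, 0.90)
)

DEFAULT_PREVALENCE = 0.46
#: Default planted standardized shifts, strongest first.
DEFAULT_PLANTED_DELTAS = (2.0, 1.8, 1.6, 1.4, 1.2, 1.0, 0.8)


@dataclass
class CohortSpec:
    """Generative parameters for one synthetic cohort."""

    n_subjects: int
    prevalence: float
    item_defs: tuple[ItemDef, ...]
    #: ordered mapping item_id -> latent standardized shift delta (>= 0)
    informative_items: Mapping[str, float] = field(default_factory=dict)
    #: per-item cutpoints; items absent here use DEFAULT_CUTPOINTS
    ordinal_cutpoints: Mapping[str, Sequence[float]] = field(default_factory=dict)
    special_code_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    exact_prevalence: bool = False
    subsample_tag: Optional[str] = None

    def __post_init__(self):
        self.item_defs = tuple(self.item_defs)
        if not self.item_defs:
            raise ValueError("item_defs must not be empty")
        if not 0 < self.prevalence < 1:
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        ids = {it.item_id for it in self.item_defs}
        for item_id, delta in self.informative_items.items():
            if item_id not in ids:
                raise ValueError(f"informative item {item_id!r} not in item_defs")
            if delta < 0:
                raise ValueError(f"delta must be >= 0, got {delta} for {item_id!r}")
        for item_id, cuts in self.ordinal_cutpoints.items():
            cuts = list(cuts)
            if any(b <= a for a, b in zip(cuts, cuts[1:])):
                raise ValueError(f"cutpoints for {item_id!r} must be strictly increasing")
        for name in ("special_code_rate", "missing_rate"):
            rate = getattr(self, name)
            if not 0 <= rate < 1:
                raise ValueError(f"{name} must be in [0, 1), got {rate}")


@dataclass
class GroundTruth:
    """What the generator planted: informative items ranked by shift."""

    #: item_ids sorted by delta descending (ties keep spec order)
    informative_items: tuple[str, ...]
    deltas: Mapping[str, float]
    #: theoretical latent-scale AUC per informative item, Phi(delta/sqrt(2))
    latent_auc: Mapping[str, float]

    def to_json(self, path) -> None:
        payload = {
            "informative_items": list(self.informative_items),
            "deltas": {k: float(v) for k, v in self.deltas.items()},
            "latent_auc": {k: float(v) for k, v in self.latent_auc.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def latent_auc(delta: float) -> float:
    """Closed-form AUC between N(0,1) and N(delta,1): Phi(delta / sqrt(2))."""
    return float(norm.cdf(delta / np.sqrt(2.0)))


def generate_cohort(spec: CohortSpec) -> tuple[ItemTable, GroundTruth]:
    """Draw one cohort from the graded item model.

    Per subject: class ~ Bernoulli(prevalence) (or an exactly-rounded count
    when ``exact_prevalence``). Per item: latent ~ N(0,1) + delta*class,
    discretized through the item's cutpoints into codes 0-3; then special
    codes 7/8 replace observed codes at ``special_code_rate`` (class
    independent) and entries are masked missing at ``missing_rate``.
    Fully reproducible from ``spec.seed``; per-item RNG streams are keyed by
    item_id so the realization does not depend on item order.
    """
    n = spec.n_subjects
    rng_labels = np.random.default_rng(derive_seed(spec.seed, "labels"))
    if spec.exact_prevalence:
        n_pos = int(round(n * spec.prevalence))
        y = np.zeros(n, dtype=int)
        y[:n_pos] = 1
        rng_labels.shuffle(y)
    else:
        y = (rng_labels.random(n) < spec.prevalence).astype(int)

    subjects = [f"S{i:05d}" for i in range(n)]
    columns = {}
    for it in spec.item_defs:
        item_id = it.item_id
        delta = float(spec.informative_items.get(item_id, 0.0))
        cuts = np.asarray(
            spec.ordinal_cutpoints.get(item_id, DEFAULT_CUTPOINTS), dtype=float
        )
        rng = np.random.default_rng(derive_seed(spec.seed, "item", item_id))
        latent = rng.standard_normal(n) + delta * y
        code = np.digitize(latent, cuts).astype(object)
        if spec.special_code_rate > 0:
            special = rng.random(n) < spec.special_code_rate
            code[special] = rng.choice([7, 8], size=int(special.sum()))
        col = pd.array(code, dtype="Int64")
        if spec.missing_rate > 0:
            missing = rng.random(n) < spec.missing_rate
            col[missing] = pd.NA
        columns[item_id] = col

    codes = pd.DataFrame(columns, index=pd.Index(subjects, name="subject_id"))
    codes = codes[[it.item_id for it in spec.item_defs]]
    labels = pd.Series(y, index=codes.index, name="label")
    table = ItemTable(
        items=spec.item_defs, codes=codes, labels=labels,
        subsample_tag=spec.subsample_tag,
    )

    informative = {k: float(v) for k, v in spec.informative_items.items() if v > 0}
    order = sorted(informative, key=lambda k: -informative[k])
    truth = GroundTruth(
        informative_items=tuple(order),
        deltas=informative,
        latent_auc={k: latent_auc(d) for k, d in informative.items()},
    )
    return table, truth


# ---------------------------------------------------------------------------
# instrument presets
# ---------------------------------------------------------------------------

# Synthetic item rosters. Abbreviation-style ids mimic the instruments'
# published short codes; the rosters themselves are package conventions
# (the real item lists live in the instruments' manuals).
_ADOS_M3_ITEMS = (
    "ARSC", "STER", "CONV", "QSOV", "EXPE", "INS", "GES", "SPAB", "EYE",
    "QSR", "IMAG", "OLANG", "ECHO", "REPT", "POINT", "SHOW", "UNIM", "SINT",
    "MANN", "SELF", "RITL", "COMPB", "ANX", "OACT", "NEGB", "IRRB", "TANT",
    "EMO",
)  # 28 items
_ADOS_M4_ITEMS = _ADOS_M3_ITEMS + ("RESP", "DLIV", "HALC")  # 31 items

_ADIR_NAMED = (
    ("SHATT", "A"),   # showing / directing attention
    ("PTINT", "A"),   # pointing to express interest
    ("IMPLAY", "A"),  # imitative social play
    ("INTCH", "A"),   # interest in children
    ("RCONV", "B"),   # reciprocal conversation
)
_ADIR_ALGORITHM_ITEMS = _ADIR_NAMED + tuple(
    (f"ADIR_A{i:02d}", "A") for i in range(1, 13)
) + tuple(
    (f"ADIR_B{i:02d}", "B") for i in range(1, 13)
) + tuple(
    (f"ADIR_C{i:02d}", "C") for i in range(1, 9)
)  # 37 items across domains A-C

_PLANTED_ADOS = ("QSOV", "EXPE", "ARSC", "SPAB", "STER", "CONV", "EYE")
_PLANTED_COMBINED = ("QSOV", "EXPE", "ARSC", "SPAB", "STER", "SHATT", "RCONV")

PRESET_NAMES = (
    "children_m3_ados",
    "adults_m4_ados",
    "children_m3_combined",
    "adults_m4_combined",
)


def _ados_defs(ids: Sequence[str]) -> tuple[ItemDef, ...]:
    return tuple(ItemDef(item_id=i, instrument=ADOS, in_algorithm=True) for i in ids)


def _adir_defs() -> tuple[ItemDef, ...]:
    return tuple(
        ItemDef(item_id=i, instrument=ADIR, in_algorithm=True, domain_tag=d)
        for i, d in _ADIR_ALGORITHM_ITEMS
    )


def module_preset(
    name: str,
    n_subjects: int = 1500,
    seed: int = 0,
    planted_deltas: Optional[Sequence[float]] = DEFAULT_PLANTED_DELTAS,
    **overrides,
) -> CohortSpec:
    """Cohort spec for one of the four study configurations.

    Item counts match the study designs: 28 (children, ADOS module 3),
    31 (adults, module 4), 65 = 28 + 37 and 68 = 31 + 37 for the combined
    ADOS + ADI-R tables. Defaults: prevalence 0.46, 5% special codes, 10%
    missingness, and seven planted informative items with shifts 2.0 down
    to 0.8 (pass ``planted_deltas=None`` or ``()`` for a null cohort).
    """
    if name == "children_m3_ados":
        items = _ados_defs(_ADOS_M3_ITEMS)
        planted_ids = _PLANTED_ADOS
    elif name == "adults_m4_ados":
        items = _ados_defs(_ADOS_M4_ITEMS)
        planted_ids = _PLANTED_ADOS
    elif name == "children_m3_combined":
        items = _ados_defs(_ADOS_M3_ITEMS) + _adir_defs()
        planted_ids = _PLANTED_COMBINED
    elif name == "adults_m4_combined":
        items = _ados_defs(_ADOS_M4_ITEMS) + _adir_defs()
        planted_ids = _PLANTED_COMBINED
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")

    deltas = tuple(planted_deltas or ())
    informative = dict(zip(planted_ids[: len(deltas)], deltas))
    params = dict(
        n_subjects=n_subjects,
        prevalence=DEFAULT_PREVALENCE,
        item_defs=items,
        informative_items=informative,
        special_code_rate=0.05,
        missing_rate=0.10,
        seed=seed,
        subsample_tag=name,
    )
    params.update(overrides)
    return CohortSpec(**params)


# ---------------------------------------------------------------------------
# YAML (de)serialization of cohort specs
# ---------------------------------------------------------------------------

def save_cohort_spec(spec: CohortSpec, path) -> None:
    payload = {
        "n_subjects": spec.n_subjects,
        "prevalence": spec.prevalence,
        "items": [
            {
                "item_id": it.item_id,
                "instrument": it.instrument,
                "in_algorithm": it.in_algorithm,
                "domain_tag": it.domain_tag,
            }
            for it in spec.item_defs
        ],
        "informative_items": {k: float(v) for k, v in spec.informative_items.items()},
        "ordinal_cutpoints": {
            k: [float(c) for c in v] for k, v in spec.ordinal_cutpoints.items()
        },
        "special_code_rate": spec.special_code_rate,
        "missing_rate": spec.missing_rate,
        "seed": spec.seed,
        "exact_prevalence": spec.exact_prevalence,
        "subsample_tag": spec.subsample_tag,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_cohort_spec(path) -> CohortSpec:
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
    return CohortSpec(
        n_subjects=int(payload["n_subjects"]),
        prevalence=float(payload["prevalence"]),
        item_defs=items,
        informative_items=payload.get("informative_items", {}),
        ordinal_cutpoints=payload.get("ordinal_cutpoints", {}),
        special_code_rate=float(payload.get("special_code_rate", 0.0)),
        missing_rate=float(payload.get("missing_rate", 0.0)),
        seed=int(payload.get("seed", 0)),
        exact_prevalence=bool(payload.get("exact_prevalence", False)),
        subsample_tag=payload.get("subsample_tag"),
    )
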
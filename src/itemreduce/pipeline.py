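"""End-to-end orchestration: split -> recode -> rank -> nested models -> selection.

One call runs the full item-reduction procedure on an input cohort (a CSV +
schema, or a synthetic preset) and writes a reproducible report bundle:

* ``ranking.tsv``          - aggregated importance hierarchy
* ``model_family.tsv``     - per-k performance, CV ("test") and holdout
                             ("blind") columns plus the McNemar p vs full
* ``selection.json``       - optimal/minimal model identities and per-k
                             McNemar table
* ``selected_features.tsv``- feature lists of the optimal and minimal models
* ``split_manifest.tsv``   - which subject went to which partition
* ``run_log.json``         - seeds, configuration flags, stage counts,
                             library versions

Outputs are byte-identical across reruns with the same configuration and
seed: every stochastic stage derives its substream from the master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from ._rng import derive_seed
from .item_data import (
    ItemTable,
    SplitResult,
    load_schema,
    read_item_table,
    recode_item_codes,
    schema_for,
    select_algorithm_items,
    train_validation_split,
    write_item_table,
    write_split_manifest,
)
from .metrics import SummaryGroup, pooled_t_from_summary
from .model_comparison import (
    SelectionResult,
    find_minimal_model,
    validation_scores,
)
from .nested_models import (
    ModelRecord,
    SelectionWeights,
    model_family_frame,
    optimal_model,
    train_reduced_models,
)
from .rf_importance import (
    FeatureRanking,
    ForestConfig,
    aggregate_ranking,
    run_cv_importance,
    write_ranking_tsv,
)
from .synthetic_cohort import (
    generate_cohort,
    load_cohort_spec,
    module_preset,
)

logger = logging.getLogger("itemreduce")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; serializable to/from YAML."""

    input_path: Optional[str] = None
    schema_path: Optional[str] = None
    preset: Optional[str] = None
    n_subjects: int = 1500
    validation_fraction: float = 0.25
    forest: ForestConfig = field(default_factory=ForestConfig)
    weights: SelectionWeights = field(default_factory=SelectionWeights)
    alpha: float = 0.05
    seed: int = 0
    out_dir: Optional[str] = None
    plain_acc: bool = False
    subset_on_adir: bool = False

    def __post_init__(self):
        if (self.input_path is None) == (self.preset is None):
            raise ValueError("specify exactly one of input_path or preset")
        if self.input_path is not None and self.schema_path is None:
            raise ValueError("input_path requires schema_path")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        forest = ForestConfig(**payload.pop("forest", {}))
        weights = SelectionWeights(**payload.pop("weights", {}))
        return cls(forest=forest, weights=weights, **payload)


@dataclass
class PipelineResult:
    """In-memory result bundle of one pipeline run."""

    table: ItemTable
    split: SplitResult
    ranking: FeatureRanking
    records: list[ModelRecord]
    optimal_record: ModelRecord
    selection: SelectionResult
    family_table: pd.DataFrame
    out_paths: dict[str, str] = field(default_factory=dict)


def _load_input(config: PipelineConfig) -> ItemTable:
    if config.preset is not None:
        spec = module_preset(
            config.preset,
            n_subjects=config.n_subjects,
            seed=derive_seed(config.seed, "cohort"),
        )
        table, _ = generate_cohort(spec)
        return table
    schema = load_schema(config.schema_path)
    return read_item_table(config.input_path, schema)


def _subset_on_adir(table: ItemTable) -> ItemTable:
    """Restrict to subjects with at least one observed ADI-R item.

    Alternative to the default missing-as-valid handling of combined
    ADOS + ADI-R tables when a subject never received the interview.
    """
    adir_cols = [it.item_id for it in table.items if it.instrument == "ADIR"]
    if not adir_cols:
        return table
    has_adir = table.codes[adir_cols].notna().any(axis=1)
    return table.select_subjects(list(table.codes.index[has_adir]))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the four-step procedure and (optionally) write the bundle."""
    table = _load_input(config)
    logger.info(
        "input: %d subjects x %d items, prevalence %.3f",
        table.n_subjects, table.n_items, table.labels.mean(),
    )

    table = recode_item_codes(table)
    table = select_algorithm_items(table)
    if config.subset_on_adir:
        table = _subset_on_adir(table)
        logger.info("after ADI-R subsetting: %d subjects", table.n_subjects)

    split = train_validation_split(
        table, config.validation_fraction, derive_seed(config.seed, "split")
    )
    logger.info(
        "split: %d train / %d validation",
        split.train.n_subjects, split.validation.n_subjects,
    )

    forest_cfg = dataclasses.replace(
        config.forest, seed=derive_seed(config.seed, "forest-stage")
    )
    runs = run_cv_importance(split.train, forest_cfg)
    ranking = aggregate_ranking(runs)
    logger.info("importance: %d runs aggregated; top item %s",
                len(runs), ranking.item_ids[0])

    records = train_reduced_models(
        split.train, ranking, forest_cfg, plain_acc=config.plain_acc
    )
    opt_record, scores = optimal_model(records, config.weights)
    logger.info("optimal model: k=%d (score %.4f)",
                opt_record.k, max(s.score for s in scores))

    val_scores = validation_scores(records, split.train, split.validation, forest_cfg)
    selection = find_minimal_model(
        records, split.train, split.validation, forest_cfg,
        alpha=config.alpha, optimal_k=opt_record.k, scores=val_scores,
    )
    logger.info("minimal model: k=%d (alpha %.2f)", selection.minimal_k, config.alpha)

    family = model_family_frame(records)
    y_val = split.validation.labels.to_numpy(dtype=int)
    blind = {"auc_blind": [], "acc_blind": [], "sens_blind": [], "spec_blind": [],
             "mcnemar_p": []}
    from .metrics import confusion_metrics, roc_auc  # local to avoid cycle noise

    for r in records:
        s = val_scores[r.k]
        preds = s >= r.threshold
        cm = confusion_metrics(preds, y_val)
        blind["auc_blind"].append(roc_auc(s, y_val))
        blind["acc_blind"].append(
            cm.accuracy if config.plain_acc else cm.balanced_accuracy
        )
        blind["sens_blind"].append(cm.sensitivity)
        blind["spec_blind"].append(cm.specificity)
        blind["mcnemar_p"].append(selection.comparison_for(r.k).p)
    for name, vals in blind.items():
        family[name] = vals

    result = PipelineResult(
        table=table,
        split=split,
        ranking=ranking,
        records=records,
        optimal_record=opt_record,
        selection=selection,
        family_table=family,
    )
    if config.out_dir is not None:
        result.out_paths = _write_bundle(config, result)
    return result


def _write_bundle(config: PipelineConfig, result: PipelineResult) -> dict[str, str]:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    p = out / "ranking.tsv"
    write_ranking_tsv(result.ranking, p)
    paths["ranking"] = str(p)

    p = out / "model_family.tsv"
    result.family_table.round(6).to_csv(p, sep="\t", index=False)
    paths["model_family"] = str(p)

    p = out / "selection.json"
    with open(p, "w") as fh:
        json.dump(result.selection.to_dict(), fh, indent=2, sort_keys=True)
    paths["selection"] = str(p)

    p = out / "selected_features.tsv"
    rows = []
    minimal = next(r for r in result.records if r.k == result.selection.minimal_k)
    for model_name, record in (("optimal", result.optimal_record),
                               ("minimal", minimal)):
        for rank, fid in enumerate(record.feature_ids, start=1):
            rows.append(
                {
                    "model": model_name,
                    "rank": rank,
                    "item_id": fid,
                    "instrument": result.table.item_def(fid).instrument,
                }
            )
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    paths["selected_features"] = str(p)

    p = out / "split_manifest.tsv"
    write_split_manifest(result.split, p)
    paths["split_manifest"] = str(p)

    p = out / "run_log.json"
    import sklearn

    log = {
        "seed": config.seed,
        "preset": config.preset,
        "input_path": config.input_path,
        "n_subjects": result.table.n_subjects,
        "n_items": result.table.n_items,
        "prevalence": round(float(result.table.labels.mean()), 6),
        "n_train": result.split.train.n_subjects,
        "n_validation": result.split.validation.n_subjects,
        "validation_fraction": config.validation_fraction,
        "forest": dataclasses.asdict(config.forest),
        "weights": dataclasses.asdict(config.weights),
        "alpha": config.alpha,
        "plain_acc": config.plain_acc,
        "subset_on_adir": config.subset_on_adir,
        "optimal_k": result.optimal_record.k,
        "minimal_k": result.selection.minimal_k,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "sklearn": sklearn.__version__,
        },
    }
    with open(p, "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    paths["run_log"] = str(p)
    return paths


# ---------------------------------------------------------------------------
# fixtures and summaries
# ---------------------------------------------------------------------------

def generate_fixtures(spec_path, out_dir) -> dict[str, str]:
    """Generate a cohort from a CohortSpec YAML: CSV + schema + ground truth."""
    spec = load_cohort_spec(spec_path)
    table, truth = generate_cohort(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": str(out / "cohort.csv"),
        "schema": str(out / "schema.yaml"),
        "ground_truth": str(out / "ground_truth.json"),
    }
    schema = schema_for(table)
    write_item_table(table, paths["cohort"], schema)
    from .item_data import save_schema

    save_schema(schema, paths["schema"])
    truth.to_json(paths["ground_truth"])
    return paths


def summarize_items(table: ItemTable, welch: bool = False) -> pd.DataFrame:
    """Per-item group comparison in cohort-table style.

    For each item: N, mean, SD per class on the recoded codes (missing
    dropped item-wise), two-sample t (pooled by default), df, p and Cohen's
    d. The positive (ASD) group is listed first, so t is negative when that
    group scores higher.
    """
    rows = []
    y = table.labels
    for it in table.items:
        col = table.codes[it.item_id].astype("Float64")
        g = {}
        ok = True
        for cls in (1, 0):
            vals = col[y == cls].dropna().to_numpy(dtype=float)
            if len(vals) < 2:
                ok = False
                break
            g[cls] = SummaryGroup(
                n=len(vals), m=float(vals.mean()), s=float(vals.std(ddof=1))
            )
        if not ok:
            continue
        res = pooled_t_from_summary(g[1], g[0], welch=welch)
        rows.append(
            {
                "item_id": it.item_id,
                "instrument": it.instrument,
                "n_asd": g[1].n, "m_asd": g[1].m, "sd_asd": g[1].s,
                "n_non": g[0].n, "m_non": g[0].m, "sd_non": g[0].s,
                "t": res.t, "df": res.df, "p": res.p, "es": res.d,
            }
        )
    return pd.DataFrame(rows)
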
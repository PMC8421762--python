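"""Validation evaluation, McNemar paired comparisons, minimal-model search."""

import numpy as np
import pytest
from scipy.stats import binom

from itemreduce import (
    CohortSpec,
    ForestConfig,
    ModelRecord,
    ThresholdResult,
    evaluate_on_validation,
    find_minimal_model,
    generate_cohort,
    mcnemar_test,
    recode_item_codes,
    train_validation_split,
)
from itemreduce.model_comparison import mcnemar_p_from_chi2, validation_scores

from conftest import ados_items, make_table


def midp_binomial_sign_test(b, c):
    """Mid-p exact binomial oracle: the small-sample companion of the
    uncorrected chi-square McNemar statistic."""
    n = b + c
    k = max(b, c)
    p = 2.0 * (binom.sf(k, n, 0.5) + 0.5 * binom.pmf(k, n, 0.5))
    return min(p, 1.0)


class TestMcNemar:
    def test_symmetric_discordance(self):
        a = [True] * 5 + [False] * 5 + [True] * 3
        b = [False] * 5 + [True] * 5 + [True] * 3
        res = mcnemar_test(a, b)
        assert (res.b, res.c) == (5, 5)
        assert res.chi2 == 0.0
        assert res.p == 1.0

    def test_no_discordance_convention(self):
        res = mcnemar_test([True, False, True], [True, False, True])
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_hand_computed_example(self):
        a = [True] * 10 + [False] * 2 + [True] * 7
        b = [False] * 10 + [True] * 2 + [True] * 7
        res = mcnemar_test(a, b)
        assert (res.b, res.c) == (10, 2)
        assert res.chi2 == pytest.approx(64 / 12, abs=1e-12)
        assert res.p == pytest.approx(0.0209, abs=5e-4)

    @pytest.mark.parametrize(
        "chi2,printed_p",
        [(0.06, 0.81), (2.50, 0.11), (1.66, 0.20),
         (3.16, 0.08), (7.23, 0.007), (7.62, 0.005)],
    )
    def test_chi2_tail_anchor_map(self, chi2, printed_p):
        """The chi-square(1) tail reproduces the reference anchor pairs to
        the precision they are printed at (one unit in the last digit)."""
        decimals = len(str(printed_p).split(".")[1])
        assert abs(mcnemar_p_from_chi2(chi2) - printed_p) < 10.0 ** (-decimals)

    def test_matches_statsmodels_uncorrected(self, rng):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for _ in range(50):
            b, c = int(rng.integers(0, 40)), int(rng.integers(0, 40))
            if b + c == 0:
                continue
            n_cc = int(rng.integers(1, 30))
            a_vec = [True] * b + [False] * c + [True] * n_cc
            b_vec = [False] * b + [True] * c + [True] * n_cc
            res = mcnemar_test(a_vec, b_vec)
            table = [[n_cc, b], [c, 0]]
            ref = sm_mcnemar(table, exact=False, correction=False)
            assert res.chi2 == pytest.approx(float(ref.statistic), abs=1e-10)
            assert res.p == pytest.approx(float(ref.pvalue), abs=1e-10)

    def test_agrees_with_midp_exact_binomial(self, rng):
        """For b + c >= 25 the uncorrected chi-square p tracks the mid-p
        exact binomial sign test within 0.02 absolute."""
        checked = 0
        while checked < 500:
            b = int(rng.integers(0, 80))
            c = int(rng.integers(0, 80))
            if b + c < 25:
                continue
            chi2 = (b - c) ** 2 / (b + c)
            p_chi = mcnemar_p_from_chi2(chi2)
            p_exact = midp_binomial_sign_test(b, c)
            assert abs(p_chi - p_exact) <= 0.02, (b, c, p_chi, p_exact)
            checked += 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_test([True, False], [True])


def _const_record(k, threshold=0.5):
    thr = ThresholdResult(threshold, 1.0, 1.0, 1.0)
    return ModelRecord(k=k, feature_ids=tuple(f"f{j}" for j in range(k)),
                       auc=1.0, threshold_result=thr, acc=1.0,
                       sensitivity=1.0, specificity=1.0)


def _validation_table(n):
    return make_table([[0]] * n, ados_items(["A"]),
                      [1] * (n // 2) + [0] * (n - n // 2))


class TestMinimalModelSearch:
    def test_identical_predictions_give_minimal_one(self):
        validation = _validation_table(30)
        y = validation.labels.to_numpy()
        records = [_const_record(k) for k in (1, 2, 3)]
        scores = {k: y.astype(float) for k in (1, 2, 3)}  # all perfect
        sel = find_minimal_model(records, validation, validation,
                                 ForestConfig(n_trees=2), scores=scores)
        assert sel.minimal_k == 1
        assert all(r.p == 1.0 for _, r in sel.comparisons)

    def test_constructed_discordance_skips_to_k2(self):
        """k=1 disagrees with the full model on 20 subjects, all favoring the
        full model (b=0, c=20 -> p ~ 7.7e-6); k=2 matches the full model."""
        validation = _validation_table(40)
        y = validation.labels.to_numpy().astype(float)
        full_scores = y.copy()                # full model perfect
        k1 = y.copy()
        k1[:20] = 1.0 - k1[:20]               # wrong on 20 subjects
        records = [_const_record(k) for k in (1, 2, 3)]
        scores = {1: k1, 2: full_scores.copy(), 3: full_scores}
        sel = find_minimal_model(records, validation, validation,
                                 ForestConfig(n_trees=2), scores=scores)
        res1 = sel.comparison_for(1)
        assert (res1.b, res1.c) == (0, 20)
        assert res1.chi2 == 20.0
        assert res1.p == pytest.approx(7.7e-6, rel=0.01)
        assert sel.minimal_k == 2
        assert not sel.minimal_is_full

    def test_no_passing_model_flags_full(self):
        validation = _validation_table(60)
        y = validation.labels.to_numpy().astype(float)
        bad = 1.0 - y
        records = [_const_record(k) for k in (1, 2)]
        scores = {1: bad, 2: y}
        sel = find_minimal_model(records, validation, validation,
                                 ForestConfig(n_trees=2), scores=scores)
        assert sel.minimal_k == 2
        assert sel.minimal_is_full

    def test_everything_below_minimal_is_significant(self):
        validation = _validation_table(80)
        y = validation.labels.to_numpy().astype(float)
        rng = np.random.default_rng(4)
        scores = {}
        for k in (1, 2, 3, 4):
            flip = rng.random(80) < (0.5 - 0.12 * k)
            s = y.copy()
            s[flip] = 1 - s[flip]
            scores[k] = s
        records = [_const_record(k) for k in (1, 2, 3, 4)]
        sel = find_minimal_model(records, validation, validation,
                                 ForestConfig(n_trees=2), scores=scores)
        for k, res in sel.comparisons:
            if k < sel.minimal_k:
                assert res.p <= sel.alpha


@pytest.fixture(scope="module")
def split_cohort():
    spec = CohortSpec(
        n_subjects=1000, prevalence=0.46,
        item_defs=tuple(ados_items([f"G{i}" for i in range(6)])),
        informative_items={"G0": 3.0, "G1": 3.0}, seed=37,
    )
    table, _ = generate_cohort(spec)
    table = recode_item_codes(table)
    return train_validation_split(table, 0.25, seed=41)


class TestValidationEvaluation:
    def test_near_perfect_separation_recovered_blind(self, split_cohort):
        from itemreduce import aggregate_ranking, run_cv_importance
        from itemreduce import train_reduced_models

        cfg = ForestConfig(n_trees=50, n_runs=4, n_folds=4, seed=43)
        ranking = aggregate_ranking(run_cv_importance(split_cohort.train, cfg))
        records = train_reduced_models(split_cohort.train, ranking, cfg, ks=[2])
        report = evaluate_on_validation(
            records[0], split_cohort.train, split_cohort.validation, cfg
        )
        assert report.sensitivity >= 0.95
        assert report.specificity >= 0.95
        assert report.threshold == records[0].threshold

    def test_shuffling_validation_subjects_changes_nothing(self, split_cohort):
        from itemreduce import aggregate_ranking, run_cv_importance
        from itemreduce import train_reduced_models

        cfg = ForestConfig(n_trees=25, n_runs=3, n_folds=3, seed=47)
        ranking = aggregate_ranking(run_cv_importance(split_cohort.train, cfg))
        records = train_reduced_models(split_cohort.train, ranking, cfg, ks=[1, 6])
        validation = split_cohort.validation
        rng = np.random.default_rng(7)
        shuffled_ids = list(validation.subjects)
        rng.shuffle(shuffled_ids)
        shuffled = validation.select_subjects(shuffled_ids)
        sel_a = find_minimal_model(records, split_cohort.train, validation, cfg)
        sel_b = find_minimal_model(records, split_cohort.train, shuffled, cfg)
        assert sel_a.to_dict() == sel_b.to_dict()

    def test_leakage_guard_warns(self, split_cohort):
        cfg = ForestConfig(n_trees=5, n_runs=2, n_folds=2, seed=3)
        record = _const_record(1)
        record = ModelRecord(
            k=1, feature_ids=("G0",), auc=1.0,
            threshold_result=ThresholdResult(0.5, 1, 1, 1),
            acc=1.0, sensitivity=1.0, specificity=1.0,
        )
        with pytest.warns(UserWarning, match="optimistic"):
            evaluate_on_validation(
                record, split_cohort.train, split_cohort.train, cfg
            )

    def test_missing_feature_column_rejected(self, split_cohort):
        cfg = ForestConfig(n_trees=5, seed=3)
        record = ModelRecord(
            k=1, feature_ids=("NOT_AN_ITEM",), auc=1.0,
            threshold_result=ThresholdResult(0.5, 1, 1, 1),
            acc=1.0, sensitivity=1.0, specificity=1.0,
        )
        with pytest.raises(ValueError, match="NOT_AN_ITEM"):
            validation_scores([record], split_cohort.train,
                              split_cohort.validation, cfg)
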
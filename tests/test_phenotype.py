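"""Phenotype scoring: imputation, confusion metrics, MCC-optimal
binarization, ROC/PR AUC and bootstrap — each checked against independent
oracles (exhaustive threshold sweeps, pair counting, hand summation)."""

import math

import numpy as np
import pandas as pd
import pytest

from idbench import (
    NEGATIVE,
    POSITIVE,
    UNKNOWN,
    ConfusionCounts,
    PhenotypeSubmission,
    assess_submission,
    bootstrap_auc,
    confusion_counts,
    impute_missing,
    metric_set,
    optimal_mcc_threshold,
    pr_auc,
    roc_auc,
    trait_seed,
)

P, N, U = POSITIVE, NEGATIVE, UNKNOWN


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def oracle_mcc(pred, truth):
    """Textbook MCC from scratch, zero when any denominator factor is zero."""
    tp = sum(1 for p, t in zip(pred, truth) if t == P and p == 1)
    fp = sum(1 for p, t in zip(pred, truth) if t == N and p == 1)
    fn = sum(1 for p, t in zip(pred, truth) if t == P and p == 0)
    tn = sum(1 for p, t in zip(pred, truth) if t == N and p == 0)
    d = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    return 0.0 if d == 0 else (tp * tn - fp * fn) / math.sqrt(d)


def oracle_best_threshold(probs, truth):
    """Exhaustive sweep over midpoint candidates, ties to smallest threshold."""
    uniq = sorted(set(probs))
    cands = [uniq[0] - 1] + [(a + b) / 2 for a, b in zip(uniq, uniq[1:])] + [uniq[-1] + 1]
    best = None
    for t in cands:
        pred = [1 if p >= t else 0 for p in probs]
        mcc = oracle_mcc(pred, truth)
        if best is None or mcc > best[1]:
            best = (t, mcc)
    return best


def oracle_auc_pairs(probs, truth):
    """Mann-Whitney pair counting with ties counted 1/2."""
    pos = [p for p, t in zip(probs, truth) if t == P]
    neg = [p for p, t in zip(probs, truth) if t == N]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def random_instance(rng, n_max=12, with_unknown=False):
    n = int(rng.integers(2, n_max + 1))
    # discretized probabilities force frequent ties
    probs = rng.choice(np.linspace(0, 1, 6), size=n).tolist()
    choices = [P, N, U] if with_unknown else [P, N]
    while True:
        truth = rng.choice(choices, size=n).tolist()
        known = [t for t in truth if t != U]
        if P in known and N in known:
            return probs, truth


# ---------------------------------------------------------------------------
# Imputation & confusion
# ---------------------------------------------------------------------------


def test_impute_missing_zeroes_only_missing_cells():
    probs = pd.DataFrame({"ID": [0.9, np.nan], "ASD": [np.nan, np.nan]}, index=["a", "b"])
    sub = impute_missing(PhenotypeSubmission("1.1", "1", probs))
    assert sub.probs.loc["a", "ID"] == 0.9
    assert (sub.probs.loc["b"] == 0.0).all() and sub.probs.loc["a", "ASD"] == 0.0


@pytest.mark.parametrize(
    "pred,truth,expected",
    [
        ([1, 0], [P, N], (1, 0, 0, 1)),
        ([1, 1, 0], [P, U, N], (1, 0, 0, 1)),
        ([0, 0, 0, 0, 0], [P] * 5, (0, 0, 5, 0)),
    ],
)
def test_confusion_counts(pred, truth, expected):
    c = confusion_counts(pred, truth)
    assert (c.tp, c.fp, c.fn, c.tn) == expected


def test_confusion_rejects_nonbinary_predictions():
    with pytest.raises(ValueError):
        confusion_counts([2, 0], [P, N])


@pytest.mark.parametrize(
    "counts,mcc,acc,f1",
    [
        ((1, 0, 0, 1), 1.0, 1.0, 1.0),
        ((0, 1, 1, 0), -1.0, 0.0, 0.0),
        ((2, 2, 0, 0), 0.0, 0.5, 2 / 3),
    ],
)
def test_metric_set_examples(counts, mcc, acc, f1):
    m = metric_set(ConfusionCounts(*counts))
    assert m.mcc == pytest.approx(mcc)
    assert m.acc == pytest.approx(acc)
    assert m.f1 == pytest.approx(f1)


def test_metric_set_matches_oracle_on_random_counts():
    rng = np.random.default_rng(7)
    for _ in range(200):
        tp, fp, fn, tn = (int(x) for x in rng.integers(0, 6, size=4))
        m = metric_set(ConfusionCounts(tp, fp, fn, tn))
        pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
        truth = [P] * tp + [N] * fp + [P] * fn + [N] * tn
        assert m.mcc == pytest.approx(oracle_mcc(pred, truth))
        assert -1.0 <= m.mcc <= 1.0 and 0.0 <= m.f1 <= 1.0


# ---------------------------------------------------------------------------
# MCC-optimal threshold
# ---------------------------------------------------------------------------


def test_threshold_perfect_separation():
    thr, mcc, pred = optimal_mcc_threshold([0.2, 0.4, 0.6, 0.8], [N, N, P, P])
    assert thr == pytest.approx(0.5) and mcc == pytest.approx(1.0)
    assert pred.tolist() == [0, 0, 1, 1]


def test_threshold_all_equal_probs_gives_zero_mcc():
    _, mcc, _ = optimal_mcc_threshold([0.5] * 4, [P, N, P, N])
    assert mcc == pytest.approx(0.0)


def test_threshold_tie_broken_toward_smaller():
    thr, mcc, _ = optimal_mcc_threshold([0.9, 0.7, 0.5, 0.3], [P, N, P, N])
    assert thr == pytest.approx(0.4)
    assert mcc == pytest.approx(2 / math.sqrt(12))


def test_threshold_matches_exhaustive_oracle_with_unknowns():
    rng = np.random.default_rng(42)
    for _ in range(400):
        probs, truth = random_instance(rng, with_unknown=True)
        thr, mcc, _ = optimal_mcc_threshold(probs, truth)
        o_thr, o_mcc = oracle_best_threshold(probs, truth)
        assert mcc == pytest.approx(o_mcc)
        assert thr == pytest.approx(o_thr)


def test_threshold_label_swap_negates_mcc():
    rng = np.random.default_rng(3)
    for _ in range(100):
        probs, truth = random_instance(rng)
        _, mcc, _ = optimal_mcc_threshold(probs, truth)
        swapped = [N if t == P else P for t in truth]
        _, mcc_min, _ = optimal_mcc_threshold([-p for p in probs], swapped)
        # swapping labels and reversing the score axis preserves the optimum
        assert mcc_min == pytest.approx(mcc)


def test_threshold_single_class_errors():
    with pytest.raises(ValueError):
        optimal_mcc_threshold([0.1, 0.9], [P, P])


# ---------------------------------------------------------------------------
# ROC / PR
# ---------------------------------------------------------------------------


def test_roc_examples():
    assert roc_auc([0.9, 0.8, 0.3, 0.1], [P, P, N, N]).auc == pytest.approx(1.0)
    assert roc_auc([0.9, 0.7, 0.5, 0.3], [P, N, P, N]).auc == pytest.approx(0.75)
    assert roc_auc([0.5, 0.5], [P, N]).auc == pytest.approx(0.5)


def test_roc_curve_shape():
    res = roc_auc([0.9, 0.7, 0.5, 0.3], [P, N, P, N])
    fprs = [f for f, _ in res.points]
    assert res.points[0] == (0.0, 0.0) and res.points[-1] == (1.0, 1.0)
    assert fprs == sorted(fprs)


def test_roc_matches_pair_counting_oracle():
    rng = np.random.default_rng(11)
    for _ in range(400):
        probs, truth = random_instance(rng, with_unknown=True)
        assert roc_auc(probs, truth).auc == pytest.approx(oracle_auc_pairs(probs, truth))


def test_roc_label_swap_complements():
    rng = np.random.default_rng(12)
    for _ in range(100):
        probs, truth = random_instance(rng)
        swapped = [N if t == P else P for t in truth]
        assert roc_auc(probs, swapped).auc == pytest.approx(1.0 - roc_auc(probs, truth).auc)


def test_roc_monotone_transform_invariance():
    rng = np.random.default_rng(13)
    probs, truth = random_instance(rng, n_max=12)
    transformed = [p**3 / 2 + 0.1 for p in probs]
    assert roc_auc(transformed, truth).auc == pytest.approx(roc_auc(probs, truth).auc)
    _, mcc_a, _ = optimal_mcc_threshold(probs, truth)
    _, mcc_b, _ = optimal_mcc_threshold(transformed, truth)
    assert mcc_b == pytest.approx(mcc_a)


def test_pr_examples():
    assert pr_auc([0.9, 0.8, 0.3], [P, P, N]) == pytest.approx(1.0)
    # hand summation of the average-precision definition
    assert pr_auc([0.9, 0.7, 0.5, 0.3], [P, N, P, N]) == pytest.approx(1 * 0.5 + (2 / 3) * 0.5)


def test_pr_constant_probs_equals_prevalence():
    truth = [P, N, N, N, P]
    assert pr_auc([0.4] * 5, truth) == pytest.approx(2 / 5)


def test_pr_no_positives_errors():
    with pytest.raises(ValueError):
        pr_auc([0.1, 0.2], [N, N])


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def test_bootstrap_perfect_submission_has_zero_spread():
    probs = [0.9] * 5 + [0.1] * 5
    truth = [P] * 5 + [N] * 5
    boot = bootstrap_auc(probs, truth, n_iter=50, seed=0)
    assert np.all(boot.roc_aucs == 1.0) and boot.sd_roc_auc == 0.0


def test_bootstrap_deterministic_under_seed():
    rng = np.random.default_rng(5)
    probs = rng.random(60)
    truth = rng.choice([P, N], size=60)
    a = bootstrap_auc(probs, truth, n_iter=100, seed=9)
    b = bootstrap_auc(probs, truth, n_iter=100, seed=9)
    assert np.array_equal(a.roc_aucs, b.roc_aucs)
    assert np.array_equal(a.pr_aucs, b.pr_aucs)


def test_bootstrap_mean_near_point_auc():
    rng = np.random.default_rng(6)
    n = 200
    truth = np.array([P] * 100 + [N] * 100)
    probs = np.where(truth == P, rng.normal(0.8, 0.5, n), rng.normal(0.0, 0.5, n))
    probs = 1 / (1 + np.exp(-probs))
    boot = bootstrap_auc(probs, truth, n_iter=1000, seed=1)
    point = roc_auc(probs, truth).auc
    bound = 3 * boot.sd_roc_auc / math.sqrt(boot.n_iter) + boot.sd_roc_auc
    assert abs(boot.mean_roc_auc - point) < bound
    assert min(boot.roc_aucs) <= boot.mean_roc_auc <= max(boot.roc_aucs)


def test_bootstrap_stratified_preserves_class_counts_and_is_deterministic():
    probs = [0.9, 0.8, 0.2, 0.3, 0.1]
    truth = [P, P, N, N, N]
    a = bootstrap_auc(probs, truth, n_iter=50, seed=2, stratified=True)
    b = bootstrap_auc(probs, truth, n_iter=50, seed=2, stratified=True)
    assert np.array_equal(a.roc_aucs, b.roc_aucs)


def test_bootstrap_excludes_unknowns():
    probs = [0.9, 0.1, 0.5]
    boot = bootstrap_auc(probs, [P, N, U], n_iter=20, seed=0)
    assert np.all(boot.roc_aucs == 1.0)  # the unknown middle value never enters


def test_trait_seed_stability():
    s = trait_seed(17, "8.6", "ID")
    assert s == trait_seed(17, "8.6", "ID")
    assert s != trait_seed(17, "8.6", "ASD")
    assert s != trait_seed(18, "8.6", "ID")


# ---------------------------------------------------------------------------
# Whole-submission assessment
# ---------------------------------------------------------------------------


def test_assess_submission_order_invariance(small_submission, small_truth):
    res = assess_submission(small_submission, small_truth, n_boot=20, master_seed=1)
    perm = list(reversed(small_submission.probs.index))
    shuffled = PhenotypeSubmission(
        small_submission.submission_id,
        small_submission.group_id,
        small_submission.probs.loc[perm],
    )
    res2 = assess_submission(shuffled, small_truth.loc[perm], n_boot=0, master_seed=1)
    for trait in res:
        assert res[trait].metrics.mcc == pytest.approx(res2[trait].metrics.mcc)
        assert res[trait].point_roc_auc == pytest.approx(res2[trait].point_roc_auc)


def test_assess_submission_unknown_as_negative_changes_counts(small_submission, small_truth):
    base = assess_submission(small_submission, small_truth, n_boot=0)
    strict = assess_submission(small_submission, small_truth, n_boot=0, unknown_as_negative=True)
    n_unknown = int((small_truth == U).to_numpy().sum())
    total_base = sum(r.counts.n for r in base.values())
    total_strict = sum(r.counts.n for r in strict.values())
    assert total_strict == total_base + n_unknown
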
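"""Per-trait scoring of phenotype probability submissions.

Each of the seven traits is assessed as an independent two-class problem:

1. missing (``*``) probabilities are imputed as 0;
2. probabilities are binarized at the threshold maximizing the Matthews
   correlation coefficient (MCC) for that trait;
3. sensitivity, specificity, MCC, accuracy and F1 are computed at that
   threshold;
4. ROC and precision-recall curves, and their AUCs, are computed over 1000
   bootstrap resamples of the patients.

Truth labels are tri-state (positive / negative / unknown); patients with
unknown truth are excluded from confusion counts and from bootstrap
resampling by default (``unknown_as_negative=True`` gives the stricter
reading in which they count as negatives).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve

from .io_formats import NEGATIVE, POSITIVE, UNKNOWN, PhenotypeSubmission

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "RocResult",
    "BootstrapAUC",
    "TraitAssessment",
    "impute_missing",
    "confusion_counts",
    "metric_set",
    "optimal_mcc_threshold",
    "roc_auc",
    "pr_auc",
    "bootstrap_auc",
    "trait_seed",
    "assess_submission",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    mcc: float
    acc: float
    f1: float
    sensitivity: float
    specificity: float


@dataclass
class RocResult:
    """ROC curve points (fpr, tpr) sorted by fpr, and the trapezoidal AUC."""

    points: list[tuple[float, float]]
    auc: float


@dataclass
class BootstrapAUC:
    """Per-iteration bootstrap ROC/PR AUCs for one (submission, trait)."""

    n_iter: int
    seed: int
    roc_aucs: np.ndarray
    pr_aucs: np.ndarray
    mean_roc_auc: float = field(init=False)
    sd_roc_auc: float = field(init=False)
    mean_pr_auc: float = field(init=False)
    sd_pr_auc: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.roc_aucs) != self.n_iter:
            raise ValueError("roc_aucs length must equal n_iter")
        self.mean_roc_auc = float(np.mean(self.roc_aucs))
        self.sd_roc_auc = float(np.std(self.roc_aucs, ddof=1)) if self.n_iter > 1 else 0.0
        self.mean_pr_auc = float(np.mean(self.pr_aucs))
        self.sd_pr_auc = float(np.std(self.pr_aucs, ddof=1)) if self.n_iter > 1 else 0.0


# ---------------------------------------------------------------------------
# Imputation and confusion arithmetic
# ---------------------------------------------------------------------------


def impute_missing(sub: PhenotypeSubmission) -> PhenotypeSubmission:
    """Replace every missing cell by probability 0 (the challenge rule)."""
    return PhenotypeSubmission(sub.submission_id, sub.group_id, sub.probs.fillna(0.0))


def _as_arrays(probs, truth) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(probs, dtype=float)
    t = np.asarray(truth, dtype=int)
    if p.shape != t.shape:
        raise ValueError("probs and truth must have equal length")
    return p, t


def confusion_counts(binary_pred, truth) -> ConfusionCounts:
    """Count TP/FP/FN/TN; patients with UNKNOWN truth are excluded."""
    pred = np.asarray(binary_pred, dtype=int)
    t = np.asarray(truth, dtype=int)
    if pred.shape != t.shape:
        raise ValueError("predictions and truth must have equal length")
    if not np.isin(pred, (0, 1)).all():
        raise ValueError("binary predictions must be 0 or 1")
    known = t != UNKNOWN
    pred, t = pred[known], t[known]
    tp = int(np.sum((pred == 1) & (t == POSITIVE)))
    fp = int(np.sum((pred == 1) & (t == NEGATIVE)))
    fn = int(np.sum((pred == 0) & (t == POSITIVE)))
    tn = int(np.sum((pred == 0) & (t == NEGATIVE)))
    return ConfusionCounts(tp, fp, fn, tn)


def metric_set(c: ConfusionCounts) -> MetricSet:
    """MCC / ACC / F1 / sensitivity / specificity from confusion counts.

    Zero-denominator conventions: MCC is 0 whenever any factor of its
    denominator is 0; sensitivity, specificity and F1 are 0 when their
    denominators are 0.
    """
    tp, fp, fn, tn = c.tp, c.fp, c.fn, c.tn
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom2 == 0 else (tp * tn - fp * fn) / np.sqrt(float(denom2))
    acc = (tp + tn) / c.n if c.n else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    return MetricSet(float(mcc), float(acc), float(f1), float(sens), float(spec))


# ---------------------------------------------------------------------------
# MCC-optimal binarization
# ---------------------------------------------------------------------------


def _candidate_thresholds(probs: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct probabilities plus sentinels
    below the minimum and above the maximum."""
    uniq = np.unique(probs)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))


def optimal_mcc_threshold(probs, truth) -> tuple[float, float, np.ndarray]:
    """Find the binarization threshold maximizing MCC for one trait.

    The prediction rule is ``p >= t -> 1``.  Candidates are midpoints between
    consecutive distinct probabilities, with sentinels below the minimum and
    above the maximum; ties are broken toward the smallest threshold.
    Returns ``(threshold, mcc_at_threshold, binary_pred)``.
    """
    p, t = _as_arrays(probs, truth)
    known = t != UNKNOWN
    if not ((t[known] == POSITIVE).any() and (t[known] == NEGATIVE).any()):
        raise ValueError("optimal threshold undefined: truth has a single class")
    best_t, best_mcc, best_pred = None, -np.inf, None
    for cand in _candidate_thresholds(p):
        pred = (p >= cand).astype(int)
        mcc = metric_set(confusion_counts(pred, t)).mcc
        if mcc > best_mcc:  # strict: ties keep the smallest threshold
            best_t, best_mcc, best_pred = float(cand), mcc, pred
    return best_t, best_mcc, best_pred


# ---------------------------------------------------------------------------
# ROC / PR
# ---------------------------------------------------------------------------


def _known_binary(probs, truth) -> tuple[np.ndarray, np.ndarray]:
    p, t = _as_arrays(probs, truth)
    known = t != UNKNOWN
    return p[known], (t[known] == POSITIVE).astype(int)


def roc_auc(probs, truth) -> RocResult:
    """ROC curve and trapezoidal AUC over the threshold sweep.

    Equals the Mann-Whitney U statistic with ties counted 1/2.
    """
    p, y = _known_binary(probs, truth)
    if y.min() == y.max():
        raise ValueError("ROC undefined: truth has a single class")
    fpr, tpr, _ = roc_curve(y, p, drop_intermediate=False)
    return RocResult(points=list(zip(fpr.tolist(), tpr.tolist())), auc=float(_sk_auc(fpr, tpr)))


def pr_auc(probs, truth) -> float:
    """Precision-recall AUC in average-precision form (rectangular sum)."""
    p, y = _known_binary(probs, truth)
    if y.sum() == 0:
        raise ValueError("PR AUC undefined: no positive labels")
    return float(average_precision_score(y, p))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

_MAX_REDRAWS = 100


def bootstrap_auc(
    probs,
    truth,
    n_iter: int = 1000,
    seed: int = 0,
    stratified: bool = False,
) -> BootstrapAUC:
    """Bootstrap ROC/PR AUC distributions over patient resamples.

    Each iteration resamples the known-label patients with replacement to the
    same size.  In the default unstratified mode, a resample containing a
    single truth class is discarded and redrawn (at most 100 times, then an
    error advises stratified input); ``stratified=True`` instead resamples
    positives and negatives separately, preserving class counts.
    """
    p, y = _known_binary(probs, truth)
    n = len(p)
    if y.min() == y.max():
        raise ValueError("bootstrap undefined: truth has a single class")
    rng = np.random.default_rng(seed)
    roc_vals = np.empty(n_iter)
    pr_vals = np.empty(n_iter)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    for i in range(n_iter):
        if stratified:
            idx = np.concatenate(
                (rng.choice(pos_idx, size=len(pos_idx), replace=True),
                 rng.choice(neg_idx, size=len(neg_idx), replace=True))
            )
        else:
            for attempt in range(_MAX_REDRAWS + 1):
                idx = rng.integers(0, n, size=n)
                if y[idx].min() != y[idx].max():
                    break
            else:
                raise ValueError(
                    "bootstrap resample degenerate after "
                    f"{_MAX_REDRAWS} redraws; use stratified=True"
                )
        roc_vals[i] = roc_auc_score(y[idx], p[idx])
        pr_vals[i] = average_precision_score(y[idx], p[idx])
    return BootstrapAUC(n_iter=n_iter, seed=seed, roc_aucs=roc_vals, pr_aucs=pr_vals)


def trait_seed(master_seed: int, submission_id: str, trait: str) -> int:
    """Stable per-(submission, trait) seed derived from a master seed.

    Adding or removing a submission never perturbs another submission's
    bootstrap stream.
    """
    ss = np.random.SeedSequence(
        [int(master_seed), zlib.crc32(submission_id.encode()), zlib.crc32(trait.encode())]
    )
    return int(ss.generate_state(1)[0])


# ---------------------------------------------------------------------------
# Whole-submission assessment
# ---------------------------------------------------------------------------


@dataclass
class TraitAssessment:
    trait: str
    threshold: float
    counts: ConfusionCounts
    metrics: MetricSet
    point_roc_auc: float
    point_pr_auc: float
    bootstrap: BootstrapAUC | None
    binary_pred: pd.Series  # over all cohort patients


def assess_submission(
    sub: PhenotypeSubmission,
    answer_key: pd.DataFrame,
    n_boot: int = 1000,
    master_seed: int = 17,
    unknown_as_negative: bool = False,
    stratified: bool = False,
    on_single_class: str = "raise",
) -> dict[str, TraitAssessment]:
    """Run the full per-trait pipeline for one submission.

    ``answer_key`` is the tri-state patients x traits label matrix aligned to
    the submission.  All threshold-dependent metrics are computed at the
    MCC-optimal threshold.  ``on_single_class`` controls traits whose known
    labels contain a single class after any cohort restriction: ``"raise"``
    or ``"skip"`` (drop the trait with a warning).
    """
    if list(sub.probs.index) != list(answer_key.index):
        raise ValueError("submission and answer key patients differ")
    sub = impute_missing(sub)
    out: dict[str, TraitAssessment] = {}
    for trait in sub.probs.columns:
        probs = sub.probs[trait].to_numpy(dtype=float)
        truth = answer_key[trait].to_numpy(dtype=int)
        if unknown_as_negative:
            truth = np.where(truth == UNKNOWN, NEGATIVE, truth)
        known = truth[truth != UNKNOWN]
        if len(known) == 0 or known.min() == known.max():
            if on_single_class == "skip":
                warnings.warn(f"trait {trait}: single truth class, skipped", stacklevel=2)
                continue
            raise ValueError(f"trait {trait}: truth has a single class")
        thr, mcc, pred = optimal_mcc_threshold(probs, truth)
        counts = confusion_counts(pred, truth)
        boot = (
            bootstrap_auc(
                probs,
                truth,
                n_iter=n_boot,
                seed=trait_seed(master_seed, sub.submission_id, trait),
                stratified=stratified,
            )
            if n_boot > 0
            else None
        )
        out[trait] = TraitAssessment(
            trait=trait,
            threshold=thr,
            counts=counts,
            metrics=metric_set(counts),
            point_roc_auc=roc_auc(probs, truth).auc,
            point_pr_auc=pr_auc(probs, truth),
            bootstrap=boot,
            binary_pred=pd.Series(pred, index=sub.probs.index, name=trait),
        )
    return out
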
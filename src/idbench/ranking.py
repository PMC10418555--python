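"""Cross-submission standardization, ranking, and consensus summaries.

Submissions are compared per trait by standardizing their bootstrap-mean ROC
AUCs to z-scores (subtract the across-submission mean, divide by the sample
SD), then averaging z over traits; rank 1 goes to the highest mean z.  A
point-AUC input is supported through the same function for callers that skip
the bootstrap.

The module also provides the diagnosed-subset re-analysis (restrict the
cohort to patients with at least one answer-key variant and rerun the whole
phenotype pipeline) and the per-trait group-consensus histogram over
truth-positive patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import POSITIVE, PhenotypeSubmission, VariantAnswerKey
from .phenotype import TraitAssessment, assess_submission

__all__ = [
    "ZScoreTable",
    "GroupConsensusCounts",
    "zscore_by_trait",
    "auc_table",
    "diagnosed_subset",
    "rerun_on_subset",
    "group_consensus",
    "combine_group_binarized",
]


@dataclass
class ZScoreTable:
    """Per-trait z-scores, mean z per submission, and ranks (1 = best)."""

    z: pd.DataFrame  # submissions x traits
    mean_z: pd.Series
    rank: pd.Series


def zscore_by_trait(auc: pd.DataFrame) -> ZScoreTable:
    """Standardize a submissions x traits AUC matrix per trait.

    Sample (n-1) SD; a constant column maps to all-zero z.  Ranks sort by
    descending mean z with ties broken by submission id.  A single-submission
    table degenerates to all-zero z with rank 1 (warned).
    """
    if len(auc) < 2:
        warnings.warn("z-scores over fewer than 2 submissions are all zero", stacklevel=2)
        z = auc * 0.0
    else:
        mean = auc.mean(axis=0)
        sd = auc.std(axis=0, ddof=1)
        # a numerically constant column (sd at rounding noise) maps to z = 0
        z = (auc - mean).divide(sd.where(sd > 1e-12, np.inf), axis=1)
    mean_z = z.mean(axis=1)
    order = sorted(mean_z.index, key=lambda sid: (-mean_z[sid], str(sid)))
    rank = pd.Series({sid: i + 1 for i, sid in enumerate(order)}, name="rank").loc[
        mean_z.index
    ]
    return ZScoreTable(z=z, mean_z=mean_z.rename("mean_z"), rank=rank)


def auc_table(
    assessments: Mapping[str, Mapping[str, TraitAssessment]],
    use: str = "bootstrap_mean",
) -> pd.DataFrame:
    """Collect a submissions x traits AUC matrix from assessment results.

    ``use`` selects ``"bootstrap_mean"`` (the ranking default) or
    ``"point"``.  Traits missing from some submission become NaN.
    """
    if use not in ("bootstrap_mean", "point"):
        raise ValueError(f"unknown AUC selector {use!r}")
    rows = {}
    for sid, by_trait in assessments.items():
        row = {}
        for trait, ta in by_trait.items():
            if use == "bootstrap_mean" and ta.bootstrap is not None:
                row[trait] = ta.bootstrap.mean_roc_auc
            else:
                row[trait] = ta.point_roc_auc
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


# ---------------------------------------------------------------------------
# Diagnosed-subset re-analysis
# ---------------------------------------------------------------------------


def diagnosed_subset(key: VariantAnswerKey) -> set[str]:
    """Patients with at least one answer-key variant of any class."""
    return {pid for pid, _, _ in key.entries}


def rerun_on_subset(
    submissions: Sequence[PhenotypeSubmission],
    answer_key: pd.DataFrame,
    subset: set[str],
    n_boot: int = 1000,
    master_seed: int = 17,
    **assess_kwargs,
) -> dict[str, dict[str, TraitAssessment]]:
    """Rerun the full phenotype pipeline on a patient subset.

    Thresholds are re-optimized on the restricted cohort.  Traits left with a
    single truth class are dropped with a warning (and hence from any mean-z
    computed downstream).  With ``subset`` equal to the full cohort this is
    identical to the full run.
    """
    if not subset:
        raise ValueError("subset must be nonempty")
    keep = [pid for pid in answer_key.index if pid in subset]
    key_r = answer_key.loc[keep]
    out: dict[str, dict[str, TraitAssessment]] = {}
    for sub in submissions:
        sub_r = PhenotypeSubmission(sub.submission_id, sub.group_id, sub.probs.loc[keep])
        out[sub.submission_id] = assess_submission(
            sub_r,
            key_r,
            n_boot=n_boot,
            master_seed=master_seed,
            on_single_class="skip",
            **assess_kwargs,
        )
    return out


# ---------------------------------------------------------------------------
# Group consensus on phenotypes
# ---------------------------------------------------------------------------


def combine_group_binarized(
    binarized: Sequence[pd.DataFrame], mode: str = "any"
) -> pd.DataFrame:
    """Combine per-submission 0/1 matrices into one group-level matrix.

    ``"any"`` (default): the group predicts positive iff at least one of its
    submissions does; ``"all"`` is the strict reading.
    """
    if not binarized:
        raise ValueError("need at least one binarized matrix")
    stack = np.stack([b.to_numpy(dtype=int) for b in binarized])
    combined = stack.max(axis=0) if mode == "any" else stack.min(axis=0)
    if mode not in ("any", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(combined, index=binarized[0].index, columns=binarized[0].columns)


@dataclass
class GroupConsensusCounts:
    """Per trait, for each truth-positive patient, the number of groups
    predicting positive; plus the histogram over 0..n_groups."""

    n_groups: int
    per_patient: dict[str, pd.Series]  # trait -> counts over truth-positive patients
    histogram: pd.DataFrame  # traits x k


def group_consensus(
    predictions_by_group: Mapping[str, pd.DataFrame],
    answer_key: pd.DataFrame,
) -> GroupConsensusCounts:
    """Histogram of how many groups correctly flag each truth-positive patient.

    ``predictions_by_group`` maps group id to a patients x traits 0/1 matrix
    (already binarized at each submission's MCC-optimal threshold and
    combined over the group's submissions).  Truth-negative and unknown
    patients are excluded; each trait's histogram totals its positive count.
    """
    groups = list(predictions_by_group)
    n_groups = len(groups)
    per_patient: dict[str, pd.Series] = {}
    hist = pd.DataFrame(
        0, index=list(answer_key.columns), columns=range(n_groups + 1), dtype=int
    )
    for trait in answer_key.columns:
        pos_patients = answer_key.index[answer_key[trait] == POSITIVE]
        counts = pd.Series(0, index=pos_patients, dtype=int)
        for gid in groups:
            pred = predictions_by_group[gid]
            counts += pred.loc[pos_patients, trait].astype(int)
        per_patient[trait] = counts
        for k in counts:
            hist.loc[trait, int(k)] += 1
    return GroupConsensusCounts(n_groups, per_patient, hist)
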
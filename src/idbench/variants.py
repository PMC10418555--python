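"""Matching predicted variants against the classified answer key.

The variant track is a multi-label problem: the laboratory assigned each
diagnosed patient one or more classified variants (DC = disease causing,
LP = likely pathogenic / putative, CF = contributing factor), and each
submission lists zero or more (patient, variant) assignments.  A true
positive is an identity match of (patient, normalized variant); predicted
class labels, if any, play no role.  True negatives are not evaluated.

Cohort-level scores follow the challenge's naming: recall is correct
predictions over answer-key variants, and "accuracy" is correct predictions
over all predicted variants — precision under standard naming; the
challenge's term is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import (
    VARIANT_CLASSES,
    VariantAnswerKey,
    VariantKey,
    VariantPredictionSet,
    normalize_chrom,
)

__all__ = [
    "MatchResult",
    "CohortVariantScore",
    "ClassCoverage",
    "ConsensusHistogram",
    "normalize_variant",
    "match_patient_variants",
    "cohort_score",
    "class_coverage",
    "consensus_histogram",
    "union_predictions",
]


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def _ref_base(reference: Mapping[str, object], chrom: str, pos0: int) -> str:
    """Base at 0-based ``pos0`` from a dict of strings or a pyfaidx-like map."""
    for name in (chrom, f"chr{chrom}"):
        if name in reference:
            return str(reference[name][pos0]).upper()
    raise KeyError(f"chromosome {chrom} not in reference")


def normalize_variant(
    key: VariantKey, reference: Mapping[str, object] | None = None
) -> VariantKey:
    """Reduce a variant to its minimal, left-most representation.

    Without a reference: trim the common suffix, then the common prefix,
    always keeping at least one base on each allele (adjusting ``pos`` when
    the prefix shrinks).  With a per-chromosome reference, indels are
    additionally left-aligned (shifted to the smallest position at which the
    representation is valid) before the final prefix trim.  Idempotent.
    """
    ref, alt, pos = key.ref, key.alt, key.pos
    # suffix trim, keeping >= 1 base each
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    if reference is not None and len(ref) != len(alt):
        # left-align: repeatedly drop a shared last base (extending left from
        # the reference when an allele would empty) until no longer possible
        while pos > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                base = _ref_base(reference, key.chrom, pos - 2)
                ref, alt, pos = base + ref, base + alt, pos - 1
    # prefix trim, keeping >= 1 base each
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if not ref or not alt:
        raise ValueError(f"degenerate representation after trimming {key.token()}")
    return VariantKey(key.chrom, pos, ref, alt)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


@dataclass
class MatchResult:
    """TP / FP / FN entry lists for one submission against the key.

    ``tp_entries`` and ``fn_entries`` carry the answer-key class; together
    they partition the key.  ``fp_entries`` are predictions matching nothing.
    """

    submission_id: str
    tp_entries: list[tuple[str, VariantKey, str]]
    fp_entries: list[tuple[str, VariantKey]]
    fn_entries: list[tuple[str, VariantKey, str]]

    @property
    def n_correct(self) -> int:
        return len(self.tp_entries)

    @property
    def n_predicted(self) -> int:
        return len(self.tp_entries) + len(self.fp_entries)

    @property
    def n_key(self) -> int:
        return len(self.tp_entries) + len(self.fn_entries)


def match_patient_variants(
    preds: VariantPredictionSet,
    key: VariantAnswerKey,
    reference: Mapping[str, object] | None = None,
) -> MatchResult:
    """Match predictions to the answer key by (patient, normalized variant).

    Duplicate predicted entries for the same identity are deduplicated before
    counting (and logged), so repeating a variant cannot inflate recall or
    accuracy.
    """
    key_map: dict[tuple[str, VariantKey], str] = {}
    for pid, vkey, cls in key.entries:
        key_map[(pid, normalize_variant(vkey, reference))] = cls

    seen: set[tuple[str, VariantKey]] = set()
    dropped = 0
    tp: list[tuple[str, VariantKey, str]] = []
    fp: list[tuple[str, VariantKey]] = []
    for pid, vkey in preds.entries:
        ident = (pid, normalize_variant(vkey, reference))
        if ident in seen:
            dropped += 1
            continue
        seen.add(ident)
        cls = key_map.get(ident)
        if cls is None:
            fp.append(ident)
        else:
            tp.append((*ident, cls))
    if dropped:
        import logging

        logging.getLogger("idbench").info(
            "%s: deduplicated %d repeated predictions", preds.submission_id, dropped
        )
    matched = {(pid, vkey) for pid, vkey, _ in tp}
    fn = [(pid, vkey, cls) for (pid, vkey), cls in key_map.items() if (pid, vkey) not in matched]
    return MatchResult(preds.submission_id, tp, fp, fn)


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------


@dataclass
class CohortVariantScore:
    """Table-style summary: counts plus recall and "accuracy" (precision)."""

    n_correct: int
    n_predicted: int
    n_key: int
    recall: float | None
    accuracy: float | None

    def rounded(self) -> tuple[float | None, float | None]:
        """(recall, accuracy) rounded to 3 decimals, the reporting precision."""
        r = None if self.recall is None else round(self.recall, 3)
        a = None if self.accuracy is None else round(self.accuracy, 3)
        return r, a


def cohort_score(
    match: MatchResult | None = None,
    *,
    n_correct: int | None = None,
    n_predicted: int | None = None,
    n_key: int | None = None,
) -> CohortVariantScore:
    """Recall and accuracy from a match result or from raw count triples.

    Zero denominators yield None (undefined), never 0.
    """
    if match is not None:
        n_correct, n_predicted, n_key = match.n_correct, match.n_predicted, match.n_key
    if n_correct is None or n_predicted is None or n_key is None:
        raise ValueError("provide a MatchResult or all three counts")
    if n_correct > min(n_predicted, n_key):
        raise ValueError("n_correct cannot exceed n_predicted or n_key")
    recall = n_correct / n_key if n_key else None
    accuracy = n_correct / n_predicted if n_predicted else None
    return CohortVariantScore(n_correct, n_predicted, n_key, recall, accuracy)


@dataclass
class ClassCoverage:
    """Per-class (DC/LP/CF) answer-key coverage of one prediction set."""

    n_key_in_class: dict[str, int]
    n_correct_in_class: dict[str, int]
    coverage_percent: dict[str, float | None]


def class_coverage(match: MatchResult) -> ClassCoverage:
    """Percentage of each answer-key class recovered by the predictions."""
    n_key = {c: 0 for c in VARIANT_CLASSES}
    n_hit = {c: 0 for c in VARIANT_CLASSES}
    for _, _, cls in match.tp_entries:
        n_key[cls] += 1
        n_hit[cls] += 1
    for _, _, cls in match.fn_entries:
        n_key[cls] += 1
    pct = {
        c: (100.0 * n_hit[c] / n_key[c]) if n_key[c] else None for c in VARIANT_CLASSES
    }
    return ClassCoverage(n_key, n_hit, pct)


# ---------------------------------------------------------------------------
# Cross-group consensus
# ---------------------------------------------------------------------------


def union_predictions(
    group_id: str, sets: Sequence[VariantPredictionSet]
) -> VariantPredictionSet:
    """A group's prediction set: the union of its submissions' entries."""
    seen: set[tuple[str, VariantKey]] = set()
    entries: list[tuple[str, VariantKey]] = []
    for vp in sets:
        for ident in vp.entries:
            if ident not in seen:
                seen.add(ident)
                entries.append(ident)
    return VariantPredictionSet(f"{group_id}.union", group_id, entries)


@dataclass
class ConsensusHistogram:
    """Per answer-key variant, how many groups correctly predicted it.

    ``per_variant`` maps (patient, variant) -> (class, k); ``histogram`` is a
    class x k table whose row sums equal each class's key count.
    """

    n_groups: int
    per_variant: dict[tuple[str, VariantKey], tuple[str, int]]
    histogram: pd.DataFrame

    def class_total(self, cls: str) -> int:
        return int(self.histogram.loc[cls].sum())


def consensus_histogram(
    per_group_matches: Sequence[MatchResult],
    key: VariantAnswerKey,
    reference: Mapping[str, object] | None = None,
) -> ConsensusHistogram:
    """Count, for each key entry, the groups whose TP set contains it.

    Pass one MatchResult per group (built from the union of the group's
    submissions) and the same ``reference`` used for matching; adding a
    submission to a group can only grow its TP set, so per-variant counts
    are monotone in group membership.
    """
    n_groups = len(per_group_matches)
    counts: dict[tuple[str, VariantKey], tuple[str, int]] = {
        (pid, normalize_variant(vkey, reference)): (cls, 0)
        for pid, vkey, cls in key.entries
    }
    for match in per_group_matches:
        for pid, vkey, cls in match.tp_entries:
            if (pid, vkey) in counts:
                c, k = counts[(pid, vkey)]
                counts[(pid, vkey)] = (c, k + 1)
    hist = pd.DataFrame(
        0, index=list(VARIANT_CLASSES), columns=range(n_groups + 1), dtype=int
    )
    for cls, k in counts.values():
        hist.loc[cls, k] += 1
    return ConsensusHistogram(n_groups, counts, hist)
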
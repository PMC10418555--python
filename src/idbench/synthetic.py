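"""Synthetic cohorts, answer keys, panel VCFs and submissions.

The original patient data behind the challenge are not distributable, so
this module generates stand-ins with the statistical structure the
assessment assumes: a 415-patient cohort whose per-trait positive counts
match the published prevalences, a 217-variant classified answer key
(60 DC + 54 LP + 103 CF, one diagnosed patient per entry), per-patient
panel VCFs carrying the planted variants plus benign background and
low-quality decoy records, and submissions of tunable skill.

Phenotype submissions follow a binormal score model: for a trait with
separation mu, truth-positive patients draw a latent score ~ Normal(mu, 1)
and everyone else ~ Normal(0, 1); the reported probability is the logistic
of the score, so the expected ROC AUC is Phi(mu / sqrt(2)).  Variant
submissions include each answer-key entry with a per-submission sensitivity
and add Poisson-distributed spurious calls per patient.

Every generator is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .io_formats import (
    NEGATIVE,
    POSITIVE,
    TRAITS,
    UNKNOWN,
    CohortDefinition,
    PhenotypeSubmission,
    VariantAnswerKey,
    VariantKey,
    VariantPredictionSet,
    VcfEntry,
    write_bed,
    write_phenotype_answer_key,
    write_phenotype_submission,
    write_variant_answer_key,
    write_variant_predictions,
    write_vcf,
)

import pandas as pd

__all__ = [
    "CohortSpec",
    "VariantKeySpec",
    "SkillProfile",
    "DEFAULT_POSITIVES",
    "DEFAULT_NEGATIVES",
    "default_panel",
    "make_cohort",
    "generate_truth",
    "generate_variant_key",
    "generate_patient_vcf",
    "simulate_phenotype_submission",
    "simulate_variant_submission",
    "generate_challenge",
    "QUAL_MIN",
    "DP_MIN",
    "GQ_MIN",
    "passes_quality",
]

#: Published per-trait positive counts in the 415-patient cohort.
DEFAULT_POSITIVES: dict[str, int] = {
    "ID": 352,
    "ASD": 205,
    "Epilepsy": 84,
    "Microcephaly": 45,
    "Macrocephaly": 47,
    "Hypotonia": 71,
    "Ataxia": 30,
}

#: Known-negative counts where published; other traits default to
#: n_patients - positives (no unknowns).
DEFAULT_NEGATIVES: dict[str, int] = {"Hypotonia": 254, "Ataxia": 285}

# Quality cuts a record must clear to count as a confident call.  The
# challenge names the fields (QUAL, coverage, genotype quality) but fixes no
# thresholds; these are this package's conventions, and decoys are generated
# to fail at least one of them.
QUAL_MIN, DP_MIN, GQ_MIN = 20.0, 10, 20
_HI_QUAL, _HI_DP, _HI_GQ = 100.0, 50, 90


def passes_quality(entry: VcfEntry) -> bool:
    """True iff the record clears all three quality cuts."""
    return (
        entry.qual is not None
        and entry.qual >= QUAL_MIN
        and entry.depth is not None
        and entry.depth >= DP_MIN
        and entry.genotype_quality is not None
        and entry.genotype_quality >= GQ_MIN
    )


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    n_patients: int = 415
    positives: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_POSITIVES))
    negatives: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_NEGATIVES))
    #: optional ID/ASD comorbidity coupling: extra sampling weight pulling ASD
    #: positives toward ID-positive patients (0 = independent traits)
    comorbidity: float = 0.0
    seed: int = 0

    def negative_count(self, trait: str) -> int:
        if trait in self.negatives:
            return int(self.negatives[trait])
        return self.n_patients - int(self.positives[trait])

    def validate(self) -> None:
        for trait, pos in self.positives.items():
            neg = self.negative_count(trait)
            if pos > self.n_patients or neg < 0 or pos + neg > self.n_patients:
                raise ValueError(f"trait {trait}: {pos}+{neg} exceeds cohort size")


@dataclass
class VariantKeySpec:
    """Answer-key composition.  The class totals are derived quantities:
    60 DC is published directly; the 217-entry total is consistent with all
    published recall/count ratios; CF ~ 103 follows from the reported
    never/once-predicted fractions, and LP = 217 - 60 - 103 = 54."""

    n_dc: int = 60
    n_lp: int = 54
    n_cf: int = 103
    n_diagnosed_patients: int = 217
    gene_regions: Sequence[tuple[str, int, int, str]] | None = None
    seed: int = 0

    @property
    def n_total(self) -> int:
        return self.n_dc + self.n_lp + self.n_cf

    def validate(self) -> None:
        if self.n_total < self.n_diagnosed_patients:
            raise ValueError("fewer entries than diagnosed patients (each needs >= 1)")


@dataclass
class SkillProfile:
    """Generative skill of one simulated submission.

    ``mu`` is the binormal separation (scalar, or per-trait mapping); the
    expected ROC AUC is Phi(mu / sqrt(2)).  ``miss_rate`` is the probability
    a probability cell is emitted as missing.  ``variant_sensitivity`` is the
    per-entry recovery probability on the variant track and
    ``variant_fp_per_patient`` the Poisson rate of spurious calls.
    """

    mu: float | Mapping[str, float] = 1.0
    miss_rate: float = 0.0
    variant_sensitivity: float = 0.8
    variant_fp_per_patient: float = 0.5

    def mu_for(self, trait: str) -> float:
        if isinstance(self.mu, Mapping):
            return float(self.mu[trait])
        return float(self.mu)

    @staticmethod
    def mu_from_auc(auc: float) -> float:
        """Separation giving expected ROC AUC ``auc``: mu = sqrt(2) Phi^-1(auc)."""
        if not 0.5 <= auc < 1.0:
            raise ValueError("target AUC must be in [0.5, 1)")
        return float(np.sqrt(2.0) * norm.ppf(auc))

    @staticmethod
    def expected_auc(mu: float) -> float:
        return float(norm.cdf(mu / np.sqrt(2.0)))


# ---------------------------------------------------------------------------
# Panel and cohort
# ---------------------------------------------------------------------------

_CHROMS = [str(c) for c in range(1, 23)] + ["X"]


def default_panel(
    n_genes: int = 74, region_length: int = 2000
) -> list[tuple[str, int, int, str]]:
    """A toy 74-region capture panel: one interval per gene, spread over
    chromosomes 1-22 and X, half-open 0-based coordinates."""
    regions = []
    for i in range(n_genes):
        chrom = _CHROMS[i % len(_CHROMS)]
        start = 1_000_000 + (i // len(_CHROMS)) * 100_000
        regions.append((chrom, start, start + region_length, f"GENE{i + 1:02d}"))
    return regions


def make_cohort(spec: CohortSpec | None = None, gene_regions=None) -> CohortDefinition:
    spec = spec or CohortSpec()
    regions = tuple(gene_regions) if gene_regions is not None else tuple(default_panel())
    ids = tuple(f"P{i:04d}" for i in range(1, spec.n_patients + 1))
    return CohortDefinition(patient_ids=ids, trait_names=TRAITS, gene_regions=regions)


# ---------------------------------------------------------------------------
# Truth and answer key
# ---------------------------------------------------------------------------


def generate_truth(spec: CohortSpec, cohort: CohortDefinition | None = None) -> pd.DataFrame:
    """Tri-state truth labels with exact per-trait marginals.

    Each trait column independently assigns exactly the specified positive
    and known-negative counts by seeded shuffling; the remainder is unknown.
    Joint structure is product-of-marginals.
    """
    spec.validate()
    cohort = cohort or make_cohort(spec)
    rng = np.random.default_rng(spec.seed)
    labels = pd.DataFrame(
        UNKNOWN, index=list(cohort.patient_ids), columns=list(cohort.trait_names), dtype=np.int8
    )
    for trait in cohort.trait_names:
        n_pos = int(spec.positives[trait])
        n_neg = spec.negative_count(trait)
        col = np.full(spec.n_patients, UNKNOWN, dtype=np.int8)
        if trait == "ASD" and spec.comorbidity > 0 and "ID" in labels:
            # weighted draw couples ASD positives to ID-positive patients
            # while keeping both marginals exact
            w = np.ones(spec.n_patients)
            w[(labels["ID"] == POSITIVE).to_numpy()] += spec.comorbidity
            pos_idx = rng.choice(
                spec.n_patients, size=n_pos, replace=False, p=w / w.sum()
            )
            col[pos_idx] = POSITIVE
            rest = rng.permutation(np.flatnonzero(col != POSITIVE))
            col[rest[:n_neg]] = NEGATIVE
        else:
            order = rng.permutation(spec.n_patients)
            col[order[:n_pos]] = POSITIVE
            col[order[n_pos : n_pos + n_neg]] = NEGATIVE
        labels[trait] = col
    return labels


def _random_variant(rng: np.random.Generator, regions, taken: set) -> VariantKey:
    """A random SNV (80%) or short indel inside a random panel region, not
    colliding with already-taken keys."""
    bases = "ACGT"
    for _ in range(1000):
        chrom, start, end, _gene = regions[rng.integers(len(regions))]
        # keep indel ref spans inside the region
        pos = int(rng.integers(start + 1, end - 4))
        kind = rng.random()
        anchor = bases[rng.integers(4)]
        if kind < 0.8:  # SNV
            ref = anchor
            alt = bases[(bases.index(anchor) + int(rng.integers(1, 4))) % 4]
        elif kind < 0.9:  # insertion
            ref = anchor
            alt = anchor + "".join(bases[rng.integers(4)] for _ in range(int(rng.integers(1, 4))))
        else:  # deletion
            ref = anchor + "".join(bases[rng.integers(4)] for _ in range(int(rng.integers(1, 4))))
            alt = anchor
        key = VariantKey(chrom, pos, ref, alt)
        if key not in taken:
            taken.add(key)
            return key
    raise ValueError("panel regions too small for the requested variant count")


def generate_variant_key(
    spec: VariantKeySpec, truth: pd.DataFrame
) -> VariantAnswerKey:
    """Plant a classified answer key over preferentially trait-positive patients.

    Exactly ``n_dc + n_lp + n_cf`` entries are distributed over exactly
    ``n_diagnosed_patients`` (each gets at least one); every variant lies
    inside a panel region.
    """
    spec.validate()
    regions = list(spec.gene_regions) if spec.gene_regions is not None else default_panel()
    rng = np.random.default_rng(spec.seed)
    patients = np.asarray(truth.index)
    if spec.n_diagnosed_patients > len(patients):
        raise ValueError("more diagnosed patients than cohort members")
    n_pos_traits = (truth.to_numpy() == POSITIVE).sum(axis=1)
    has_pos = n_pos_traits > 0
    pos_pool = patients[has_pos]
    other_pool = patients[~has_pos]
    rng.shuffle(pos_pool)
    rng.shuffle(other_pool)
    ordered = np.concatenate([pos_pool, other_pool])
    diagnosed = list(ordered[: spec.n_diagnosed_patients])

    classes = ["DC"] * spec.n_dc + ["LP"] * spec.n_lp + ["CF"] * spec.n_cf
    rng.shuffle(classes)
    # one entry per diagnosed patient first, extras to random diagnosed patients
    owners = list(diagnosed)
    extra = spec.n_total - len(diagnosed)
    if extra > 0:
        owners += list(rng.choice(diagnosed, size=extra, replace=True))
    taken: set[VariantKey] = set()
    entries = [
        (str(pid), _random_variant(rng, regions, taken), cls)
        for pid, cls in zip(owners, classes)
    ]
    return VariantAnswerKey(entries)


# ---------------------------------------------------------------------------
# VCFs
# ---------------------------------------------------------------------------

_CHROM_ORDER = {c: i for i, c in enumerate(_CHROMS + ["Y", "MT"])}


def _sort_key(e: VcfEntry):
    return (_CHROM_ORDER.get(e.key.chrom, 99), e.key.pos, e.key.ref, e.key.alt)


def generate_patient_vcf(
    patient_id: str,
    key: VariantAnswerKey,
    gene_regions,
    background_rate: float = 5.0,
    decoy_rate: float = 3.0,
    seed: int = 0,
) -> list[VcfEntry]:
    """VCF records for one patient: planted key variants (high quality),
    Poisson(background_rate) benign background variants (high quality) and
    Poisson(decoy_rate) decoys, each failing at least one of the
    QUAL/DP/GQ cuts."""
    rng = np.random.default_rng(seed)
    regions = list(gene_regions)
    taken: set[VariantKey] = set()
    records: list[VcfEntry] = []

    def high_quality(vkey: VariantKey) -> VcfEntry:
        return VcfEntry(
            key=vkey,
            qual=float(np.round(_HI_QUAL + rng.uniform(0, 900), 1)),
            depth=int(rng.integers(_HI_DP, 300)),
            genotype_quality=int(rng.integers(_HI_GQ, 100)),
            genotype="0/1",
        )

    for pid, vkey, _cls in key.entries:
        if pid == patient_id:
            taken.add(vkey)
            records.append(high_quality(vkey))
    for _ in range(rng.poisson(background_rate)):
        records.append(high_quality(_random_variant(rng, regions, taken)))
    for _ in range(rng.poisson(decoy_rate)):
        vkey = _random_variant(rng, regions, taken)
        fail = rng.integers(1, 8)  # nonempty subset of the 3 cuts, bit-coded
        qual = float(np.round(rng.uniform(0, QUAL_MIN - 1), 1)) if fail & 1 else float(
            np.round(_HI_QUAL + rng.uniform(0, 900), 1)
        )
        depth = int(rng.integers(0, DP_MIN)) if fail & 2 else int(rng.integers(_HI_DP, 300))
        gq = int(rng.integers(0, GQ_MIN)) if fail & 4 else int(rng.integers(_HI_GQ, 100))
        records.append(VcfEntry(vkey, qual, depth, gq, "0/1"))
    records.sort(key=_sort_key)
    return records


# ---------------------------------------------------------------------------
# Simulated submissions
# ---------------------------------------------------------------------------


def simulate_phenotype_submission(
    truth: pd.DataFrame,
    profile: SkillProfile,
    seed: int = 0,
    submission_id: str = "1.1",
    group_id: str | None = None,
) -> PhenotypeSubmission:
    """Binormal-model probabilities: positives score ~ N(mu, 1), everyone
    else ~ N(0, 1); probability = logistic(score); cells go missing
    independently with ``miss_rate``."""
    rng = np.random.default_rng(seed)
    n = len(truth.index)
    probs = pd.DataFrame(index=truth.index, columns=truth.columns, dtype=float)
    for trait in truth.columns:
        mu = profile.mu_for(trait)
        is_pos = (truth[trait] == POSITIVE).to_numpy()
        scores = rng.normal(0.0, 1.0, size=n) + mu * is_pos
        p = 1.0 / (1.0 + np.exp(-scores))
        if profile.miss_rate > 0:
            p[rng.random(n) < profile.miss_rate] = np.nan
        probs[trait] = p
    gid = group_id if group_id is not None else submission_id.split(".")[0]
    return PhenotypeSubmission(submission_id, gid, probs)


def simulate_variant_submission(
    key: VariantAnswerKey,
    profile: SkillProfile,
    patient_ids: Sequence[str],
    gene_regions,
    seed: int = 0,
    submission_id: str = "1.1",
    group_id: str | None = None,
) -> VariantPredictionSet:
    """Include each key entry with probability ``variant_sensitivity``; add
    Poisson(``variant_fp_per_patient``) spurious calls per patient at
    non-key panel positions."""
    rng = np.random.default_rng(seed)
    regions = list(gene_regions)
    taken: set[VariantKey] = {vkey for _, vkey, _ in key.entries}
    entries: list[tuple[str, VariantKey]] = []
    for pid, vkey, _cls in key.entries:
        if rng.random() < profile.variant_sensitivity:
            entries.append((pid, vkey))
    for pid in patient_ids:
        for _ in range(rng.poisson(profile.variant_fp_per_patient)):
            entries.append((str(pid), _random_variant(rng, regions, taken)))
    gid = group_id if group_id is not None else submission_id.split(".")[0]
    return VariantPredictionSet(submission_id, gid, entries)


# ---------------------------------------------------------------------------
# Full challenge bundle
# ---------------------------------------------------------------------------

#: Target ROC AUCs of the default simulated submissions (one per group).
DEFAULT_SUBMISSION_AUCS: tuple[float, ...] = (0.55, 0.65, 0.75, 0.85)
DEFAULT_SUBMISSION_SENSITIVITIES: tuple[float, ...] = (0.35, 0.50, 0.65, 0.82)
DEFAULT_SUBMISSION_FP_RATES: tuple[float, ...] = (1.0, 0.6, 0.3, 0.3)
DEFAULT_MISS_RATE = 0.02


def generate_challenge(
    out_dir: str | Path,
    cohort_spec: CohortSpec | None = None,
    key_spec: VariantKeySpec | None = None,
    target_aucs: Sequence[float] = DEFAULT_SUBMISSION_AUCS,
    variant_sensitivities: Sequence[float] = DEFAULT_SUBMISSION_SENSITIVITIES,
    variant_fp_rates: Sequence[float] = DEFAULT_SUBMISSION_FP_RATES,
    miss_rate: float = DEFAULT_MISS_RATE,
    background_rate: float = 5.0,
    decoy_rate: float = 3.0,
    seed: int = 0,
    write_vcfs: bool = True,
) -> dict[str, object]:
    """Generate and write a complete synthetic challenge to ``out_dir``.

    Emits the panel BED, tri-state phenotype answer key, classified variant
    answer key, per-patient VCFs (``vcf/``) and one submission pair per
    target AUC (``submissions/``).  Returns the in-memory objects.
    """
    out = Path(out_dir)
    (out / "submissions").mkdir(parents=True, exist_ok=True)
    if write_vcfs:
        (out / "vcf").mkdir(exist_ok=True)
    root = np.random.SeedSequence(seed)
    seeds = iter(root.generate_state(4 + 2 * len(target_aucs) + 10_000))

    cohort_spec = cohort_spec or CohortSpec(seed=int(next(seeds)) % (2**31))
    key_spec = key_spec or VariantKeySpec(seed=int(next(seeds)) % (2**31))
    cohort = make_cohort(cohort_spec, key_spec.gene_regions)
    truth = generate_truth(cohort_spec, cohort)
    key = generate_variant_key(
        VariantKeySpec(
            key_spec.n_dc,
            key_spec.n_lp,
            key_spec.n_cf,
            key_spec.n_diagnosed_patients,
            cohort.gene_regions,
            key_spec.seed,
        ),
        truth,
    )

    write_bed(cohort.gene_regions, out / "panel.bed")
    write_phenotype_answer_key(truth, out / "phenotype_key.tsv")
    write_variant_answer_key(key, out / "variant_key.tsv")

    if write_vcfs:
        for pid in cohort.patient_ids:
            records = generate_patient_vcf(
                pid,
                key,
                cohort.gene_regions,
                background_rate=background_rate,
                decoy_rate=decoy_rate,
                seed=int(next(seeds)) % (2**31),
            )
            write_vcf(records, out / "vcf" / f"{pid}.vcf", sample_name=pid)

    submissions = []
    prediction_sets = []
    for i, auc in enumerate(target_aucs):
        sid = f"{i + 1}.1"
        profile = SkillProfile(
            mu=SkillProfile.mu_from_auc(auc),
            miss_rate=miss_rate,
            variant_sensitivity=variant_sensitivities[i % len(variant_sensitivities)],
            variant_fp_per_patient=variant_fp_rates[i % len(variant_fp_rates)],
        )
        sub = simulate_phenotype_submission(
            truth, profile, seed=int(next(seeds)) % (2**31), submission_id=sid
        )
        vp = simulate_variant_submission(
            key,
            profile,
            cohort.patient_ids,
            cohort.gene_regions,
            seed=int(next(seeds)) % (2**31),
            submission_id=sid,
        )
        write_phenotype_submission(sub, out / "submissions" / f"sub_{sid}_phenotypes.tsv")
        write_variant_predictions(vp, out / "submissions" / f"sub_{sid}_variants.tsv")
        submissions.append(sub)
        prediction_sets.append(vp)

    return {
        "cohort": cohort,
        "truth": truth,
        "variant_key": key,
        "submissions": submissions,
        "prediction_sets": prediction_sets,
    }
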
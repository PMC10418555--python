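"""Readers, writers and validators for the challenge's on-disk dialects.

The assessment exchanges four kinds of files:

* phenotype submissions — TSV, one row per patient, one probability column per
  trait, ``*`` marking a cell the predictor declined to fill;
* variant predictions — TSV of ``patient_id<TAB>variant_token[<TAB>score]``;
* answer keys — tri-state phenotype labels and a classified variant list;
* sequencing inputs — single-sample VCF 4.2 and a BED4 file of captured
  panel regions.

Coordinates follow the standard conventions: VCF positions are 1-based,
BED intervals are half-open 0-based.  Chromosome names are compared after
stripping any ``chr`` prefix, case-insensitively, because hg19 files
circulate in both conventions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger("idbench")

#: Fixed trait order of the challenge template.
TRAITS: tuple[str, ...] = (
    "ID",
    "ASD",
    "Epilepsy",
    "Microcephaly",
    "Macrocephaly",
    "Hypotonia",
    "Ataxia",
)

#: Answer-key variant classes: disease causing, likely pathogenic ("putative"),
#: contributing factor (autism-susceptibility genes, insufficient alone).
VARIANT_CLASSES: tuple[str, ...] = ("DC", "LP", "CF")

#: Marker predictors leave in a probability cell they decline to fill.
MISSING_MARKER = "*"

_VALID_BASES = frozenset("ACGTN")


def normalize_chrom(chrom: str) -> str:
    """Strip a ``chr`` prefix and uppercase, so ``chr1``/``1`` compare equal."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortDefinition:
    """The cohort under assessment: patients, traits, and panel regions."""

    patient_ids: tuple[str, ...]
    trait_names: tuple[str, ...] = TRAITS
    gene_regions: tuple[tuple[str, int, int, str], ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("patient_ids must be unique")
        if len(set(self.trait_names)) != len(self.trait_names):
            raise ValueError("trait_names must be unique")
        for chrom, start, end, gene in self.gene_regions:
            if start >= end:
                raise ValueError(f"region {gene}: start {start} >= end {end}")

    @property
    def chromosomes(self) -> frozenset[str]:
        return frozenset(normalize_chrom(c) for c, *_ in self.gene_regions)


@dataclass
class PhenotypeSubmission:
    """Per-patient trait probabilities from one submission.

    ``probs`` is patients x traits; NaN marks a missing (``*``) cell.
    """

    submission_id: str
    group_id: str
    probs: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.probs.to_numpy(dtype=float)
        known = vals[~np.isnan(vals)]
        if known.size and (known.min() < 0 or known.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a variant in VCF coordinates (1-based, chr-less chrom)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) is not a variant")
        bad = (set(self.ref) | set(self.alt)) - _VALID_BASES
        if bad:
            raise ValueError(f"invalid bases {sorted(bad)} in {self.ref}>{self.alt}")

    def token(self) -> str:
        return f"{self.chrom}-{self.pos}-{self.ref}-{self.alt}"


@dataclass
class VariantAnswerKey:
    """Laboratory ground truth: (patient, variant, class) entries."""

    entries: list[tuple[str, VariantKey, str]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, VariantKey]] = set()
        for pid, key, cls in self.entries:
            if cls not in VARIANT_CLASSES:
                raise ValueError(f"unknown variant class {cls!r}")
            ident = (pid, key)
            if ident in seen:
                raise ValueError(f"duplicate answer-key entry {pid} {key.token()}")
            seen.add(ident)

    def by_patient(self) -> dict[str, list[tuple[VariantKey, str]]]:
        out: dict[str, list[tuple[VariantKey, str]]] = {}
        for pid, key, cls in self.entries:
            out.setdefault(pid, []).append((key, cls))
        return out

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in VARIANT_CLASSES}
        for _, _, cls in self.entries:
            counts[cls] += 1
        return counts

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class VariantPredictionSet:
    """One submission's predicted (patient, variant) assignments.

    A patient may legitimately have zero predicted variants.
    """

    submission_id: str
    group_id: str
    entries: list[tuple[str, VariantKey]]
    scores: list[float | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scores and len(self.scores) != len(self.entries):
            raise ValueError("scores, when given, must parallel entries")


@dataclass(frozen=True)
class Violation:
    """A validation finding; violations are data, not exceptions."""

    kind: str
    message: str


# ---------------------------------------------------------------------------
# Variant token parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"^(?P<chrom>[^-:]+)[-:](?P<pos>\d+)[-:](?P<ref>[A-Za-z]+)[-:](?P<alt>[A-Za-z]+)$")


def parse_variant_token(token: str) -> VariantKey:
    """Parse ``chrom-pos-ref-alt`` (or ``:``-separated, ``chr``-prefixed)."""
    m = _TOKEN_RE.match(token.strip())
    if m is None:
        raise ValueError(f"malformed variant token {token!r}")
    try:
        return VariantKey(m["chrom"], int(m["pos"]), m["ref"], m["alt"])
    except ValueError as exc:
        raise ValueError(f"malformed variant token {token!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# Phenotype submissions
# ---------------------------------------------------------------------------


def _submission_ids_from_name(path: Path) -> tuple[str, str]:
    """Derive (submission_id, group_id) from a file name like sub_8.6_*.tsv."""
    m = re.search(r"(\d+)\.(\d+)", path.stem)
    if m:
        return f"{m.group(1)}.{m.group(2)}", m.group(1)
    return path.stem, path.stem


def read_phenotype_submission(
    path: str | Path,
    cohort: CohortDefinition,
    submission_id: str | None = None,
    group_id: str | None = None,
) -> PhenotypeSubmission:
    """Read a TSV phenotype submission, normalizing row order to the cohort.

    ``*`` cells become NaN (missing); numeric cells are validated to [0, 1].
    """
    path = Path(path)
    if submission_id is None or group_id is None:
        sid, gid = _submission_ids_from_name(path)
        submission_id = submission_id or sid
        group_id = group_id or gid
    raw = pd.read_csv(path, sep="\t", dtype=str)
    expected_cols = ["patient_id", *cohort.trait_names]
    if list(raw.columns) != expected_cols:
        raise ValueError(
            f"{path.name}: expected columns {expected_cols}, got {list(raw.columns)}"
        )
    if raw["patient_id"].duplicated().any():
        dup = raw.loc[raw["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValueError(f"{path.name}: duplicated patient {dup!r}")
    unknown = set(raw["patient_id"]) - set(cohort.patient_ids)
    if unknown:
        raise ValueError(f"{path.name}: unknown patient id {sorted(unknown)[0]!r}")
    missing = set(cohort.patient_ids) - set(raw["patient_id"])
    if missing:
        raise ValueError(f"{path.name}: patient {sorted(missing)[0]!r} absent")

    raw = raw.set_index("patient_id")
    probs = pd.DataFrame(index=list(cohort.patient_ids), columns=list(cohort.trait_names), dtype=float)
    for trait in cohort.trait_names:
        col = raw[trait]
        for pid, cell in col.items():
            cell = str(cell).strip()
            if cell == MISSING_MARKER:
                val = np.nan
            else:
                try:
                    val = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path.name}: patient {pid}, trait {trait}: unparseable value {cell!r}"
                    ) from None
                if not 0.0 <= val <= 1.0:
                    raise ValueError(
                        f"{path.name}: patient {pid}, trait {trait}: value {cell} outside [0, 1]"
                    )
            probs.at[pid, trait] = val
    return PhenotypeSubmission(submission_id, group_id, probs)


def write_phenotype_submission(sub: PhenotypeSubmission, path: str | Path) -> None:
    """Write the submission TSV; NaN cells are emitted as ``*``."""
    with open(path, "w") as fh:
        fh.write("patient_id\t" + "\t".join(sub.probs.columns) + "\n")
        for pid, row in sub.probs.iterrows():
            cells = [
                MISSING_MARKER if pd.isna(v) else f"{v:.6f}" for v in row.to_numpy()
            ]
            fh.write(str(pid) + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Variant predictions and answer keys
# ---------------------------------------------------------------------------


def read_variant_predictions(
    path: str | Path,
    submission_id: str | None = None,
    group_id: str | None = None,
) -> VariantPredictionSet:
    """Read ``patient_id<TAB>variant[<TAB>score]`` predictions (with header)."""
    path = Path(path)
    if submission_id is None or group_id is None:
        sid, gid = _submission_ids_from_name(path)
        submission_id = submission_id or sid
        group_id = group_id or gid
    entries: list[tuple[str, VariantKey]] = []
    scores: list[float | None] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("patient_id"):
            raise ValueError(f"{path.name}: missing header line")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path.name}:{lineno}: expected >= 2 columns")
            entries.append((parts[0], parse_variant_token(parts[1])))
            scores.append(float(parts[2]) if len(parts) > 2 and parts[2] != "" else None)
    if all(s is None for s in scores):
        scores = []
    return VariantPredictionSet(submission_id, group_id, entries, scores)


def write_variant_predictions(vp: VariantPredictionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("patient_id\tvariant\tscore\n")
        scores = vp.scores or [None] * len(vp.entries)
        for (pid, key), score in zip(vp.entries, scores):
            s = "" if score is None else f"{score:.6f}"
            fh.write(f"{pid}\t{key.token()}\t{s}\n")


def read_variant_answer_key(path: str | Path) -> VariantAnswerKey:
    """Read the classified answer key: ``patient_id<TAB>variant<TAB>class``."""
    path = Path(path)
    entries: list[tuple[str, VariantKey, str]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("patient_id"):
            raise ValueError(f"{path.name}: missing header line")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path.name}:{lineno}: expected 3 columns")
            entries.append((parts[0], parse_variant_token(parts[1]), parts[2]))
    return VariantAnswerKey(entries)


def write_variant_answer_key(key: VariantAnswerKey, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("patient_id\tvariant\tclass\n")
        for pid, vkey, cls in key.entries:
            fh.write(f"{pid}\t{vkey.token()}\t{cls}\n")


# ---------------------------------------------------------------------------
# Submission validation
# ---------------------------------------------------------------------------


def validate_submission(
    sub: PhenotypeSubmission | None,
    vp: VariantPredictionSet | None,
    cohort: CohortDefinition,
) -> list[Violation]:
    """Mirror of the challenge's distributed validation script.

    Returns an empty list iff both tables satisfy their invariants and every
    predicted variant lies on a chromosome covered by the panel.  Missing
    probability cells are legal input (imputation happens downstream).
    """
    violations: list[Violation] = []
    patients = set(cohort.patient_ids)
    if sub is not None:
        if set(sub.probs.index) != patients:
            extra = sorted(set(sub.probs.index) - patients)
            absent = sorted(patients - set(sub.probs.index))
            for pid in extra:
                violations.append(Violation("UNKNOWN_PATIENT", f"phenotype row for unknown patient {pid}"))
            for pid in absent:
                violations.append(Violation("MISSING_PATIENT", f"no phenotype row for patient {pid}"))
        if list(sub.probs.columns) != list(cohort.trait_names):
            violations.append(Violation("BAD_TRAITS", "trait columns differ from cohort order"))
        vals = sub.probs.to_numpy(dtype=float)
        known = vals[~np.isnan(vals)]
        if known.size and (known.min() < 0 or known.max() > 1):
            violations.append(Violation("VALUE_OUT_OF_RANGE", "probability outside [0, 1]"))
    if vp is not None:
        panel_chroms = cohort.chromosomes
        seen: set[tuple[str, VariantKey]] = set()
        for pid, key in vp.entries:
            if pid not in patients:
                violations.append(Violation("UNKNOWN_PATIENT", f"variant prediction for unknown patient {pid}"))
            if panel_chroms and key.chrom not in panel_chroms:
                violations.append(Violation("OFF_PANEL_CHROM", f"{key.token()} on chromosome outside the panel"))
            ident = (pid, key)
            if ident in seen:
                violations.append(Violation("DUPLICATE_ENTRY", f"duplicate prediction {pid} {key.token()}"))
            seen.add(ident)
    return violations


# ---------------------------------------------------------------------------
# Phenotype answer key (tri-state labels)
# ---------------------------------------------------------------------------

POSITIVE, NEGATIVE, UNKNOWN = 1, 0, -1
_LABEL_TO_TEXT = {POSITIVE: "1", NEGATIVE: "0", UNKNOWN: "?"}
_TEXT_TO_LABEL = {v: k for k, v in _LABEL_TO_TEXT.items()}


def read_phenotype_answer_key(path: str | Path, cohort: CohortDefinition) -> pd.DataFrame:
    """Read tri-state truth labels (``1``/``0``/``?``) into patients x traits."""
    raw = pd.read_csv(path, sep="\t", dtype=str).set_index("patient_id")
    labels = pd.DataFrame(UNKNOWN, index=list(cohort.patient_ids), columns=list(cohort.trait_names), dtype=np.int8)
    for trait in cohort.trait_names:
        for pid, cell in raw[trait].items():
            cell = str(cell).strip()
            if cell not in _TEXT_TO_LABEL:
                raise ValueError(f"patient {pid}, trait {trait}: bad label {cell!r}")
            labels.at[pid, trait] = _TEXT_TO_LABEL[cell]
    return labels


def write_phenotype_answer_key(labels: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("patient_id\t" + "\t".join(labels.columns) + "\n")
        for pid, row in labels.iterrows():
            fh.write(str(pid) + "\t" + "\t".join(_LABEL_TO_TEXT[int(v)] for v in row) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VcfEntry:
    """One (split) VCF record: identity plus the quality fields the challenge
    tells predictors to filter on.  Unknown fields are None."""

    key: VariantKey
    qual: float | None
    depth: int | None
    genotype_quality: int | None
    genotype: str


def read_vcf(path: str | Path) -> list[VcfEntry]:
    """Read a single-sample VCF 4.2; multi-allelic records are split per alt.

    A FORMAT field absent from a record is retained as None and logged once
    per file.
    """
    entries: list[VcfEntry] = []
    warned: set[str] = set()
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None:
                continue
            gt_str, dp, gq = ".", None, None
            if samples:
                sample = rec.samples[samples[0]]
                gt = sample.get("GT")
                if gt is None or all(a is None for a in gt):
                    gt_str = "."
                else:
                    sep = "|" if sample.phased else "/"
                    gt_str = sep.join("." if a is None else str(a) for a in gt)
                dp = sample.get("DP")
                gq = sample.get("GQ")
            for name, val in (("GT", gt_str if gt_str != "." else None), ("DP", dp), ("GQ", gq)):
                if val is None and name not in warned:
                    logger.warning("%s: FORMAT field %s missing in at least one record", path, name)
                    warned.add(name)
            for alt in rec.alts:
                entries.append(
                    VcfEntry(
                        key=VariantKey(rec.chrom, rec.pos, rec.ref, alt),
                        qual=rec.qual,
                        depth=int(dp) if dp is not None else None,
                        genotype_quality=int(gq) if gq is not None else None,
                        genotype=gt_str,
                    )
                )
    return entries


def write_vcf(
    entries: Iterable[VcfEntry],
    path: str | Path,
    sample_name: str = "SAMPLE",
    contigs: Sequence[str] | None = None,
) -> None:
    """Write a minimal single-sample VCF 4.2 (GT/DP/GQ FORMAT fields)."""
    entries = list(entries)
    if contigs is None:
        seen: dict[str, None] = {}
        for e in entries:
            seen.setdefault(e.key.chrom, None)
        contigs = list(seen)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_name}\n")
        for e in entries:
            qual = "." if e.qual is None else f"{e.qual:g}"
            dp = "." if e.depth is None else str(e.depth)
            gq = "." if e.genotype_quality is None else str(e.genotype_quality)
            fh.write(
                f"{e.key.chrom}\t{e.key.pos}\t.\t{e.key.ref}\t{e.key.alt}\t{qual}\t.\t.\tGT:DP:GQ\t{e.genotype}:{dp}:{gq}\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read a BED4+ file of captured regions (half-open, 0-based, verbatim)."""
    regions: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"line {lineno}: BED4 requires a gene symbol column")
            chrom, start, end, gene = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start >= end:
                raise ValueError(f"line {lineno}: start {start} >= end {end}")
            regions.append((normalize_chrom(chrom), start, end, gene))
    return regions


def write_bed(regions: Iterable[tuple[str, int, int, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, gene in regions:
            fh.write(f"{chrom}\t{start}\t{end}\t{gene}\n")


def read_config(path: str | Path) -> Mapping[str, object]:
    """Read a small key-value (YAML) config naming trait order / file paths."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    return data
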
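# Methods

## Setting and scope

`idbench` implements the assessor's side of a blind prediction challenge on a
targeted 74-gene NDD panel: 415 patients, seven phenotypic traits, and a
laboratory answer key of classified variants (DC = disease causing, LP =
likely pathogenic / putative, CF = contributing factor).  It scores two
tracks — per-trait probability submissions and per-patient variant lists —
and ranks submissions across traits.  It does not predict anything itself:
prediction methods, variant annotation (VEP/CADD-style tools) and wet-lab
re-evaluation are out of scope.

## Phenotype track

Each trait is treated as an independent binary problem over patients.  Truth
labels are tri-state: positive, negative, unknown.  For some traits the
laboratory recorded explicit negatives (hypotonia 254, ataxia 285 of 415);
elsewhere positives + negatives need not reach the cohort size, so unknowns
are a first-class label.  By default unknown-truth patients are excluded from
confusion counts and from bootstrap resampling; `unknown_as_negative=True`
reproduces the stricter reading that treats them as negatives.

**Imputation.**  A `*` cell means the predictor declined to answer; it is
kept at parse time (so the raw file stays auditable) and imputed as
probability 0 at assessment time.

**Binarization.**  The operating threshold maximizes MCC.  The prediction
rule is p ≥ t → positive.  Candidate thresholds are the midpoints between
consecutive distinct submitted probabilities plus one sentinel below the
minimum and one above the maximum — this candidate set provably contains a
global maximizer, and the search is exhaustively checkable.  Ties are broken
toward the smallest threshold, which favors sensitivity.  MCC is defined as 0
whenever a factor of its denominator vanishes (the standard convention,
preserving the [−1, 1] range); sensitivity, specificity and F1 are 0 when
their denominators vanish.  Accuracy and F1 are reported at the MCC-optimal
threshold and labelled as such.

**Curves.**  ROC AUC is the trapezoidal area under the full threshold-sweep
curve (equivalently the Mann–Whitney statistic with ties counted ½); PR AUC
uses the average-precision form (rectangular summation, no interpolation of
precision).  Both are delegated to scikit-learn; the test suite checks them
against independent pair-counting and hand-summation oracles.

**Bootstrap.**  1000 iterations by default.  Each iteration resamples the
known-label patients with replacement to the same size; a resample containing
a single truth class is discarded and redrawn (cap 100, then an error advises
`stratified=True`, which instead resamples each class to its own size).  The
bootstrap is seeded per (submission, trait) by hashing the ids into a
`SeedSequence` with the master seed, so adding a submission never perturbs
another's stream, and results are invariant to patient order given canonical
input ordering.

**Ranking.**  Per trait, the bootstrap-mean ROC AUCs of all submissions are
standardized to z-scores with the sample (n−1) SD; a numerically constant
column maps to z = 0.  Submissions are ranked by the unweighted mean z over
traits, ties broken by submission id; `auc_table(..., use="point")` feeds
point AUCs through the same machinery for callers that skip the bootstrap.

**Diagnosed-subset rerun.**  The diagnosed subset is the set of patients with
at least one answer-key variant of any class.  The rerun restricts both the
submissions and the truth matrix to that subset and repeats the entire
pipeline, re-optimizing thresholds; traits left with a single truth class are
dropped from the mean-z with a warning.

**Group consensus.**  For each truth-positive (patient, trait), the number of
groups predicting positive is counted, where a group predicts positive iff at
least one of its submissions does at its own MCC-optimal threshold (an
"all submissions" strict mode is available).  Truth-negative and unknown
patients are excluded, so each trait's histogram totals its positive count.

## Variant track

A predicted (patient, variant) pair is a true positive iff it identity-matches
an answer-key entry after normalization; predicted class labels are ignored.
True negatives are not evaluated — predictors only emit variants they believe
relevant.  Duplicate predictions of the same identity are deduplicated before
counting, so repetition cannot inflate either metric.  Scores:

* recall = n_correct / n_key, with n_key the full DC+LP+CF key (217 by
  default);
* "accuracy" = n_correct / n_predicted — precision under standard naming; the
  challenge's term is kept.  Zero denominators yield undefined, never 0.
* per-class coverage = 100 · correct-in-class / key-in-class;
* consensus histogram: per key variant, the number of groups (union of each
  group's submissions) whose matches contain it.

**Normalization.**  Without a reference, the common suffix then prefix are
trimmed, keeping at least one base per allele and advancing the position on
prefix trims; this is idempotent and suffices to match padded representations
of the same indel.  With a per-chromosome reference (FASTA), indels are also
left-aligned by the usual extend-left/trim loop before the final prefix trim.
Both modes are provided because whether the original assessment normalized
representations is not stated; trim-only is the default in tests since the
synthetic panel has no real reference sequence.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
exercised:

* **Truth marginals** are exact by construction: each trait column is a
  seeded shuffle assigning the configured positive count (defaults 352, 205,
  84, 45, 47, 71, 30 for ID, ASD, epilepsy, microcephaly, macrocephaly,
  hypotonia, ataxia), the configured known-negative count (hypotonia 254,
  ataxia 285; elsewhere the complement) and unknowns for the remainder.
  Joint structure across traits is product-of-marginals — only marginal
  prevalences are published.  (A reported ASD text count of 202 conflicts
  with the tabulated 205; the table value is used.)
* **Answer key**: 217 entries over exactly 217 diagnosed patients, chosen
  preferentially among trait-positive ones.  Class totals default to 60 DC
  (published directly), CF ≈ 103 (back-solved from the reported fractions of
  never/once-predicted contributing factors) and LP = 217 − 60 − 103 = 54;
  the 217 total is consistent with every published recall/count pair.  All
  three are overridable.  Variants are random SNVs (80%) or 1–3 bp indels
  planted inside panel regions, generated already in minimal representation.
* **Panel**: a toy 74-region BED (one 2 kb interval per gene, chromosomes
  1–22 and X, hg19-style chr-less names).  No real reference sequence is
  bundled or downloaded.
* **VCFs**: planted variants and Poisson(5)/patient benign background
  variants are emitted with QUAL ≥ 100, DP ≥ 50, GQ ≥ 90;
  Poisson(3)/patient decoys each fail at least one of the filter cuts
  QUAL < 20, DP < 10, GQ < 20.  The cut values are this package's
  conventions — the challenge names the fields but fixes no thresholds — and
  applying them removes exactly the decoys.
* **Phenotype submissions** follow a binormal model: positives draw a latent
  score ~ N(μ, 1), everyone else ~ N(0, 1), probability = logistic(score),
  so the expected ROC AUC is Φ(μ/√2); cells go missing independently at
  `miss_rate` (default 0.02 for the bundled submissions).  Default targets
  for the four generated submissions are AUC 0.55/0.65/0.75/0.85.
* **Variant submissions** include each key entry with probability
  `variant_sensitivity` (defaults 0.35/0.50/0.65/0.82 across the four
  submissions, the top one matching the best published recall regime) and add
  Poisson spurious calls per patient at non-key panel positions.

What passing on synthetic data does **not** show: the generator has no
linkage between genotype and phenotype columns, no allele frequencies,
inheritance or trio structure, no sequence context, and independent traits
(an optional comorbidity knob can correlate ID and ASD, off by default —
implemented as product-of-marginals unless enabled).  Conclusions about real
cohorts therefore rest on the scoring logic being correct, not on the
generator being realistic.

## Numerical choices and degenerate inputs

* Threshold search and all metrics are exact arithmetic on counts; no
  floating-point tolerance enters except the z-score constant-column guard
  (sample SD ≤ 1e−12 treated as constant).
* Single-class traits: threshold, ROC and bootstrap raise; the subset rerun
  converts this to a warning-and-drop.
* Probabilities exactly at a threshold count as positive (p ≥ t).
* Reported recall/accuracy round to 3 decimals, and coverage to 0.1%,
  matching the challenge's reporting precision; rounded values recover the
  integer counts (round(r · n_key) = n_correct).
* Problem sizes in the test and acceptance runs: the full 415-patient cohort
  everywhere; 1000 bootstrap iterations where the bootstrap is under test;
  the skill-recovery study uses point AUCs over 100 generator seeds, the
  package's documented point-AUC ranking path.

## Known limitations

* No DeLong or other analytic confidence intervals; uncertainty comes from
  the bootstrap only.
* No calibration analysis of submitted probabilities.
* VCF support is deliberately minimal: single-sample, GT/DP/GQ, split
  multi-allelics; no phasing semantics, symbolic alleles or BCF.
* The submission dialect (TSV layouts, `*` marker, token format) is this
  package's definition; the original challenge template is not published, so
  files from other tooling may need a thin conversion step.
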
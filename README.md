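# idbench

Assessment pipeline for blind-challenge scoring of phenotype and causal-variant
predictions from targeted gene-panel sequencing of pediatric neurodevelopmental
disorder (NDD) cohorts.

In this setting a clinical laboratory sequences a 74-gene panel in 415 patients,
labels each patient for seven phenotypic traits (intellectual disability, autism
spectrum disorder, epilepsy, microcephaly, macrocephaly, hypotonia, ataxia) and
classifies the variants it considers relevant into three classes — disease
causing (DC), likely pathogenic / putative (LP) and contributing factor (CF).
Prediction teams, given only the VCFs, submit (a) a probability per patient per
trait and (b) zero or more candidate variants per patient.  `idbench` is the
assessor's side of that exchange: it validates submissions, scores them against
the answer key, and ranks them — plus a synthetic cohort generator so the whole
pipeline is testable without access to any patient data.

## Methods in brief

**Phenotype track.**  Each trait is scored as an independent binary problem.
Missing cells (`*`) are imputed as probability 0.  Probabilities are binarized
at the threshold t* maximizing the Matthews correlation coefficient,

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

with candidates at midpoints between consecutive distinct probabilities (ties
broken toward the smaller threshold, rule p ≥ t → positive).  Sensitivity,
specificity, accuracy, F1 and MCC are reported at t*.  ROC and precision–recall
AUCs are computed over 1000 bootstrap resamples of the patients; patients with
unknown truth are excluded.  Submissions are compared by standardizing the
bootstrap-mean ROC AUC per trait to z-scores and ranking by the unweighted mean
z over traits.

**Variant track.**  A prediction is a true positive iff the (patient,
normalized variant) pair appears in the answer key; variant representations are
minimalized (suffix/prefix trimming, optional reference left-alignment) before
matching.  Reported scores are recall = correct/key-variants and "accuracy" =
correct/predicted (precision under standard naming; the challenge's term is
kept), per-class DC/LP/CF coverage, and a cross-group consensus histogram of
how many groups recovered each key variant.

**Synthetic cohorts.**  `generate_truth` reproduces the published per-trait
marginals exactly (352/205/84/45/47/71/30 positives out of 415; 254 known
hypotonia negatives, 285 ataxia negatives).  `generate_variant_key` plants a
217-entry key (60 DC + 54 LP + 103 CF) over 217 diagnosed patients inside the
panel regions.  Submissions of tunable skill follow a binormal model with
expected ROC AUC Φ(μ/√2), and per-patient VCFs carry the planted variants plus
benign background and low-quality decoy records.

## Worked example

```python
import idbench as ib

truth = ib.generate_truth(ib.CohortSpec(seed=0))
key = ib.generate_variant_key(ib.VariantKeySpec(seed=1), truth)

# a submission with expected ROC AUC 0.8 on every trait
profile = ib.SkillProfile(mu=ib.SkillProfile.mu_from_auc(0.80),
                          variant_sensitivity=0.82, variant_fp_per_patient=0.4)
sub = ib.simulate_phenotype_submission(truth, profile, seed=2)

res = ib.assess_submission(sub, truth, n_boot=1000, master_seed=17)
r = res["Hypotonia"]
print(f"threshold {r.threshold:.3f}  MCC {r.metrics.mcc:.3f}  "
      f"AUC {r.bootstrap.mean_roc_auc:.3f} ± {r.bootstrap.sd_roc_auc:.3f}")

vp = ib.simulate_variant_submission(key, profile, truth.index,
                                    ib.default_panel(), seed=3)
score = ib.cohort_score(ib.match_patient_variants(vp, key))
print(f"recall {score.recall:.3f}  accuracy {score.accuracy:.3f}")
```

prints

```
threshold 0.814  MCC 0.440  AUC 0.807 ± 0.030
recall 0.834  accuracy 0.514
```

The threshold is the probability cut maximizing MCC for hypotonia; the AUC is
the mean ± SD of the 1000 bootstrap ROC AUCs (close to the generative target
0.80); recall is the fraction of the 217 answer-key variants recovered and
accuracy the fraction of predicted variants that were correct.

The same stages are available from the shell:

```sh
idbench synth --out challenge --seed 42
idbench assess-phenotypes --submissions challenge/submissions \
        --answer-key challenge/phenotype_key.tsv --out results/pheno
idbench assess-variants --predictions challenge/submissions \
        --answer-key challenge/variant_key.tsv --out results/vars
idbench rank --auc-table results/pheno/auc_table.tsv --out results/rank.tsv
idbench consensus --binarized results/pheno/binarized \
        --answer-key challenge/phenotype_key.tsv --out results/consensus.tsv
```

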
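import numpy as np
import pandas as pd
import pytest

from idbench import (
    NEGATIVE,
    POSITIVE,
    TRAITS,
    UNKNOWN,
    CohortDefinition,
    PhenotypeSubmission,
)


@pytest.fixture
def small_cohort() -> CohortDefinition:
    return CohortDefinition(
        patient_ids=tuple(f"P{i:03d}" for i in range(1, 7)),
        gene_regions=(("1", 100, 2000, "GENEA"), ("X", 500, 3000, "GENEB")),
    )


@pytest.fixture
def small_submission(small_cohort) -> PhenotypeSubmission:
    rng = np.random.default_rng(0)
    probs = pd.DataFrame(
        rng.random((len(small_cohort.patient_ids), len(TRAITS))),
        index=list(small_cohort.patient_ids),
        columns=list(TRAITS),
    )
    return PhenotypeSubmission("1.1", "1", probs)


@pytest.fixture
def small_truth(small_cohort) -> pd.DataFrame:
    rng = np.random.default_rng(1)
    labels = rng.choice(
        [POSITIVE, NEGATIVE, UNKNOWN],
        size=(len(small_cohort.patient_ids), len(TRAITS)),
        p=[0.45, 0.45, 0.10],
    )
    # guarantee both classes per trait
    labels[0, :] = POSITIVE
    labels[1, :] = NEGATIVE
    return pd.DataFrame(
        labels.astype(np.int8),
        index=list(small_cohort.patient_ids),
        columns=list(TRAITS),
    )
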
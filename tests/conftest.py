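import pytest

from bioage import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-design cohort shared across tests (seed 0)."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def clinical_training(default_cohort):
    """Clinical biological samples and their chronological ages."""
    meta = default_cohort.metadata
    sub = meta[(meta["modality"] == "clinical") & (meta["replicate_id"] == 0)]
    x = default_cohort.features["clinical"].loc[sub["sample_id"]]
    ca = sub.set_index("sample_id").loc[x.index, "ca_years"]
    return x, ca
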
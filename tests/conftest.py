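import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "snpmeta",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("snpmeta")

from snpmeta import (  # noqa: E402
    GenotypeCountRecord,
    SimulationConfig,
    paper_like_fixture,
    simulate_studies,
)


def make_record(case=(50, 100, 50), ctrl=(60, 90, 50), **kwargs):
    """A valid record with overridable fields."""
    defaults = dict(
        study_id="s1", snp_id="rs0000001",
        effect_allele="A", ref_allele="G",
        ethnicity="Asian", disease="hypertension",
        control_source="population", gender="mixed",
        case_hom_ref=case[0], case_het=case[1], case_hom_alt=case[2],
        ctrl_hom_ref=ctrl[0], ctrl_het=ctrl[1], ctrl_hom_alt=ctrl[2],
    )
    defaults.update(kwargs)
    return GenotypeCountRecord(**defaults)


@pytest.fixture(scope="session")
def rs1558139_records():
    return paper_like_fixture("rs1558139")


@pytest.fixture(scope="session")
def rs2108622_records():
    return paper_like_fixture("rs2108622")


@pytest.fixture(scope="session")
def null_corpus():
    """10 studies, true allele OR = 1, no heterogeneity."""
    return simulate_studies(SimulationConfig(
        n_studies=10, n_case_range=(300, 800), n_ctrl_range=(300, 800),
        true_allele_or=1.0, tau=0.0, seed=7))
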
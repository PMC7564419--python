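import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_clinical_tsv(tmp_path):
    path = tmp_path / "clinical.tsv"
    path.write_text(
        "patient_id\tsurvival_years\tevent\tmetastasis_at_diagnosis\trace\n"
        "P1\t1.5\t1\t0\twhite\n"
        "P2\t3.0\t0\t1\tblack\n"
    )
    return path


@pytest.fixture
def expression_tsv(tmp_path):
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene\tS1\tS2\n"
        "TP53\t5.1\t4.9\n"
        "MYC\t7.2\t6.8\n"
        "RAD21\t6.0\t6.1\n"
    )
    return path
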
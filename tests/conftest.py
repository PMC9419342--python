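import pytest

from hfiprev import CohortCarrierCounts, load_builtin_panel
from hfiprev.synthetic_data import (
    paperlike_af_comparison_records,
    paperlike_config,
)

# Published screening-cohort counts used throughout: a pediatric cohort of
# 20,919 (61 carriers) and a parental cohort of 10,031 (27 carriers).
CHILD = CohortCarrierCounts(
    n_total=20_919, n_male=12_783, n_female=8_136,
    carriers_male=36, carriers_female=25,
)
PARENT = CohortCarrierCounts(
    n_total=10_031, n_male=5_006, n_female=5_024,
    carriers_male=11, carriers_female=16,
)


@pytest.fixture(scope="session")
def builtin_panel():
    return load_builtin_panel()


@pytest.fixture
def child_counts():
    return CHILD


@pytest.fixture
def parent_counts():
    return PARENT


@pytest.fixture(scope="session")
def comparison_records():
    return paperlike_af_comparison_records()


@pytest.fixture
def paperlike_cfg():
    return paperlike_config(seed=20_220_826)
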
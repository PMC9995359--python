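import pytest

from tcrclust.io import GermlineDB
from tcrclust.simulate import GERMLINE_SEQS, default_study_config, generate


@pytest.fixture(scope="session")
def germline():
    return GermlineDB(GERMLINE_SEQS)


@pytest.fixture(scope="session")
def small_cohort():
    """A 5,000-cell default-structure cohort shared across read-only tests."""
    config = default_study_config(cells_per_subject=1250)
    return generate(config, seed=7)
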
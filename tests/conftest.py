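import pytest

from ayr.cohort import Respondent
from ayr.synthetic import CohortConfig, generate


def make_respondent(**kwargs) -> Respondent:
    """A valid all-negative respondent with selected fields overridden."""
    base = dict(id="r0", age=30, family_history_known=True)
    base.update(kwargs)
    return Respondent(**base)


@pytest.fixture
def respondent_factory():
    return make_respondent


@pytest.fixture
def random_cohort():
    """A medium random cohort drawn from the default calibration."""
    return generate(CohortConfig(n=2000, seed=42))
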
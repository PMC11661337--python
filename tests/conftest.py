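import pytest

from nsdcog import (apply_norms, fit_all_norms, make_ppmi_like_cohort,
                    stage_cohort)


@pytest.fixture(scope="session")
def ppmi_cohort():
    return make_ppmi_like_cohort(1)


@pytest.fixture(scope="session")
def staged(ppmi_cohort):
    return stage_cohort(ppmi_cohort)


@pytest.fixture(scope="session")
def scored(staged):
    reference = staged[staged["cohort_role"] == "robust_hc"]
    return apply_norms(staged, fit_all_norms(reference))
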
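import pytest

import ifndiv as iv


@pytest.fixture(scope="session")
def default_cohort():
    """Default six-group cohort at the fixed fixture seed, with truth."""
    return iv.generate_cohort(iv.default_config(seed=0))


@pytest.fixture(scope="session")
def default_cohort_normalized(default_cohort):
    mat, truth = default_cohort
    return iv.normalize_to_hc_median(mat, mat.samples_in_group("HC")), truth


@pytest.fixture(scope="session")
def two_group():
    """SLE-like vs IFNbeta-MS-like cohort (plus HCs) at the fixture seed."""
    return iv.generate_cohort(iv.two_group_config(seed=0))
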
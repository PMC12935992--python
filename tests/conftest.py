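import warnings

import pytest

from mcpei.simulate import generate_cohort, get_preset

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_cohort():
    """Calibrated evaluation-scale cohort (n=600, fixed seed)."""
    return generate_cohort(get_preset("default_paper", seed=1000))


@pytest.fixture(scope="session")
def default_chain(default_cohort):
    """Full exposure -> DR -> IPTW chain on the default cohort."""
    from mcpei.sensitivity import primary_chain

    c = default_cohort
    return primary_chain(c.patients, c.infusion_days, c.outcomes, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(get_preset("default_paper", seed=7, n_patients=120))
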
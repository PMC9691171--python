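import matplotlib
import pytest

matplotlib.use("Agg")

from needsel.design import build_design, default_spec
from needsel.outcomes import derive_outcomes
from needsel.synthetic import AGE_CENTER, default_config, simulate_panel


@pytest.fixture(scope="session")
def small_panel():
    """Simulated panel, 300 individuals x 5 waves, generator defaults."""
    return simulate_panel(default_config(n_individuals=300, seed=42),
                          return_truth=True)


@pytest.fixture(scope="session")
def small_coded(small_panel):
    coded, _ = derive_outcomes(small_panel)
    return coded


@pytest.fixture(scope="session")
def small_design(small_coded):
    return build_design(small_coded, default_spec(age_center=AGE_CENTER))


@pytest.fixture(scope="session")
def small_fit(small_design):
    """One shared maximum-simulated-likelihood fit for downstream tests."""
    from needsel.model import fit_model

    return fit_model(small_design, n_draws=80, seed=7)
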
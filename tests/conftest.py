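import numpy as np
import pytest

import cetclock as cc


@pytest.fixture(scope="session")
def standard_run():
    """The standard recovery scenario: 6 species x 2 tissues x 40 samples,
    2,000 CpGs, 200 planted age CpGs, seed 42."""
    scenario = cc.standard_scenario()
    panel, betas, cpg_map, truth = cc.generate_panel(scenario)
    return scenario, panel, betas, cpg_map, truth


@pytest.fixture(scope="session")
def small_run():
    """A compact panel for fast clock and I/O tests."""
    scenario = cc.standard_scenario(
        n_species=3, samples_per_stratum=15, n_cpgs=300, n_age_cpgs=40,
        n_sex_cpgs=6, seed=7,
    )
    return (scenario, *cc.generate_panel(scenario))


@pytest.fixture
def tiny_panel():
    rng = np.random.default_rng(0)
    n = 12
    return cc.SamplePanel(
        sample_id=[f"s{i}" for i in range(n)],
        species=["killer whale"] * 6 + ["beluga"] * 6,
        tissue=["blood", "skin"] * 6,
        age_years=rng.uniform(0, 40, n),
        sex=["F", "M"] * 6,
        age_known=[True] * n,
    )
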
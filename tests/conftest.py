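import numpy as np
import pytest

import mixlr
from mixlr.epg_simulator import ContributionSpec, SimulatorParams, generate_protocol_dataset
from mixlr.panel_io import AnalysisConfig
from mixlr.popgen import sample_genotype_profile
from mixlr.variance_model import VarianceModel


@pytest.fixture(scope="session")
def panel8():
    return mixlr.mini_panel(8)


@pytest.fixture(scope="session")
def panel22():
    return mixlr.default_panel()


@pytest.fixture(scope="session")
def freqs8(panel8):
    return mixlr.synthetic_frequency_table(panel8, seed=1)


@pytest.fixture(scope="session")
def freqs22(panel22):
    return mixlr.synthetic_frequency_table(panel22, seed=1)


@pytest.fixture(scope="session")
def sim_params():
    return SimulatorParams()


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def vm_true(panel22):
    """The simulator's own dispersion and stutter, as a fitted model."""
    return VarianceModel(vf=40.0, stutter={l: 0.07 for l in panel22.locus_names})


@pytest.fixture(scope="session")
def protocol_data(sim_params, panel8, freqs8):
    """150 single-source calibration profiles (10 donors x 3 levels x 5)."""
    return generate_protocol_dataset(sim_params, panel8, freqs8, seed=2)


@pytest.fixture(scope="session")
def donors22(freqs22, panel22):
    rng = np.random.default_rng(5)
    return {
        name: sample_genotype_profile(freqs22, panel22.locus_names, "All", rng)
        for name in ("minor", "major", "third", "non1", "non2")
    }


@pytest.fixture(scope="session")
def mix_1_10(donors22, sim_params, panel22):
    """A clean undiluted 1:10 two-person mixture (50:500 pg)."""
    return mixlr.simulate_epg_profile(
        [
            ContributionSpec("minor", donors22["minor"], 50.0),
            ContributionSpec("major", donors22["major"], 500.0),
        ],
        sim_params, 30.0, 8, panel22,
    )


@pytest.fixture(scope="session")
def wg_1_10(mix_1_10, vm_true, config):
    """Shared deconvolution of the 1:10 mixture (8 chains x 2000)."""
    settings = mixlr.MCMCSettings(
        chains=8, iterations_per_chain=2000, preprocessing_steps=2000, seed=11
    )
    return mixlr.run_mcmc(mix_1_10, 2, [], vm_true, settings, config)
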
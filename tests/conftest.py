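import pytest

from silencescan.pipeline import run_pipeline
from silencescan.simulate import SAMPLES, SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: 150 genes, 3e5-read libraries, fewer background
    peaks. Statistical structure identical to the default conditions."""
    return SimulationConfig(
        n_genes=150,
        library_sizes={s: 300_000 for s in SAMPLES},
        n_background_peaks=40,
        intergenic_tail_bp=100_000,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config, seed=7)


@pytest.fixture(scope="session")
def small_result(small_study):
    return run_pipeline(small_study)
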
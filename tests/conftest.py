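import pytest

from domtransect.pipeline import PipelineConfig, run_pipeline
from domtransect.synthetic import TransectScenario, generate_transect_bundle


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic transect bundle (with noise)."""
    return generate_transect_bundle(TransectScenario(seed=1))


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Noise-free bundle for exact parameter-recovery checks."""
    return generate_transect_bundle(TransectScenario(seed=1, noise_sd=0.0))


@pytest.fixture(scope="session")
def fast_config():
    """Pipeline configuration trimmed for test runtime (no bin-size sweep,
    fewer envfit permutations); scientific defaults otherwise."""
    return PipelineConfig(run_sweep=False, n_permutations_envfit=999, seed=1)


@pytest.fixture(scope="session")
def report(bundle, fast_config):
    return run_pipeline(fast_config, bundle=bundle)
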
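import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def small_dataset():
    """20 barcodes, 4000 reads, one error per read on average."""
    from barcycle import SimulationConfig, generate_dataset, windows

    cfg = SimulationConfig(n_barcodes=20, n_reads=4000, error_lambda=1.0, seed=7)
    reads, truth = generate_dataset(cfg)
    return windows(reads, 12), truth


@pytest.fixture
def clean_dataset():
    """20 barcodes, 4000 error-free reads."""
    from barcycle import SimulationConfig, generate_dataset, windows

    cfg = SimulationConfig(n_barcodes=20, n_reads=4000, error_lambda=0.0, seed=11)
    reads, truth = generate_dataset(cfg)
    return windows(reads, 12), truth
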
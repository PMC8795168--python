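import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded 10-sample cohort shared by the integration-style tests."""
    from reanalyzer.synthdata import SimConfig, simulate
    return simulate(SimConfig(seed=11, n_samples=10, variants_per_sample=500))


@pytest.fixture(scope="session")
def toy_reference():
    from reanalyzer.variantcore import DictReference
    import numpy as np
    rng = np.random.default_rng(424242)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = lut[rng.integers(0, 4, size=20_000)].tobytes().decode()
    return DictReference({"1": seq, "13": seq[::-1]})
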
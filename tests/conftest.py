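import numpy as np
import pytest

from cregulon import RegulatoryNetwork, run_benchmark


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_network(rng):
    strength = rng.uniform(0, 1, size=(4, 6))
    return RegulatoryNetwork(
        cluster_id="c1",
        strength=strength,
        tf_ids=[f"TF{i + 1}" for i in range(4)],
        tg_ids=[f"TG{j + 1}" for j in range(6)],
    )


@pytest.fixture(scope="session")
def benchmark_reports():
    """Full-pipeline benchmark runs across ten seeds (shared by the
    module-recovery and association acceptance checks)."""
    return [run_benchmark(seed=seed) for seed in range(10)]
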
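import numpy as np
import pandas as pd
import pytest

from lamellakit import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_table():
    """Particle table with known depth/thickness columns for curation tests."""
    rng = np.random.default_rng(99)
    n = 300
    tomos = np.repeat([f"tomo_{i:03d}" for i in range(1, 7)], n // 6)
    return pd.DataFrame(
        {
            "tomogram_id": tomos,
            "x": rng.uniform(0, 1000, n),
            "y": rng.uniform(0, 1000, n),
            "z": rng.uniform(0, 500, n),
            "cc_score": rng.uniform(0.1, 1.0, n),
            "depth_nm": rng.uniform(-5, 100, n),
            "local_thickness_nm": np.repeat(
                [60.0, 110.0, 155.0, 175.0, 210.0, 250.0], n // 6
            ),
        }
    )


@pytest.fixture(scope="session")
def scenario():
    return synthetic.LamellaScenario(seed=42)


@pytest.fixture(scope="session")
def simulated(scenario):
    return synthetic.simulate_lamella_particles(scenario)
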
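import numpy as np
import pandas as pd
import pytest

from sting_sclc import ExpressionMatrix, NEReference, SimulationConfig, simulate_cohort


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, linear scale, hand-sized for boundary tests."""
    df = pd.DataFrame(
        {
            "s1": [0.0, 2.0, 5.0],
            "s2": [0.0, 0.0, 1.0],
            "s3": [0.0, 0.0, 3.0],
            "s4": [0.0, 4.0, 0.0],
        },
        index=["GA", "GB", "GC"],
    )
    return ExpressionMatrix(df, "linear")


@pytest.fixture
def toy_reference() -> NEReference:
    rng = np.random.default_rng(7)
    genes = [f"N{i:02d}" for i in range(12)]
    return NEReference(genes, rng.normal(5, 2, 12), rng.normal(5, 2, 12))


@pytest.fixture(scope="session")
def default_cohort():
    """The seeded default synthetic cohort (n=60, delta=2 SD), shared across tests."""
    cfg = SimulationConfig(seed=11)
    m, labels, gs, ref = simulate_cohort(cfg)
    return cfg, m, labels, gs, ref
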
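import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from paragi import (
    CountMatrix,
    LibraryAnnotation,
    ReferenceSets,
    SimConfig,
    simulate_screens,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """3 arrays x (T0 + one endpoint)."""
    df = pd.DataFrame(
        {"T0": [100, 200, 300], "D21": [50, 400, 300]},
        index=["arr1", "arr2", "arr3"],
    )
    return CountMatrix(counts=df, t0_sample="T0")


@pytest.fixture
def tiny_annotation() -> LibraryAnnotation:
    return LibraryAnnotation.from_records([
        ("arr1", "GENE1", None, "none"),
        ("arr2", "GENE2", None, "none"),
        ("arr3", "GENE1", "GENE2", "none"),
    ])


@pytest.fixture
def tiny_refs() -> ReferenceSets:
    return ReferenceSets(
        essential_genes=frozenset({"ESS1", "ESS2"}),
        nonessential_genes=frozenset({"NON1", "NON2"}),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A cheap simulated screen set for integration-style tests."""
    cfg = SimConfig(seed=11, n_genes=200, n_pairs=120, n_screens=2,
                    n_control_each=20, frac_essential_singles=0.2)
    return simulate_screens(cfg)
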
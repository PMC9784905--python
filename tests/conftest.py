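import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")

from translatome import (
    SampleSheet,
    CountMatrix,
    GeneLengthTable,
    compute_tpm,
    SimulationConfig,
    simulate_experiment,
)


@pytest.fixture
def small_sheet() -> SampleSheet:
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["S1", "S2"],
                "cell_type": ["B", "B"],
                "assay": ["ribo", "rna"],
                "replicate": [1, 1],
            }
        )
    )


@pytest.fixture
def small_counts(small_sheet) -> CountMatrix:
    frame = pd.DataFrame(
        {"S1": [10, 20, 30], "S2": [0, 5, 5]}, index=["g1", "g2", "g3"]
    )
    return CountMatrix(counts=frame, samples=small_sheet)


@pytest.fixture
def small_lengths() -> GeneLengthTable:
    return GeneLengthTable(pd.Series([1000, 500, 2000], index=["g1", "g2", "g3"]))


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulated experiment (seed 1), shared per session."""
    cfg = SimulationConfig(seed=1)
    return cfg, simulate_experiment(cfg)


@pytest.fixture(scope="session")
def default_tpm(default_sim):
    _, (counts, lengths, _, _) = default_sim
    return compute_tpm(counts, lengths)


def paired_sheet(n_replicates: int = 3, cells=("B", "T")) -> SampleSheet:
    rows = [
        {
            "sample_id": f"{c}_{a}_{r}",
            "cell_type": c,
            "assay": a,
            "replicate": r,
        }
        for c in cells
        for a in ("ribo", "rna")
        for r in range(1, n_replicates + 1)
    ]
    return SampleSheet(pd.DataFrame(rows))
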
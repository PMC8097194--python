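import numpy as np
import pytest

from spclone import (
    CellCycleModel,
    CloneDataset,
    CohortDesign,
    ParameterDistribution,
    SPParameters,
    TimeGrid,
    generate_cohort,
    large_sample_design,
)


@pytest.fixture(scope="session")
def benchmark_params() -> SPParameters:
    """The exponential-cycle benchmark parameter set (lambda=2.9/wk)."""
    return SPParameters(division_rate=2.9, symmetric_prob=0.06,
                        progenitor_fraction=0.5)


@pytest.fixture(scope="session")
def standard_grid() -> TimeGrid:
    return TimeGrid.standard()


@pytest.fixture(scope="session")
def large_cohort(benchmark_params):
    """Large-sample exponential cohort: ~1e5 simulated clones, known truth."""
    design = large_sample_design(benchmark_params, n_total_clones=100_000,
                                 rng_seed=20_250_901)
    return generate_cohort(design)


@pytest.fixture(scope="session")
def noisy_gamma_cohort():
    """Realistic cohort: Gamma(8) cell cycles + inter-mouse variation.

    Distribution means/sds follow the standard benchmark protocol for
    biological variation: lambda = 2.9 +/- 0.1, r = 0.09 +/- 0.01,
    rho = 0.7 +/- 0.05; 21 mice (3 per timepoint), 10^4 simulated clones
    per mouse, all survivors retained.
    """
    design = CohortDesign(
        mice_per_timepoint=3,
        clones_per_mouse=None,
        simulated_clones_per_mouse=10_000,
        parameters=ParameterDistribution(2.9, 0.1, 0.09, 0.01, 0.7, 0.05),
        cell_cycle=CellCycleModel(kind="gamma", gamma_shape=8.0),
        rng_seed=42,
    )
    return generate_cohort(design)


@pytest.fixture()
def toy_dataset() -> CloneDataset:
    return CloneDataset.from_records([
        ("m1", 3.0, 1), ("m1", 3.0, 2), ("m2", 10.0, 4),
    ])
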
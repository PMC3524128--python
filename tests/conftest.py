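import numpy as np
import pytest

from microcna.aberration_calling import call_aberrations
from microcna.segmentation import SegmentationParams, segment_cohort
from microcna.synthetic_cohort import (
    ArrayDesignParams,
    CohortSimParams,
    design_array,
    simulate_cohort,
)

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size synthetic cohort at study-like defaults (128 genes, 96 samples)."""
    windows, probes = design_array(seed=DEFAULT_SEED)
    return simulate_cohort(windows, probes, CohortSimParams(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def default_calls(default_cohort):
    """Segments and micro/macro calls for the full-size cohort (computed once)."""
    segments = segment_cohort(default_cohort.log_ratio_matrix, default_cohort.windows)
    micros, macros = call_aberrations(segments)
    return {"segments": segments, "micros": micros, "macros": macros}


@pytest.fixture(scope="session")
def small_design():
    params = ArrayDesignParams(n_genes=12, gene_length_range=(12_000, 40_000))
    return design_array(params, seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def small_cohort(small_design):
    windows, probes = small_design
    return simulate_cohort(
        windows, probes, CohortSimParams(n_samples=24, seed=DEFAULT_SEED)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(DEFAULT_SEED)
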
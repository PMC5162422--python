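import numpy as np
import pytest

from olivenmr import default_design, generate_cohort
from olivenmr.preprocessing import (
    build_bucket_table,
    normalize_total_sum,
    pareto_scale,
)


@pytest.fixture(scope="session")
def coarse_grid():
    """Coarser ppm grid for fast fixtures (still ~4x finer than a bucket)."""
    return np.linspace(10.2, 0.3, 4096)


@pytest.fixture(scope="session")
def small_cohort(coarse_grid):
    """Two-harvest cohort: 4 cultivars x 6 plants on the coarse grid."""
    design = default_design(plants_per_cultivar=6, seed=11, ppm_grid=coarse_grid)
    return generate_cohort(design)


@pytest.fixture(scope="session")
def small_scaled_table(small_cohort):
    table = build_bucket_table(small_cohort.spectra, small_cohort.metadata)
    return pareto_scale(normalize_total_sum(table))
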
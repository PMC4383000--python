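import numpy as np
import pandas as pd
import pytest

from tetrakit import (
    GenomeSpec,
    Chromosome,
    GenotypeMatrix,
    MarkerMap,
    MeiosisParams,
    ObservationParams,
    build_marker_map,
    default_genome,
    observe_tetrads,
    simulate_tetrads,
)
from tetrakit.sim_meiosis import MISSING, SK, ZH


@pytest.fixture(scope="session")
def small_genome() -> GenomeSpec:
    return default_genome(n_chromosomes=2, chrom_length=3_000_000)


@pytest.fixture(scope="session")
def marker_map(small_genome) -> MarkerMap:
    return build_marker_map(small_genome, median_spacing=235, seed=11)


@pytest.fixture(scope="session")
def sim_truth(small_genome, marker_map):
    params = MeiosisParams(co_mean_per_tetrad=8.0)
    return simulate_tetrads(small_genome, marker_map, params, n_tetrads=8, seed=21)


@pytest.fixture(scope="session")
def perfect_matrix(sim_truth, marker_map) -> GenotypeMatrix:
    obs = ObservationParams(coverage=1.0, error_rate=0.0, seed=31)
    return observe_tetrads(sim_truth, marker_map, obs)


def make_matrix(calls_by_cell, positions=None, chrom="chr1", tetrad=1):
    """Build a one-tetrad GenotypeMatrix from four per-cell call lists.

    Call lists use codes SK/ZH/MISSING; all four must have equal length.
    """
    calls = np.array(calls_by_cell, dtype=np.int8).T  # markers x cells
    n = calls.shape[0]
    if positions is None:
        positions = np.arange(1, n + 1) * 100
    markers = pd.DataFrame({"chrom": chrom, "pos": np.asarray(positions)})
    cells = pd.DataFrame({"tetrad": tetrad, "cell": [1, 2, 3, 4]})
    return GenotypeMatrix(markers, cells, calls)


@pytest.fixture
def toy_matrix_builder():
    return make_matrix
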
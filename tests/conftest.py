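"""Shared fixtures: small simulated datasets with known truth."""

import numpy as np
import pandas as pd
import pytest

from doqc.genotype_io import GenotypeMatrix, GeneticMap, FounderGenotypes
from doqc.simulate_do import SimConfig, make_dataset


@pytest.fixture(scope="session")
def default_sim():
    """The standard desk-scale cohort: 60 samples, 10 x 200 markers at 1 cM,
    with engineered bad samples, a duplicate pair, a sex mislabel, XO, XXY."""
    return make_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_sim():
    """A quick cohort for pipeline-level tests."""
    config = SimConfig(
        n_chromosomes=3,
        n_markers_per_chromosome=120,
        n_samples_by_generation=((8, 8), (11, 12)),
        n_x_markers=60,
        seed=5,
    )
    return make_dataset(config)


@pytest.fixture(scope="session")
def clean_sim():
    """Clean cohort: no injected errors, missingness, or problem samples."""
    config = SimConfig(
        bad_samples=(),
        duplicate_pairs=(),
        n_xo_females=0,
        n_xxy_males=0,
        n_sex_mislabels=0,
        epsilon_sim=0.0,
        missing_rate=0.0,
        seed=11,
    )
    return make_dataset(config)


@pytest.fixture(scope="session")
def dense_clean_sim():
    """Dense error-free cohort: high per-segment marker information."""
    config = SimConfig(
        n_chromosomes=2,
        n_markers_per_chromosome=250,
        marker_spacing_cM=0.2,
        n_samples_by_generation=((11, 12),),
        bad_samples=(),
        duplicate_pairs=(),
        n_xo_females=0,
        n_xxy_males=0,
        n_sex_mislabels=0,
        epsilon_sim=0.0,
        missing_rate=0.0,
        seed=7,
    )
    return make_dataset(config)


@pytest.fixture
def tiny_map():
    table = pd.DataFrame(
        {
            "chromosome": ["1", "1", "1", "2", "2"],
            "position_cM": [0.0, 1.0, 2.5, 0.0, 3.0],
        },
        index=pd.Index(["m1", "m2", "m3", "m4", "m5"], name="marker"),
    )
    return GeneticMap(table)


@pytest.fixture
def tiny_genotypes(tiny_map):
    calls = pd.DataFrame(
        [[0, 1], [1, 2], [2, -1], [0, 0], [-1, 1]],
        index=tiny_map.marker_ids,
        columns=["s1", "s2"],
        dtype=np.int8,
    )
    return GenotypeMatrix(calls)


@pytest.fixture
def tiny_founders(tiny_map):
    calls = pd.DataFrame(
        [
            [0, 0, 0, 0, 0, 0, 0, 1],
            [0, 0, 0, 0, 0, 0, 1, 1],
            [0, 1, 0, 1, 0, 1, 0, 1],
            [0, 0, 0, 0, 1, 1, 1, 1],
            [0, 0, 1, 1, 1, -1, 0, 0],
        ],
        index=tiny_map.marker_ids,
        columns=list("ABCDEFGH"),
        dtype=np.int8,
    )
    return FounderGenotypes(calls)
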
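import numpy as np
import pandas as pd
import pytest

from agemark.simdata import SimConfig, simulate_experiment
from agemark.tracks import CoverageTrack


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A fast, fully featured configuration (80 genes on a 1-Mb chromosome)."""
    return SimConfig(
        n_genes=80,
        chrom_length=1_000_000,
        chip_depth=400_000,
        rna_depth=200_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_track(values, bin_size=25, chrom="chr1") -> CoverageTrack:
    return CoverageTrack(bin_size, {chrom: np.asarray(values, dtype=np.int64)})


@pytest.fixture()
def tiny_track():
    return make_track([3, 0, 2, 5, 1, 0, 0, 4])
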
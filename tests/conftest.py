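import numpy as np
import pandas as pd
import pytest

from placloop import SimulationConfig, normalize_bin_pairs, simulate_study
from placloop.grid import BinGrid


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """Desk-scale study small enough for per-test reuse."""
    return SimulationConfig(
        seed=11,
        chrom_length_bp=3_000_000,
        n_peaks=90,
        n_planted_loops=8,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return simulate_study(small_cfg)


@pytest.fixture(scope="session")
def small_normalized(small_study):
    return normalize_bin_pairs(small_study.bin_pairs, small_study.features)


@pytest.fixture()
def tiny_grid() -> BinGrid:
    return BinGrid({"chr1": 100_000, "chr2": 50_000}, resolution=5_000)


@pytest.fixture()
def unit_features() -> pd.DataFrame:
    """A feature table with every covariate equal to 1 (200 bins of 1 kb)."""
    starts = np.arange(200) * 1_000
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "end": starts + 1_000,
            "f": 1.0,
            "gc": 1.0,
            "m": 1.0,
            "IP": 1,
        }
    )
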
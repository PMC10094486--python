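import numpy as np
import pandas as pd
import pytest

from polyhex.simulate import SimConfig, build_parent_panel


@pytest.fixture(scope="session")
def small_cfg():
    """A 3 x 8 Mb genome small enough for fast unit tests."""
    return SimConfig(
        n_chromosomes=3,
        chrom_length_bp=8_000_000,
        snp_density=1.0,
        per_site_depth=20.0,
        n_individuals=3,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return build_parent_panel(small_cfg, np.random.default_rng(small_cfg.seed))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_counts(chrom, positions, a, b, individual="ind1"):
    """Hand-built single-individual count table."""
    return pd.DataFrame(
        {
            "individual": individual,
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=np.int64),
            "count_9311": np.asarray(a, dtype=np.int64),
            "count_nip": np.asarray(b, dtype=np.int64),
        }
    )
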
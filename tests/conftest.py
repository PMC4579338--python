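import numpy as np
import pytest

from mosaicna import NoiseModel, simulate_sample, small_genome
from mosaicna.synthetic_cohort import child_rng, simulate_genotypes


@pytest.fixture(scope="session")
def genome_1chr():
    """One 120-Mb chromosome at the default 4-kb probe spacing."""
    return small_genome(n_chroms=1, chrom_mb=120.0)


@pytest.fixture(scope="session")
def genome_2chr():
    """Two 180-Mb chromosomes at the default 4-kb probe spacing."""
    return small_genome(n_chroms=2, chrom_mb=180.0)


@pytest.fixture(scope="session")
def grid_1chr(genome_1chr):
    return genome_1chr.probe_grid()


@pytest.fixture(scope="session")
def grid_2chr(genome_2chr):
    return genome_2chr.probe_grid()


@pytest.fixture
def paired_factory():
    """Simulate a (control, test) pair sharing germline genotypes.

    Returns a function (genome, grid, specs, seed, noise=default,
    control_specs=[]) -> (control, test).
    """

    def make(genome, grid, specs, seed, noise=None, control_specs=()):
        noise = noise if noise is not None else NoiseModel()
        rg = child_rng(seed, "genotypes")
        freqs = rg.uniform(0.05, 0.95, len(grid))
        genotypes = simulate_genotypes(freqs, rg)
        control = simulate_sample(
            genome, genotypes, list(control_specs), noise,
            child_rng(seed, "control"), "ctrl", grid=grid,
        )
        test = simulate_sample(
            genome, genotypes, list(specs), noise,
            child_rng(seed, "test"), "test", grid=grid,
        )
        return control, test

    return make


def probe_frame(chrom, positions, lrr, baf, gtype):
    """Hand-build a probe table DataFrame for small unit tests."""
    import pandas as pd

    n = len(positions)
    return pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n)],
            "chrom": [chrom] * n if isinstance(chrom, str) else chrom,
            "pos": positions,
            "lrr": np.broadcast_to(np.asarray(lrr, float), (n,)).copy(),
            "baf": np.broadcast_to(np.asarray(baf, float), (n,)).copy(),
            "gtype": [gtype] * n if isinstance(gtype, str) else list(gtype),
        }
    )
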
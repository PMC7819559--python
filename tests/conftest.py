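"""Shared fixtures: one simulated dataset reused across the suite."""

import numpy as np
import pandas as pd
import pytest

from urbmeth.config import SimulationConfig
from urbmeth.coverage import merge_strands, relaxed_background, unite
from urbmeth.annotation import build_catalog
from urbmeth.diffmeth import DifferentialMethylation
from urbmeth.simulate import simulate_dataset


@pytest.fixture(scope="session")
def dataset():
    return simulate_dataset(SimulationConfig(rng_seed=11))


@pytest.fixture(scope="session")
def merged_counts(dataset):
    return {sid: merge_strands(df, dataset.genome)
            for sid, df in dataset.strand_counts.items()}


@pytest.fixture(scope="session")
def matrix(dataset, merged_counts):
    return unite(merged_counts, dataset.samples)


@pytest.fixture(scope="session")
def background_sites(merged_counts):
    return relaxed_background(merged_counts)


@pytest.fixture(scope="session")
def catalog(dataset):
    return build_catalog(dataset.genome, dataset.genes)


@pytest.fixture(scope="session")
def dms_results(matrix):
    return DifferentialMethylation(matrix).fit()


@pytest.fixture()
def toy_genome():
    """20 kb AT-rich chromosome with a known CpG at 1000 and one at 1500."""
    rng = np.random.default_rng(0)
    seq = list(rng.choice(list("AT"), size=20_000))
    seq[1000:1002] = ["C", "G"]
    seq[1500:1502] = ["C", "G"]
    return {"chr1": "".join(seq)}


def make_matrix(meth, total, n_urban=6, n_forest=6, positions=None):
    """Small MethylationMatrix from explicit (n_sites, n_samples) arrays."""
    from urbmeth.coverage import MethylationMatrix
    meth = np.atleast_2d(np.asarray(meth))
    total = np.atleast_2d(np.asarray(total))
    n_sites = meth.shape[0]
    if positions is None:
        positions = np.arange(n_sites) * 100 + 100
    sites = pd.DataFrame({"chrom": "chr1", "pos": positions})
    samples = pd.DataFrame({
        "sample_id": [f"u{i}" for i in range(n_urban)] + [f"f{i}" for i in range(n_forest)],
        "habitat": ["urban"] * n_urban + ["forest"] * n_forest,
        "tissue": "liver",
    })
    return MethylationMatrix(sites=sites, meth=meth, total=total, samples=samples)
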
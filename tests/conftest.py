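import numpy as np
import pytest

from causalscca import (HyperParams, LDBlockPartition, PenaltyWeights,
                        make_dataset, make_truth, partition_ld_blocks,
                        pairwise_corr, preset)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """A desk-size simulated regime shared by solver-level tests."""
    return preset("data1", seed=7, n=60, p=20, q=(12, 10, 8), block_size=5)


@pytest.fixture(scope="session")
def tiny_data(tiny_config):
    truth = make_truth(tiny_config)
    geno, pheno, labels = make_dataset(truth, tiny_config)
    part = partition_ld_blocks(pairwise_corr(geno))
    return {"truth": truth, "geno": geno, "pheno": pheno, "labels": labels,
            "partition": part}


@pytest.fixture
def default_hp():
    return HyperParams(eta=0.1, penalty=PenaltyWeights())


def random_partition(rng, p, max_block=4):
    """Random disjoint interval partition of 0..p-1 for property tests."""
    blocks, start = [], 0
    while start < p:
        size = int(rng.integers(1, max_block + 1))
        blocks.append(np.arange(start, min(start + size, p)))
        start += size
    return LDBlockPartition(blocks=blocks, threshold=0.2)
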
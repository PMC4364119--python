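import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ssrpipe import GenotypeDataset, IslandModelSpec, generate_genotypes


@pytest.fixture
def tiny_dataset() -> GenotypeDataset:
    """Two populations, two loci, four individuals each, no missing data."""
    return GenotypeDataset(
        locus_names=["L1", "L2"],
        pop_names=["A", "B"],
        individual_names=[[f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)]],
        genotypes=[
            [
                [(100, 102), (200, 200)],
                [(100, 100), (200, 202)],
                [(102, 102), (202, 202)],
                [(100, 102), (200, 202)],
            ],
            [
                [(102, 104), (202, 202)],
                [(104, 104), (202, 204)],
                [(102, 104), (204, 204)],
                [(104, 104), (202, 204)],
            ],
        ],
        group_ids=["g1", "g2"],
    )


@pytest.fixture(scope="session")
def island_dataset():
    """A moderately differentiated 6-pop island-model dataset (seeded)."""
    spec = IslandModelSpec(
        n_pops=6, n_per_pop=8, n_loci=14, n_alleles=5, fst=0.05,
        seed=42, n_groups=2,
    )
    dataset, truth = generate_genotypes(spec)
    return dataset, truth


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
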
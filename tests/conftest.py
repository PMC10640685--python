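import random

import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

from kmersnp.genome_io import GenomeRecord


def random_genome(rng: random.Random, length: int, genome_id: str = "g1"):
    seq = "".join(rng.choice("ACGT") for _ in range(length))
    return GenomeRecord(genome_id=genome_id, sequences=[(genome_id, seq)])


def mutated_family(rng: random.Random, n_genomes: int, length: int, n_muts: int):
    """Ancestor plus genomes with random (possibly clashing) substitutions."""
    ancestor = "".join(rng.choice("ACGT") for _ in range(length))
    genomes = []
    for i in range(n_genomes):
        seq = list(ancestor)
        for _ in range(n_muts):
            pos = rng.randrange(length)
            seq[pos] = rng.choice("ACGT")
        gid = f"g{i + 1:02d}"
        genomes.append(GenomeRecord(genome_id=gid, sequences=[(gid, "".join(seq))]))
    return genomes


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture
def planted_fixture():
    """Five genomes, 30 substitutions planted in k-unique contexts, k=13."""
    from kmersnp.synthetic_data import plant_mutations

    records, truth = plant_mutations(
        n_genomes=5, n_snps=30, genome_length=2500, k=13, seed=11
    )
    return records, truth, 13
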
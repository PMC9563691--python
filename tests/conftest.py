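import pytest

from phylokmer import (
    IndexConfig,
    SimulationConfig,
    build_index,
    evolve_genomes,
    generate_tree,
    parse_newick,
)


@pytest.fixture
def toy_tree():
    """((A,B)AB,C)root — the smallest tree with a non-trivial internal node."""
    return parse_newick("((A,B)AB,C)root;")


@pytest.fixture
def random_community():
    """Factory for (tree, genomes) fixtures with substitution-divergent genomes."""

    def make(seed: int, n_leaves: int = 8, genome_length: int = 1500, sub: float = 0.05):
        config = SimulationConfig(
            n_leaves=n_leaves,
            root_genome_length=genome_length,
            branch_substitution_prob=sub,
            seed=seed,
        )
        tree, _ = generate_tree(config)
        genomes = evolve_genomes(tree, config)
        return tree, genomes

    return make


@pytest.fixture
def toy_index(toy_tree):
    """Index over three handcrafted 60 bp genomes sharing staged regions.

    Genome layout (k=7): a region unique to A, a region shared by A and
    B only, and a region common to all three — so the index contains
    values at a leaf, an internal node and the root.
    """
    shared_ab = "ACGTTGCAACGGTTAACCGGATAT"
    common = "TTGACCTGAGGCTATATCCGGCAA"
    unique_a = "CCCGATCGTAGCTAGGCTAACGTA"
    unique_b = "GGGTACCATGGATCCAAGCTTGCA"
    unique_c = "AAATCGATGCATGCTAGCTAGGAA"
    genomes = {
        "A": [unique_a + shared_ab + common],
        "B": [unique_b + shared_ab + common],
        "C": [unique_c + common],
    }
    index = build_index(genomes, toy_tree, IndexConfig(k=7))
    return index, genomes
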
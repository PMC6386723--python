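import numpy as np
import pandas as pd
import pytest

from margifuse import simulate as sim


@pytest.fixture(scope="session")
def small_config():
    return sim.SimConfig(
        n_chromosomes=3,
        chrom_length=10_000_000,
        n_genes=60,
        n_read_pairs=20_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return sim.make_genome(small_config)


@pytest.fixture(scope="session")
def small_susceptible(small_genome, small_config):
    annotation, _ = small_genome
    return sim.choose_susceptible_pairs(annotation, small_config)


@pytest.fixture(scope="session")
def small_pairs(small_genome, small_susceptible, small_config):
    annotation, chrom_sizes = small_genome
    return sim.simulate_imargi(annotation, chrom_sizes, small_config, small_susceptible)


@pytest.fixture()
def toy_annotation():
    """Four genes on two chromosomes with hand-checkable coordinates."""
    return pd.DataFrame(
        {
            "gene_id": ["geneW", "geneX", "geneY", "geneZ"],
            "chrom": ["chr1", "chr1", "chr2", "chr1"],
            "start": [100_000, 500_000, 500_000, 2_000_000],
            "end": [110_000, 520_000, 520_000, 2_050_000],
            "strand": ["+", "-", "+", "+"],
        }
    )


def make_pair(rna_chrom, rna_pos, dna_chrom, dna_pos, rna_strand="+", dna_strand="+",
              read_id="r"):
    return pd.DataFrame(
        [[read_id, rna_chrom, rna_pos, rna_strand, dna_chrom, dna_pos, dna_strand]],
        columns=["read_id", "rna_chrom", "rna_pos", "rna_strand",
                 "dna_chrom", "dna_pos", "dna_strand"],
    )


@pytest.fixture()
def make_pair_row():
    return make_pair
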
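import numpy as np
import pytest

from circpipe.core_io import Genome, Transcript
from circpipe.simulate import SimConfig, make_genome_and_genes, plant_circles


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated world shared by read-level tests."""
    config = SimConfig(seed=11, n_genes=6, depth=300)
    genome, transcripts = make_genome_and_genes(config)
    truths = plant_circles(genome, transcripts, 4, 0.5, seed=11,
                           min_ring_length=config.read_length)
    return config, genome, transcripts, truths


def make_plus_gene(seed: int = 0, exon_lens=(150, 160, 170), intron_lens=(90, 110),
                   offset: int = 200, chrom: str = "c1", coding: bool = True):
    """Handcrafted single + strand gene with GT/AG boundaries at every exon edge."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    total = offset + sum(exon_lens) + sum(intron_lens) + 200
    seq = list("".join(bases[rng.integers(0, 4, size=total)]))
    exons = []
    pos = offset
    for i, el in enumerate(exon_lens):
        if i > 0:
            pos += intron_lens[i - 1]
        exons.append((pos, pos + el))
        pos += el
    for a, b in exons:
        seq[a - 2:a] = "AG"
        seq[b:b + 2] = "GT"
    genome = Genome({chrom: "".join(seq)})
    tx = Transcript("txP", "geneP", chrom, "+", tuple(exons), coding=coding,
                    cds=exons[0] if coding else None)
    return genome, tx
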
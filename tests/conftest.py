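import numpy as np
import pytest

from insulmine.annotation_io import GeneModel, GenomeIndex


def make_index(genes, genome_id="test"):
    """Build a GenomeIndex from (gene_id, seqid, start, end, strand, fpkm) tuples."""
    return GenomeIndex.build(
        genome_id,
        [GeneModel(seqid=s, start=a, end=b, gene_id=g, strand=st, fpkm=f)
         for (g, s, a, b, st, f) in genes],
    )


def random_gene_tuples(rng: np.random.Generator, n_genes: int, n_seqids: int = 2):
    """Random non-degenerate gene layouts, including occasional overlaps."""
    genes = []
    for i in range(n_genes):
        seqid = f"c{rng.integers(1, n_seqids + 1)}"
        start = int(rng.integers(0, 50_000))
        length = int(rng.integers(100, 3_000))
        strand = "+" if rng.integers(2) else "-"
        fpkm = float(rng.choice([0.0, 0.5, 1.0, 3.0, 10.0, 50.0, 200.0]))
        genes.append((f"g{i:03d}", seqid, start, start + length, strand, fpkm))
    return genes


@pytest.fixture
def two_gene_index():
    return make_index(
        [("gL", "chr1", 0, 100, "+", 10.0), ("gR", "chr1", 150, 300, "+", 20.0)]
    )
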
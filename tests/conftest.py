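import numpy as np
import pytest

from regulonscan import (BindingSiteSet, GeneFeature, GenomeRecord, UpstreamRegion,
                         build_pfm)


@pytest.fixture
def toy_sites() -> BindingSiteSet:
    """The worked-example site collection {ACGT, ACGA, ACTT, GCGT}."""
    return BindingSiteSet(sites=["ACGT", "ACGA", "ACTT", "GCGT"])


@pytest.fixture
def toy_pfm(toy_sites):
    return build_pfm(toy_sites)


@pytest.fixture
def uniform_pfm():
    from regulonscan.motif_builder import FrequencyMatrix
    return FrequencyMatrix(freqs=np.full((4, 4), 0.25), n_sites=0)


def make_region(sequence: str, gene_id: str = "gene", genome_id: str = "syn",
                strand: str = "+") -> UpstreamRegion:
    """Bare upstream region for scanner/motif tests."""
    return UpstreamRegion(gene_id=gene_id, genome_id=genome_id,
                          sequence=sequence.upper(), span=(0, len(sequence)),
                          contig_id="chr", strand=strand)


def make_genome(contig: str, features: list[tuple], genome_id: str = "g") -> GenomeRecord:
    """features: (gene_id, start, end, strand) tuples on contig 'chr'."""
    feats = [GeneFeature(gene_id=g, contig_id="chr", start=s, end=e, strand=st)
             for g, s, e, st in features]
    return GenomeRecord(genome_id=genome_id, contigs={"chr": contig}, features=feats)


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
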
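import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ecrscan.core import Annotation, Gene, GenomicInterval, PipelineParams, Transcript
from ecrscan.simulate import SimSpec, generate_annotation

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return PipelineParams()


@pytest.fixture(scope="session")
def sim_spec():
    return SimSpec(seed=7)


@pytest.fixture(scope="session")
def sim_annotation(sim_spec):
    return generate_annotation(sim_spec)


def make_gene(
    gene_id: str,
    chrom: str,
    strand: str,
    span: tuple[int, int],
    exons: list[tuple[int, int]],
    principal: bool = True,
) -> Gene:
    """Small helper to build a single-transcript gene."""
    tx = Transcript(
        transcript_id=f"{gene_id}.T1",
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        start=span[0],
        end=span[1],
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
        principal=principal,
    )
    return Gene(gene_id, chrom, strand, [tx])


def random_annotation(rng: np.random.Generator, n_genes: int = 8) -> Annotation:
    """Randomized single-transcript annotation for conservation properties."""
    genes = {}
    cursor = 0
    for i in range(n_genes):
        cursor += int(rng.integers(100, 1000))
        n_exons = int(rng.integers(1, 6))
        exons = []
        pos = cursor
        for _ in range(n_exons):
            length = int(rng.integers(50, 300))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(0, 400))  # gap 0 => abutting exons
        gid = f"R{i:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        genes[gid] = make_gene(gid, "chr1", strand, (exons[0][0], exons[-1][1]), exons)
        cursor = exons[-1][1]
    return Annotation(genes=genes)
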
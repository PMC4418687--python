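from __future__ import annotations

import re

import numpy as np
import pytest

from tnscan.formats_io import GeneAnnotation, GenomeRef
from tnscan.synthetic_data import SimParams, simulate_genome, simulate_library


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def gene_plus() -> GeneAnnotation:
    return GeneAnnotation("c1", "G1", "thrA", "threonine synthase", 1, 100, "+")


@pytest.fixture
def gene_minus() -> GeneAnnotation:
    return GeneAnnotation("c1", "G2", "", "", 1, 100, "-")


@pytest.fixture
def bare_genome() -> GenomeRef:
    return GenomeRef("c1", 10_000)


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated dataset shared by integration-style tests."""
    params = SimParams(
        genome_length=200_000,
        n_genes=180,
        essential_fraction=0.10,
        n_unique_insertions=3_000,
        essential_leak=0.02,
        seed=11,
    )
    genome, genes, truth = simulate_genome(params)
    library = simulate_library(genome, genes, truth, params)
    return params, genome, genes, truth, library


def write_sam(path, records, contigs=(("c1", 10_000),), header=True):
    """Write a SAM file from (qname, flag, rname, pos, mapq, cigar) tuples."""
    with open(path, "w") as fh:
        if header:
            fh.write("@HD\tVN:1.6\n")
            for name, length in contigs:
                fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for qname, flag, rname, pos, mapq, cigar in records:
            n = sum(int(x) for x in re.findall(r"(\d+)[MIS=X]", cigar))
            fh.write(
                f"{qname}\t{flag}\t{rname}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t"
                f"{'A' * n}\t{'I' * n}\n"
            )
    return path
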
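from __future__ import annotations

import numpy as np
import pytest

from edbsa import simcross as sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_maps():
    """Two 500 kb chromosomes with a marker every 10 kb."""
    return sim.default_marker_maps(n_chromosomes=2, length_bp=500_000, spacing_bp=10_000)


@pytest.fixture(scope="session")
def small_config():
    return sim.CrossConfig(causal_chrom="chr1", causal_pos=250_000, seed=42)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory, small_config, small_maps):
    """One full emitted simulation, shared across the session."""
    out = tmp_path_factory.mktemp("simout")
    paths = sim.emit_truth_and_files(out, small_config, small_maps)
    return paths


def toy_gene(strand: str = "+", chrom: str = "chrX"):
    """Hand-built two-exon gene on a short synthetic chromosome.

    The CDS is ATGAAAGCTAGCGGATGA (MKASG*) split 9+9 across the exons at
    [11,19] and [30,38]; intron [20,29].
    """
    from edbsa.formats_io import GeneModel, reverse_complement

    cds = "ATGAAAGCTAGCGGATGA"
    left = "T" * 10
    intron = "GTTTTTTTAG"
    right = "C" * 10
    if strand == "+":
        seq = left + cds[:9] + intron + cds[9:] + right
    else:
        rc = reverse_complement(cds)
        seq = left + rc[:9] + intron + rc[9:] + right
    model = GeneModel(
        gene_id="toy",
        chrom=chrom,
        strand=strand,
        exons=[(11, 19), (30, 38)],
        cds=[(11, 19), (30, 38)],
        transcript_id="toy.t1",
    )
    return {chrom: seq}, model
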
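"""Shared fixtures: small synthetic datasets built at test time."""

import numpy as np
import pytest

from m6aclip.annotation import GeneAnnotation, TranscriptModel
from m6aclip.simulate import (
    SimulationConfig,
    make_genome_and_annotation,
    plant_sites,
    simulate_clip_reads,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulation used by several module tests."""
    cfg = SimulationConfig(n_genes=30, n_sites=60, reads_per_library=8000, seed=101)
    genome, annot = make_genome_and_annotation(cfg)
    truth = plant_sites(genome, annot, cfg)
    ip, inp = simulate_clip_reads(truth, annot, cfg, "CA", "WT")
    return {
        "config": cfg, "genome": genome, "annotation": annot,
        "truth": truth, "ip": ip, "input": inp,
    }


@pytest.fixture
def three_exon_transcript():
    """A plus-strand transcript with one internal exon, for junction tests."""
    return TranscriptModel(
        "tx_test", "gene_test", "chr1", "+",
        exons=[(0, 200), (400, 600), (800, 1000)],
        cds_start=50, cds_end=550,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
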
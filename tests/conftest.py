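from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from nmdscan.annotation_db import (
    GenomicInterval,
    TranscriptDatabase,
    TranscriptModel,
)

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


def make_tx(tx_id, exons, *, gene="G1", biotype="protein_coding",
            strand="+", chrom="chr1", cds_end=None, source="synthetic"):
    """Terse transcript-model builder for hand fixtures."""
    return TranscriptModel(
        transcript_id=tx_id, gene_id=gene, gene_symbol=gene,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
        cds_end=cds_end, biotype=biotype, source=source,
    )


@pytest.fixture
def cassette_gene_db():
    """Two-isoform gene: inclusion isoform is NMD, skipping is coding."""
    inclusion = make_tx(
        "T.inc", [(100, 200), (300, 400), (500, 600), (700, 800)],
        biotype="nmd",
    )
    skipping = make_tx(
        "T.skip", [(100, 200), (300, 400), (700, 800)],
        biotype="protein_coding",
    )
    return TranscriptDatabase([inclusion, skipping])


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """Full 60-gene synthetic fixture bundle written to disk once."""
    from nmdscan.synthetic_data import SimConfig, write_fixtures

    out = tmp_path_factory.mktemp("fixtures")
    cfg = SimConfig(n_genes=60, seed=20260920 % 2**16, depth=2000.0)
    paths = write_fixtures(cfg, out)
    return cfg, paths


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
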
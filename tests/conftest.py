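import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thermosplice.io_formats import GeneModel, TranscriptModel
from thermosplice.synthetic_data import SimConfig, gen_gene_models

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def ir_gene():
    """Canonical intron-retention gene: spliced vs retained isoform."""
    t1 = TranscriptModel("t1", [(0, 100), (200, 300)])
    t2 = TranscriptModel("t2", [(0, 300)])
    return GeneModel("gIR", "chr1", "+", 0, 300, [t1, t2])


@pytest.fixture
def random_gene_factory():
    """Random multi-isoform genes on a coarse grid (shared splice sites)."""

    def make(rng, gene_id="g", max_transcripts=4, max_exons=8, grid_step=20,
             span=400):
        grid = np.arange(0, span, grid_step)
        nt = int(rng.integers(2, max_transcripts + 1))
        transcripts = []
        for j in range(nt):
            k = int(rng.integers(1, max_exons + 1))
            k = min(k, len(grid) // 2)
            cuts = np.sort(rng.choice(grid, size=2 * k, replace=False))
            exons = [(int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(k)]
            transcripts.append(TranscriptModel(f"t{j}", exons))
        strand = "+" if rng.random() < 0.5 else "-"
        start = min(t.start for t in transcripts)
        end = max(t.end for t in transcripts)
        return GeneModel(gene_id, "chr1", strand, start, end, transcripts)

    return make


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded gene-model simulation shared across tests."""
    cfg = SimConfig(seed=101, n_genes=60)
    genes, truth = gen_gene_models(cfg)
    return cfg, genes, truth
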
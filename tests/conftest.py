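import pytest

from gcstratify.io_formats import GeneModel, GenomicInterval, SequenceRecord
from gcstratify.synthetic import SimulationConfig, simulate_genome


def make_model(
    tid="t1",
    seqid="chr1",
    start=101,
    end=200,
    strand="+",
    cds=None,
    exons=None,
    source="est2genome",
    aed=None,
    gene_id=None,
):
    """Terse single-transcript GeneModel builder for tests."""
    cds = cds or [(start, end)]
    ivs = [GenomicInterval(seqid, s, e, strand) for s, e in cds]
    ex = [GenomicInterval(seqid, s, e, strand) for s, e in exons] if exons else []
    return GeneModel(
        gene_id=gene_id or tid.split(".")[0],
        transcript_id=tid,
        location=GenomicInterval(seqid, min(i.start for i in ivs + ex) if ex else ivs[0].start,
                                 max(i.end for i in ivs + ex) if ex else ivs[-1].end, strand),
        cds=ivs,
        exons=ex,
        source_label=source,
        aed=aed,
    )


@pytest.fixture
def toy_genome():
    return [
        SequenceRecord(id="chr1", sequence="ATGCCCGGT" + "ACGT" * 25),
        SequenceRecord(id="chr2", sequence="GGCCGGCCAATT" * 10),
    ]


@pytest.fixture(scope="session")
def sim_small():
    """Small deterministic synthetic dataset shared across tests."""
    cfg = SimulationConfig(seed=11, n_genes=120, evidence_dropout=0.1)
    genome, models, truth = simulate_genome(cfg)
    return cfg, genome, models, truth


@pytest.fixture(scope="session")
def sim_bimodal_2000():
    """One default-condition genome (2000 genes) for distribution-level checks."""
    cfg = SimulationConfig(seed=7, n_genes=2000)
    genome, models, truth = simulate_genome(cfg)
    return cfg, genome, models, truth
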
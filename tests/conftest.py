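"""Shared fixtures: hand-built gene models and seeded synthetic datasets."""

import pytest

from beesplice.gene_model import Gene, GeneModel, Transcript
from beesplice.io_formats import GenomicInterval
from beesplice.synthetic_data import SimulationConfig, simulate


def build_model(genes):
    """Build a GeneModel from {gene_id: (chrom, strand, {tid: [(s, e), ...]})}."""
    model = GeneModel()
    for gid, (chrom, strand, transcripts) in genes.items():
        gene = Gene(id=gid, chrom=chrom, strand=strand)
        for tid, exons in transcripts.items():
            ivs = [GenomicInterval(chrom, s, e, strand) for s, e in sorted(exons)]
            gene.transcripts[tid] = Transcript(
                id=tid, gene_id=gid, exons=ivs,
                exon_provenance=["annotated"] * len(ivs),
            )
        model.genes[gid] = gene
    model.rebuild_indexes()
    return model


@pytest.fixture
def three_exon_model():
    """One plus-strand gene: exons (100,200), (300,400), (500,600)."""
    return build_model(
        {"g1": ("chr1", "+", {"g1.t1": [(100, 200), (300, 400), (500, 600)]})}
    )


@pytest.fixture(scope="session")
def event_dataset():
    """Moderate dataset with all planted event kinds (compact introns)."""
    cfg = SimulationConfig(
        seed=7, n_genes=48, n_ir=6, n_ce=6, n_alt_donor=6, n_alt_acceptor=6,
        n_afe=4, n_ale=4, n_novel_exon=4, n_novel_transcript=2,
        n_decoy_junctions=12, intron_len_mean=600, intron_len_min=250,
        methylation_coupling="random",
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """No planted events: annotation junctions only, background noise."""
    cfg = SimulationConfig(seed=11, n_genes=25, intron_len_mean=600,
                           intron_len_min=250)
    return simulate(cfg)
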
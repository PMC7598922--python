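import pytest

from circdec.annotation import (
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    build_splice_index,
)
from circdec.simulate import Simulation, SimulationConfig


def make_gene(gene_id, chrom, strand, exon_bounds, tx_id=None):
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_bounds]
    return GeneModel(gene_id, [TranscriptModel(tx_id or f"{gene_id}.t1", exons)])


@pytest.fixture
def toy_genes():
    """Two four-exon genes, one per strand, plus a gene on a second
    chromosome — enough structure for snapping/classification tests."""
    return [
        make_gene("g1", "chr1", "+", [(100, 200), (300, 400), (500, 600), (700, 800)]),
        make_gene("g2", "chr1", "-", [(2000, 2100), (2200, 2300), (2400, 2500), (2600, 2700)]),
        make_gene("g3", "chr2", "+", [(50, 150), (250, 350)]),
    ]


@pytest.fixture
def toy_index(toy_genes):
    return build_splice_index(toy_genes)


@pytest.fixture(scope="session")
def sim_small():
    """Shared small simulation: 20 genes, 10 planted circles, 20k reads."""
    return Simulation(SimulationConfig(n_reads=20_000, n_genes=20, n_circles=10, seed=7))


@pytest.fixture(scope="session")
def sim_small_files(sim_small, tmp_path_factory):
    """Reference + one written sample per condition for file-based tests."""
    outdir = tmp_path_factory.mktemp("sim_small")
    ref = sim_small.write_reference(outdir)
    plans, paths = {}, {}
    for cond in sim_small.conditions:
        plan = sim_small.sample_plan(cond, 1)
        plans[cond] = plan
        paths[cond] = sim_small.write_sample(plan, outdir)
    return {"sim": sim_small, "ref": ref, "plans": plans, "paths": paths}
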
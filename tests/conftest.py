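import pytest

from plastedit import Config, GeneModel, GeneticCode, GenomeRecord
from plastedit.io_formats import Feature


@pytest.fixture(scope="session")
def code():
    return GeneticCode.table11()


@pytest.fixture(scope="session")
def config():
    return Config()


def build_single_gene_genome(cds, strand="+", flank5="", flank3="", gene_id="g001"):
    """In-memory genome: flank5 + gene block + flank3, one gene/CDS pair.

    ``cds`` is given in coding sense; flanks are genomic (forward strand).
    """
    from plastedit.io_formats import revcomp

    block = cds if strand == "+" else revcomp(cds)
    seq = flank5 + block + flank3
    start, end = len(flank5), len(flank5) + len(block)
    features = [
        Feature("source", [(0, len(seq))], "+", {"organism": ["synthetic construct"]}),
        Feature("gene", [(start, end)], strand, {"gene": [gene_id]}),
        Feature("CDS", [(start, end)], strand, {"gene": [gene_id]}),
    ]
    genome = GenomeRecord(
        accession="TESTACC", sequence=seq, topology="linear", features=features
    )
    model = GeneModel(
        gene_id=gene_id,
        product="",
        intervals=[(start, end)],
        strand=strand,
        source_feature_index=2,
    )
    return genome, model


@pytest.fixture
def single_gene_genome():
    return build_single_gene_genome
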
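import pytest

from splicescape.models_io import GeneModel, TranscriptModel
from splicescape.synthetic_data import (
    generate_dataset,
    generate_expression,
    generate_genome_and_genes,
    generate_lncrnas,
)


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic study: genes + lncRNAs + expression + MS data."""
    return generate_dataset(seed=1)


@pytest.fixture(scope="session")
def genes_only():
    """Genome + gene catalogue with planted events, no downstream data."""
    return generate_genome_and_genes(seed=11)


@pytest.fixture(scope="session")
def noiseless():
    """Noise-free expression over the default catalogue (planted truth exact)."""
    ds = generate_genome_and_genes(seed=3)
    generate_expression(ds, noise_cv=0.0, seed=4)
    return ds


def make_gene(gene_id, isoforms, strand="+", chrom="chrT", reference=None):
    """Compact gene-model builder for hand-written structures."""
    txs = [
        TranscriptModel(
            transcript_id=f"{gene_id}.t{i + 1}",
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            exons=list(exons),
        )
        for i, exons in enumerate(isoforms)
    ]
    return GeneModel(gene_id, txs, reference_transcript_id=reference)
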
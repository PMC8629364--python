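import pytest
from Bio import SeqIO

from sloperon.core_io import LabelTable, attach_labels, parse_gene_annotation
from sloperon.synth_data import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def synth_dataset(tmp_path_factory):
    """Default synthetic dataset (fixed seed), shared across the suite."""
    outdir = tmp_path_factory.mktemp("synth_default")
    return generate_dataset(SynthConfig(seed=1), outdir)


@pytest.fixture(scope="session")
def synth_genes(synth_dataset):
    genes = parse_gene_annotation(synth_dataset.paths["annotation"])
    return attach_labels(genes, LabelTable.from_tsv(synth_dataset.paths["labels"]))


@pytest.fixture(scope="session")
def synth_genome(synth_dataset):
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(synth_dataset.paths["genome"]), "fasta")}
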
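import numpy as np
import pytest

from covskew.gene_model import read_bed12, filter_gene_model
from covskew.synth import ToyReadSpec, generate_toy_bam

TOY_CELLS = {
    "cellA": [("txPlain", 30, "uniform"), ("txSpliced", 20, "five_prime")],
    "cellB": [("txMinus", 25, "three_prime")],
    "cellC": [("txSpliced", 15, "uniform"), ("txMinus", 10, "five_prime")],
}


@pytest.fixture(scope="session")
def toy_dataset(tmp_path_factory):
    """Per-cell toy BAMs + BED12 + pileup-oracle truth table."""
    out = tmp_path_factory.mktemp("toy_percell")
    spec = ToyReadSpec(cells=dict(TOY_CELLS), read_length=50, barcoded=False, seed=7)
    return generate_toy_bam(spec, out)


@pytest.fixture(scope="session")
def toy_dataset_barcoded(tmp_path_factory):
    """Same read plan, one barcoded BAM with CB tags + barcodes.tsv."""
    out = tmp_path_factory.mktemp("toy_barcoded")
    spec = ToyReadSpec(cells=dict(TOY_CELLS), read_length=50, barcoded=True, seed=7)
    return generate_toy_bam(spec, out)


@pytest.fixture(scope="session")
def gene_models(toy_dataset):
    return filter_gene_model(read_bed12(toy_dataset.bed_path))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
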
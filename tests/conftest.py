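import numpy as np
import pytest

from funcdiv.data_model import GeneRecord, IsoformRecord, default_species_table
from funcdiv.simulate import SimConfig, simulate_dataset


def make_record(
    gene_id="g1",
    species_id="hsapiens",
    human_symbol="SYM1",
    P=1,
    motifs=(1,),
    one_to_one=True,
):
    """Hand-rolled GeneRecord with I = len(motifs)."""
    return GeneRecord(
        gene_id=gene_id,
        species_id=species_id,
        human_symbol=human_symbol,
        paralogue_count=P,
        isoforms=tuple(
            IsoformRecord(f"{gene_id}_iso{i + 1}", m) for i, m in enumerate(motifs)
        ),
        one_to_one=one_to_one,
    )


@pytest.fixture(scope="session")
def species_table():
    return default_species_table()


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-gene synthetic dataset shared across read-only tests."""
    return simulate_dataset(SimConfig(seed=123, n_genes=300))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def annotation_tsv(tmp_path):
    """One gene with three isoforms, flat per-isoform dialect."""
    path = tmp_path / "ann.tsv"
    header = "gene_id\tspecies_id\thuman_symbol\tparalogue_count\tisoform_id\tmotif_count\tone_to_one\n"
    rows = [
        "g1\thsapiens\tSYM1\t2\tiso1\t3\ttrue\n",
        "g1\thsapiens\tSYM1\t2\tiso2\t0\ttrue\n",
        "g1\thsapiens\tSYM1\t2\tiso3\t5\ttrue\n",
    ]
    path.write_text(header + "".join(rows))
    return path
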
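import numpy as np
import pytest

from qpcrkit.data_io import CtRecord, CtTable, ROLE_STANDARD, ROLE_UNKNOWN
from qpcrkit.stability import QuantityMatrix
from qpcrkit.synthetic import SimulationDesign, generate_dataset


def make_unknown(gene, sample, type_, ct, serial=1):
    return CtRecord(gene, sample, type_, serial, ct, ROLE_UNKNOWN)


def make_standard(gene, serial, ct, sample="std_r1", type_="STD"):
    return CtRecord(gene, sample, type_, serial, ct, ROLE_STANDARD)


@pytest.fixture
def tiny_table():
    """2 genes x 3 samples of unknowns plus a 3-level standard series."""
    records = []
    for gene, base in (("GeneA", 20.0), ("GeneB", 24.0)):
        for level in (1, 2, 3):
            records.append(make_standard(gene, level, base + 3.3219 * (level - 1)))
        for i, (sample, type_) in enumerate(
            (("c1", "CTL"), ("c2", "CTL"), ("t1", "TRT"))
        ):
            records.append(make_unknown(gene, sample, type_, base + 0.5 * i))
    return CtTable(records)


@pytest.fixture(scope="session")
def default_dataset():
    """Seeded default-shape simulation shared across tests."""
    return generate_dataset(SimulationDesign(seed=11))


def random_qm(rng, n_genes=5, n_samples=6, gene_prefix="g"):
    genes = [f"{gene_prefix}{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    q = np.exp2(rng.normal(0.0, 1.0, size=(n_genes, n_samples)))
    return QuantityMatrix(genes, samples, q)


def log2q_dict(qm):
    """Oracle-side view of a quantity matrix: gene -> list of log2 q."""
    return {g: list(np.log2(qm.row(g))) for g in qm.genes}
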
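import numpy as np
import pytest

from gppi.features import default_property_table
from gppi.graphs import build_graph
from gppi.model import EncoderConfig, init_model
from gppi.structure_io import ProteinStructure, ResidueRecord
from gppi.synthetic_data import SyntheticConfig, generate_chain, generate_world


@pytest.fixture(scope="session")
def table():
    return default_property_table()


def make_structure(coords, codes=None, protein_id="toy"):
    """Structure with explicit Calpha coordinates (one chain, 1-based)."""
    coords = np.asarray(coords, dtype=float)
    codes = codes or "A" * len(coords)
    residues = [
        ResidueRecord(code=codes[i], chain_id="A", seq_index=i + 1,
                      ca_coord=coords[i])
        for i in range(len(coords))
    ]
    return ProteinStructure(protein_id=protein_id, residues=residues,
                            source="synthetic")


@pytest.fixture
def structure_factory():
    return make_structure


@pytest.fixture(scope="session")
def chain_pair(table):
    """Two modest random chains and their contact graphs."""
    st_a = generate_chain(24, seed=3, protein_id="A1")
    st_b = generate_chain(20, seed=7, protein_id="B1")
    return build_graph(st_a, table), build_graph(st_b, table)


@pytest.fixture(scope="session")
def small_model():
    cfg = EncoderConfig(n_layers=2, n_heads=2, hidden_dim=8,
                        embedding_dim=6, dropout=0.0, seed=1)
    return init_model(cfg)


@pytest.fixture(scope="session")
def small_world():
    """Cheap synthetic world for pipeline tests."""
    cfg = SyntheticConfig(n_proteins=30, n_pairs=60, length_range=(20, 30),
                          seed=7)
    return generate_world(cfg)
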
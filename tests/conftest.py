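import numpy as np
import pandas as pd
import pytest

from cernet.datatypes import ExpressionDataset, Interaction
from cernet.interactome import Interactome


def make_dataset(values, genes=None, samples=None, dataset_id="DS1", anchor="ONECUT2"):
    values = np.asarray(values, dtype=float)
    genes = genes or [anchor] + [f"G{i}" for i in range(1, values.shape[0])]
    samples = samples or [f"S{j}" for j in range(1, values.shape[1] + 1)]
    df = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionDataset(dataset_id=dataset_id, values=df, anchor=anchor)


@pytest.fixture
def toy_dataset():
    rng = np.random.default_rng(7)
    return make_dataset(rng.normal(size=(6, 12)))


@pytest.fixture
def small_interactome():
    """Anchor shares miR-9 and miR-124 with GENE_A; GENE_B is disjoint."""
    inters = [
        Interaction("miR-9", "ONECUT2", total_sites=26, conserved_sites=13,
                    sources={"db1", "db2", "db3"}),
        Interaction("miR-124", "ONECUT2", total_sites=4, conserved_sites=2,
                    sources={"db1", "db2", "db3", "db4"}),
        Interaction("miR-9", "GENE_A", total_sites=3, conserved_sites=1, sources={"db1"}),
        Interaction("miR-124", "GENE_A", total_sites=2, conserved_sites=0, sources={"db1"}),
        Interaction("miR-7", "GENE_B", total_sites=5, conserved_sites=5, sources={"db1"}),
    ]
    return Interactome(interactions=inters)
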
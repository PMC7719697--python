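import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pancanet.core import ExpressionStudy


def make_study(values: np.ndarray, n_tumor: int, n_normal: int,
               technology: str = "microarray", cancer_type: str = "synthetic",
               dataset_id: str = "TST000001") -> ExpressionStudy:
    """Wrap a raw genes x samples array into an ExpressionStudy."""
    genes = [f"G{i:04d}" for i in range(1, values.shape[0] + 1)]
    cols = [f"T{i:03d}" for i in range(1, n_tumor + 1)] + \
           [f"N{i:03d}" for i in range(1, n_normal + 1)]
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=cols)
    groups = pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal,
                       index=cols, name="group")
    return ExpressionStudy(frame, groups, technology, cancer_type, dataset_id)


@pytest.fixture
def star_graph() -> nx.Graph:
    """Star with center 'c' and four leaves, all nodes flagged as seeds."""
    g = nx.Graph()
    g.add_node("c", is_seed=True)
    for leaf in "abde":
        g.add_node(leaf, is_seed=True)
        g.add_edge("c", leaf, confidence=0.9)
    return g


@pytest.fixture
def path_graph() -> nx.Graph:
    g = nx.path_graph(["a", "b", "c"])
    nx.set_node_attributes(g, True, "is_seed")
    return g
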
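import numpy as np
import pandas as pd
import pytest

from vagusconn.skeletons import Skeleton, SkeletonNode


def random_tree_skeleton(rng: np.random.Generator, n_nodes: int,
                         neuron_id: str = "n", scale: float = 100.0) -> Skeleton:
    """Random rooted tree with uniformly random parents and coordinates;
    independent of the package's synthetic generator."""
    nodes = {1: SkeletonNode(1, None, 0.0, 0.0, 0.0)}
    for i in range(2, n_nodes + 1):
        parent = int(rng.integers(1, i))
        x, y, z = rng.uniform(-scale, scale, size=3)
        nodes[i] = SkeletonNode(i, parent, float(x), float(y), float(z))
    return Skeleton(neuron_id, nodes, origin_node=1)


def chain_skeleton(coords, neuron_id="chain") -> Skeleton:
    nodes = {}
    for i, (x, y, z) in enumerate(coords, start=1):
        parent = None if i == 1 else i - 1
        nodes[i] = SkeletonNode(i, parent, float(x), float(y), float(z))
    return Skeleton(neuron_id, nodes, origin_node=1)


def connector_table(rows) -> pd.DataFrame:
    """rows: (connector_id, pre_neuron, pre_node, post_neuron, post_node,
    region, tissue_tag)"""
    return pd.DataFrame(rows, columns=[
        "connector_id", "pre_neuron", "pre_node", "post_neuron", "post_node",
        "region", "tissue_tag"])


def annotation_table(rows) -> pd.DataFrame:
    """rows: (neuron_id, cell_class, cluster, hemisphere, modality)"""
    return pd.DataFrame(rows, columns=[
        "neuron_id", "cell_class", "cluster", "hemisphere", "modality"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
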
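import numpy as np
import pytest

from perturbsim import (
    EdgeRecord,
    InputSpec,
    MetaPathwayGraph,
    NodeRecord,
    PolarGaussian,
)


@pytest.fixture
def fork_graph():
    """a activates b and inhibits c: the smallest branching example."""
    return MetaPathwayGraph(
        [NodeRecord("a"), NodeRecord("b"), NodeRecord("c")],
        [EdgeRecord("a", "b", 1), EdgeRecord("a", "c", -1)],
        {"pw1": {"a", "b"}, "pw2": {"b", "c"}},
    )


@pytest.fixture
def chain_graph():
    """a -> b -> c, all activating, unit out-degrees."""
    return MetaPathwayGraph(
        [NodeRecord("a"), NodeRecord("b"), NodeRecord("c")],
        [EdgeRecord("a", "b", 1), EdgeRecord("b", "c", 1)],
    )


@pytest.fixture
def gaussian():
    return PolarGaussian(np.random.default_rng(1))


def calibration_graph():
    """Star of activating sources into a scored hub.

    Ten sources feed the hub directly (path coefficient 1) and ten more
    split their outflow between the hub and a leak node (coefficient
    1/2), so null activity scores at the hub spread over many tally
    values instead of piling up at the extremes.
    """
    nodes = [NodeRecord("hub", "hub", "gene"), NodeRecord("leak", "leak", "gene")]
    edges = []
    for k in range(10):
        nodes.append(NodeRecord(f"d{k:02d}", "", "gene"))
        edges.append(EdgeRecord(f"d{k:02d}", "hub", 1))
        nodes.append(NodeRecord(f"h{k:02d}", "", "gene"))
        edges.append(EdgeRecord(f"h{k:02d}", "hub", 1))
        edges.append(EdgeRecord(f"h{k:02d}", "leak", 1))
    return MetaPathwayGraph(nodes, edges)


def write_tsv(path, text):
    path.write_text(text)
    return path


@pytest.fixture
def network_files(tmp_path):
    nodes = write_tsv(
        tmp_path / "nodes.tsv",
        "id\tname\tcategory\na\talpha\tgene\nb\tbeta\tgene\nc\tgamma\tmirna\n",
    )
    edges = write_tsv(
        tmp_path / "edges.tsv",
        "source\ttarget\tweight\na\tb\t+1\na\tc\t-1\n",
    )
    membership = write_tsv(
        tmp_path / "membership.tsv",
        "pathway_id\tpathway_name\tnode_id\npw1\tfirst\ta\npw1\tfirst\tb\n",
    )
    return edges, nodes, membership
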
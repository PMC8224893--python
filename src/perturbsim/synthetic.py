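"""Synthetic networks and pseudo-observed data.

Every stage of the pipeline can be exercised on generated inputs: an
Erdős–Rényi-style signed digraph with randomly grown pathway subsets, a
toy activation cascade with a closed-form steady state, and a noisy
"observed LogFC" table with known ground truth for the evaluation
metrics.  All generators are pure functions of their parameters and
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .logfc import LogFCParams, PolarGaussian, build_delta_e
from .metapathway import EdgeRecord, InputSpec, MetaPathwayGraph, NodeRecord
from .propagation import propagate_exact

__all__ = ["NetworkRecipe", "random_network", "toy_cascade", "synth_observed_logfc"]


@dataclass(frozen=True)
class NetworkRecipe:
    """Parameters of a random signed digraph.

    ``edge_probability`` is the independent chance of each ordered node
    pair (lower-to-higher index only when ``acyclic``) carrying an edge;
    ``inhibition_fraction`` is the chance an edge is inhibiting (-1).
    """

    n_nodes: int
    edge_probability: float
    inhibition_fraction: float = 0.3
    acyclic: bool = True
    n_pathways: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if not 0 <= self.edge_probability < 1:
            raise ValueError("edge_probability must be in [0, 1)")
        if not 0 <= self.inhibition_fraction <= 1:
            raise ValueError("inhibition_fraction must be in [0, 1]")
        if self.n_pathways < 0:
            raise ValueError("n_pathways must be >= 0")


def _node_id(i: int, width: int) -> str:
    return f"n{i:0{width}d}"


def random_network(recipe: NetworkRecipe) -> MetaPathwayGraph:
    """Generate a signed digraph from a :class:`NetworkRecipe`.

    When ``acyclic``, edges run only from lower to higher node index, so
    the index order is a topological order by construction.  Pathways
    are random connected subsets grown by breadth-first search over the
    undirected skeleton, giving overlapping membership structure.
    """
    rng = np.random.default_rng(recipe.seed)
    n = recipe.n_nodes
    width = max(3, len(str(n - 1)))
    nodes = [NodeRecord(_node_id(i, width), f"gene {i}", "gene") for i in range(n)]
    edges: list[EdgeRecord] = []
    adjacency: dict[int, set[int]] = {i: set() for i in range(n)}
    for i in range(n):
        targets = range(i + 1, n) if recipe.acyclic else range(n)
        for j in targets:
            if j == i:
                continue
            if rng.random() < recipe.edge_probability:
                sign = -1 if rng.random() < recipe.inhibition_fraction else 1
                edges.append(EdgeRecord(_node_id(i, width), _node_id(j, width), sign))
                adjacency[i].add(j)
                adjacency[j].add(i)
    membership = {}
    names = {}
    for p in range(recipe.n_pathways):
        pid = f"P{p:03d}"
        size = int(rng.integers(2, max(3, n // 3) + 1))
        start = int(rng.integers(n))
        grown = [start]
        frontier = [start]
        seen = {start}
        while frontier and len(grown) < size:
            nxt = frontier.pop(0)
            neigh = sorted(adjacency[nxt] - seen)
            if neigh:
                rng.shuffle(neigh)
            for other in neigh:
                if len(grown) >= size:
                    break
                seen.add(other)
                grown.append(other)
                frontier.append(other)
        membership[pid] = {_node_id(i, width) for i in grown}
        names[pid] = f"pathway {p}"
    return MetaPathwayGraph(nodes, edges, membership, names)


def toy_cascade(
    depth: int, branching: int = 1, inhibit_last: bool = False
) -> MetaPathwayGraph:
    """A rooted activating tree with closed-form propagation.

    Every node at depth d has ``branching`` children, so a root
    expression change of x propagates to exactly x / branching**d at
    depth d.  With ``inhibit_last`` the edge into the lexicographically
    last leaf is inhibiting, flipping that leaf's sign.  Two pathways
    are attached: all nodes, and the leaves.
    """
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    nodes = [NodeRecord("root", "root", "gene")]
    edges: list[EdgeRecord] = []
    level = ["root"]
    for d in range(1, depth + 1):
        nxt = []
        for parent in level:
            for _ in range(branching):
                nid = f"d{d}_{len(nxt):03d}"
                nxt.append(nid)
                nodes.append(NodeRecord(nid, nid, "gene"))
                edges.append(EdgeRecord(parent, nid, 1))
        level = nxt
    if inhibit_last:
        last_leaf = level[-1]
        edges = [
            EdgeRecord(e.source, e.target, -1 if e.target == last_leaf else e.weight)
            for e in edges
        ]
    membership = {
        "all": {rec.id for rec in nodes},
        "leaves": set(level),
    }
    return MetaPathwayGraph(
        nodes, edges, membership, {"all": "whole cascade", "leaves": "leaf layer"}
    )


def synth_observed_logfc(
    graph: MetaPathwayGraph,
    input_spec: InputSpec,
    noise_sd: float,
    rng: np.random.Generator,
    params: LogFCParams = LogFCParams(),
) -> dict[str, float]:
    """One noisy realisation of observed log-fold-changes.

    A single synthetic LogFC draw is propagated exactly and independent
    Gaussian noise of standard deviation ``noise_sd`` is added per node,
    emulating an observed differential-expression table whose ground
    truth is the propagation itself.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    delta = build_delta_e(graph, input_spec, PolarGaussian(rng), params)
    perturbed = propagate_exact(graph, delta)
    noise = rng.normal(0.0, noise_sd, size=len(graph.node_ids)) if noise_sd else np.zeros(len(graph.node_ids))
    return {
        nid: perturbed.values[nid] + float(noise[i])
        for i, nid in enumerate(graph.node_ids)
    }
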
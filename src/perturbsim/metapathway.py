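"""Signed directed meta-pathway graphs and simulation inputs.

A *meta-pathway* is a single directed graph obtained by merging many
pathway maps on their shared nodes.  Nodes are biological elements
(genes, miRNAs, metabolites); each edge carries a weight of ``+1``
(activation) or ``-1`` (inhibition).  Pathway identity is retained as a
membership map from pathway id to the set of member node ids, so that
results can later be aggregated back to pathway level.

The module also models the *simulation input*: a map from node id to a
deregulation direction (``+1`` up, ``-1`` down), an optional list of
non-expressed nodes to be removed from the network, and optional
dependency groups of input nodes whose deregulations are not
independent (handled by inserting a virtual regulator node).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "NodeRecord",
    "EdgeRecord",
    "MetaPathwayGraph",
    "InputSpec",
    "GraphValidationError",
    "ParseError",
    "load_network",
    "write_network",
    "load_input",
    "load_nonexpressed",
    "merge_graphs",
    "add_dependency_node",
    "apply_nonexpressed",
]

CATEGORIES = ("gene", "mirna", "metabolite", "virtual")

DIRECTION_LABELS = {"OVEREXPRESSION": 1, "UNDEREXPRESSION": -1}


class GraphValidationError(ValueError):
    """A graph, input or file violates a structural invariant."""


class ParseError(ValueError):
    """A TSV row could not be interpreted; message names file and line."""


@dataclass(frozen=True)
class NodeRecord:
    """One biological element of the network."""

    id: str
    name: str = ""
    category: str = "gene"

    def __post_init__(self) -> None:
        if not self.id:
            raise GraphValidationError("node id must be non-empty")
        if self.category not in CATEGORIES:
            raise GraphValidationError(
                f"node {self.id!r}: unknown category {self.category!r}"
            )


@dataclass(frozen=True)
class EdgeRecord:
    """A signed directed interaction: +1 activating, -1 inhibiting."""

    source: str
    target: str
    weight: int

    def __post_init__(self) -> None:
        if self.weight not in (1, -1):
            raise GraphValidationError(
                f"edge {self.source!r}->{self.target!r}: weight must be +1 or -1, "
                f"got {self.weight!r}"
            )


class MetaPathwayGraph:
    """Signed directed graph with pathway membership.

    Parameters
    ----------
    nodes
        Node records; ids must be unique.
    edges
        Edge records; endpoints must exist among ``nodes`` and
        (source, target) pairs must be unique.
    membership
        Mapping pathway id -> set of member node ids.  May be empty.
    pathway_names
        Optional display names per pathway id.
    """

    def __init__(
        self,
        nodes: Iterable[NodeRecord],
        edges: Iterable[EdgeRecord] = (),
        membership: Mapping[str, Iterable[str]] | None = None,
        pathway_names: Mapping[str, str] | None = None,
    ) -> None:
        g = nx.DiGraph()
        for rec in nodes:
            if g.has_node(rec.id):
                raise GraphValidationError(f"duplicate node id {rec.id!r}")
            g.add_node(rec.id, name=rec.name, category=rec.category)
        for rec in edges:
            for endpoint in (rec.source, rec.target):
                if not g.has_node(endpoint):
                    raise GraphValidationError(
                        f"edge {rec.source!r}->{rec.target!r} references unknown "
                        f"node {endpoint!r}"
                    )
            if g.has_edge(rec.source, rec.target):
                raise GraphValidationError(
                    f"duplicate edge {rec.source!r}->{rec.target!r}"
                )
            g.add_edge(rec.source, rec.target, weight=int(rec.weight))
        self._g = g
        self._membership: dict[str, frozenset[str]] = {}
        membership = membership or {}
        for pid, members in membership.items():
            members = frozenset(members)
            unknown = sorted(m for m in members if not g.has_node(m))
            if unknown:
                raise GraphValidationError(
                    f"pathway {pid!r} references unknown nodes: {unknown}"
                )
            self._membership[pid] = members
        self._pathway_names = dict(pathway_names or {})

    # -- basic queries -------------------------------------------------

    @property
    def m(self) -> int:
        """Number of nodes."""
        return self._g.number_of_nodes()

    @property
    def node_ids(self) -> tuple[str, ...]:
        """Node ids in canonical (sorted) order."""
        return tuple(sorted(self._g.nodes))

    @property
    def membership(self) -> dict[str, frozenset[str]]:
        return dict(self._membership)

    @property
    def pathway_names(self) -> dict[str, str]:
        return dict(self._pathway_names)

    def __contains__(self, node_id: str) -> bool:
        return self._g.has_node(node_id)

    def node(self, node_id: str) -> NodeRecord:
        try:
            attrs = self._g.nodes[node_id]
        except KeyError:
            raise KeyError(f"unknown node {node_id!r}") from None
        return NodeRecord(node_id, attrs.get("name", ""), attrs.get("category", "gene"))

    def nodes(self) -> list[NodeRecord]:
        return [self.node(i) for i in self.node_ids]

    def edges(self) -> list[EdgeRecord]:
        return sorted(
            (EdgeRecord(u, v, d["weight"]) for u, v, d in self._g.edges(data=True)),
            key=lambda e: (e.source, e.target),
        )

    def weight(self, source: str, target: str) -> int:
        return int(self._g.edges[source, target]["weight"])

    def upstream(self, k: str) -> set[str]:
        """Sources of in-edges of node ``k`` (the set U(k))."""
        if not self._g.has_node(k):
            raise KeyError(f"unknown node {k!r}")
        return set(self._g.predecessors(k))

    def downstream(self, k: str) -> set[str]:
        """Targets of out-edges of node ``k`` (the set D(k))."""
        if not self._g.has_node(k):
            raise KeyError(f"unknown node {k!r}")
        return set(self._g.successors(k))

    def out_weight_total(self, k: str) -> int:
        """Total absolute outgoing weight of ``k``; with weights in {+1,-1}
        this equals the out-degree."""
        if not self._g.has_node(k):
            raise KeyError(f"unknown node {k!r}")
        return int(self._g.out_degree(k))

    def to_networkx(self) -> nx.DiGraph:
        """A copy of the underlying :class:`networkx.DiGraph`."""
        return self._g.copy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetaPathwayGraph):
            return NotImplemented
        return (
            self.nodes() == other.nodes()
            and self.edges() == other.edges()
            and self._membership == other._membership
        )

    def __repr__(self) -> str:
        return (
            f"MetaPathwayGraph(m={self.m}, edges={self._g.number_of_edges()}, "
            f"pathways={len(self._membership)})"
        )


@dataclass(frozen=True)
class InputSpec:
    """Simulation input: deregulated nodes and constraints.

    ``directions`` maps node id to -1 (down), 0 or +1 (up); ``nonexpressed``
    lists nodes absent in the studied cell line; ``dependency_groups`` are
    lists of (node id, direction) pairs whose deregulations are coupled.
    """

    directions: Mapping[str, int] = field(default_factory=dict)
    nonexpressed: frozenset[str] = field(default_factory=frozenset)
    dependency_groups: tuple[tuple[tuple[str, int], ...], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "directions", dict(self.directions))
        object.__setattr__(self, "nonexpressed", frozenset(self.nonexpressed))
        object.__setattr__(
            self,
            "dependency_groups",
            tuple(tuple((n, int(v)) for n, v in g) for g in self.dependency_groups),
        )
        for node, v in self.directions.items():
            if v not in (-1, 0, 1):
                raise GraphValidationError(
                    f"input node {node!r}: direction must be -1, 0 or +1, got {v!r}"
                )
        overlap = self.nonexpressed & {
            n for n, v in self.directions.items() if v != 0
        }
        if overlap:
            raise GraphValidationError(
                f"nodes marked both deregulated and non-expressed: {sorted(overlap)}"
            )
        for group in self.dependency_groups:
            for node, v in group:
                if v not in (-1, 1):
                    raise GraphValidationError(
                        f"dependency-group member {node!r} must have direction ±1"
                    )
                if self.directions.get(node) != v:
                    raise GraphValidationError(
                        f"dependency-group member {node!r} must appear in the input "
                        f"with the same direction"
                    )

    @property
    def active_nodes(self) -> tuple[str, ...]:
        """Deregulated node ids (direction ±1), in sorted order."""
        return tuple(sorted(n for n, v in self.directions.items() if v != 0))

    @property
    def direction_values(self) -> tuple[int, ...]:
        """Directions of :attr:`active_nodes`, in the same order."""
        return tuple(self.directions[n] for n in self.active_nodes)


# ----------------------------------------------------------------------
# TSV input / output
# ----------------------------------------------------------------------

def _read_rows(path: str | Path, n_min: int, n_max: int | None = None):
    """Yield (line_number, fields) for each non-comment, non-blank line."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            hi = n_max if n_max is not None else n_min
            if not (n_min <= len(fields) <= hi):
                raise ParseError(
                    f"{path}:{lineno}: expected {n_min}"
                    + (f"-{hi}" if hi != n_min else "")
                    + f" tab-separated fields, got {len(fields)}"
                )
            yield lineno, fields


def _skip_header(rows, expected_first: str):
    rows = iter(rows)
    try:
        first = next(rows)
    except StopIteration:
        return
    if first[1][0].strip().lower() != expected_first:
        yield first
    yield from rows


def load_network(
    edges_path: str | Path,
    nodes_path: str | Path,
    membership_path: str | Path | None = None,
) -> MetaPathwayGraph:
    """Load a meta-pathway graph from TSV tables.

    ``nodes_path``: ``id<TAB>name<TAB>category``; ``edges_path``:
    ``source<TAB>target<TAB>weight`` with weight in {+1, -1, 1};
    ``membership_path`` (optional): ``pathway_id<TAB>pathway_name<TAB>node_id``.
    Header lines and ``#`` comments are ignored.
    """
    nodes = []
    for lineno, f in _skip_header(_read_rows(nodes_path, 3), "id"):
        try:
            nodes.append(NodeRecord(f[0].strip(), f[1].strip(), f[2].strip()))
        except GraphValidationError as exc:
            raise ParseError(f"{nodes_path}:{lineno}: {exc}") from exc
    edges = []
    for lineno, f in _skip_header(_read_rows(edges_path, 3), "source"):
        raw = f[2].strip()
        if raw in {"+1", "1"}:
            w = 1
        elif raw == "-1":
            w = -1
        else:
            raise ParseError(
                f"{edges_path}:{lineno}: weight must be one of +1, 1, -1, got {raw!r}"
            )
        edges.append(EdgeRecord(f[0].strip(), f[1].strip(), w))
    membership: dict[str, set[str]] = {}
    pathway_names: dict[str, str] = {}
    if membership_path is not None:
        for lineno, f in _skip_header(_read_rows(membership_path, 3), "pathway_id"):
            pid, pname, nid = (x.strip() for x in f)
            membership.setdefault(pid, set()).add(nid)
            pathway_names.setdefault(pid, pname)
    return MetaPathwayGraph(nodes, edges, membership, pathway_names)


def write_network(
    graph: MetaPathwayGraph,
    edges_path: str | Path,
    nodes_path: str | Path,
    membership_path: str | Path | None = None,
) -> None:
    """Write a graph back to the TSV dialects read by :func:`load_network`."""
    with Path(nodes_path).open("w", encoding="utf-8") as fh:
        fh.write("id\tname\tcategory\n")
        for rec in graph.nodes():
            fh.write(f"{rec.id}\t{rec.name}\t{rec.category}\n")
    with Path(edges_path).open("w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tweight\n")
        for rec in graph.edges():
            fh.write(f"{rec.source}\t{rec.target}\t{rec.weight:+d}\n")
    if membership_path is not None:
        names = graph.pathway_names
        with Path(membership_path).open("w", encoding="utf-8") as fh:
            fh.write("pathway_id\tpathway_name\tnode_id\n")
            for pid in sorted(graph.membership):
                for nid in sorted(graph.membership[pid]):
                    fh.write(f"{pid}\t{names.get(pid, pid)}\t{nid}\n")


def load_input(path: str | Path) -> InputSpec:
    """Read a simulation-input TSV: ``node_id<TAB>direction[<TAB>group]``.

    Direction is ``OVEREXPRESSION`` or ``UNDEREXPRESSION``; an optional
    third column labels dependency groups.
    """
    directions: dict[str, int] = {}
    groups: dict[str, list[tuple[str, int]]] = {}
    for lineno, f in _skip_header(_read_rows(path, 2, 3), "node_id"):
        node = f[0].strip()
        label = f[1].strip().upper()
        if label not in DIRECTION_LABELS:
            raise ParseError(
                f"{path}:{lineno}: direction must be OVEREXPRESSION or "
                f"UNDEREXPRESSION, got {f[1]!r}"
            )
        v = DIRECTION_LABELS[label]
        if node in directions:
            raise ParseError(f"{path}:{lineno}: duplicate input node {node!r}")
        directions[node] = v
        if len(f) == 3 and f[2].strip():
            groups.setdefault(f[2].strip(), []).append((node, v))
    return InputSpec(
        directions=directions,
        dependency_groups=tuple(tuple(g) for _, g in sorted(groups.items())),
    )


def load_nonexpressed(path: str | Path) -> frozenset[str]:
    """Read a non-expressed list: one node id per line."""
    ids = set()
    for _, f in _read_rows(path, 1):
        ids.add(f[0].strip())
    return frozenset(ids)


# ----------------------------------------------------------------------
# Graph surgery
# ----------------------------------------------------------------------

def merge_graphs(graphs: Sequence[MetaPathwayGraph]) -> MetaPathwayGraph:
    """Merge pathway graphs on their common nodes.

    Node and edge sets are unions; membership entries of every source
    graph are retained.  The same (source, target) edge appearing with
    opposite signs in two graphs is a hard error: a silently chosen sign
    would invert every downstream prediction.
    """
    if not graphs:
        raise ValueError("merge_graphs requires at least one graph")
    nodes: dict[str, NodeRecord] = {}
    weights: dict[tuple[str, str], int] = {}
    membership: dict[str, set[str]] = {}
    pathway_names: dict[str, str] = {}
    for g in graphs:
        for rec in g.nodes():
            prev = nodes.get(rec.id)
            if prev is not None and (prev.name, prev.category) != (rec.name, rec.category):
                raise GraphValidationError(
                    f"node {rec.id!r} has conflicting annotations across graphs"
                )
            nodes[rec.id] = rec
        for rec in g.edges():
            key = (rec.source, rec.target)
            if key in weights and weights[key] != rec.weight:
                raise GraphValidationError(
                    f"edge {rec.source!r}->{rec.target!r} has conflicting weights "
                    f"{weights[key]:+d} and {rec.weight:+d}"
                )
            weights[key] = rec.weight
        for pid, members in g.membership.items():
            membership.setdefault(pid, set()).update(members)
        for pid, name in g.pathway_names.items():
            pathway_names.setdefault(pid, name)
    edges = [EdgeRecord(s, t, w) for (s, t), w in weights.items()]
    return MetaPathwayGraph(nodes.values(), edges, membership, pathway_names)


def add_dependency_node(
    graph: MetaPathwayGraph, input_spec: InputSpec
) -> tuple[MetaPathwayGraph, InputSpec]:
    """Resolve dependency groups by inserting virtual regulator nodes.

    For each group a fresh virtual node V* is added with one edge
    V* -> member of weight equal to the member's direction; the members'
    own directions are removed from the input and replaced by V* = +1.
    The original graph is not mutated.
    """
    if not input_spec.dependency_groups:
        return graph, input_spec
    nodes = graph.nodes()
    edges = graph.edges()
    directions = dict(input_spec.directions)
    existing = set(graph.node_ids)
    for gi, group in enumerate(input_spec.dependency_groups, start=1):
        if len(group) < 2:
            raise GraphValidationError(
                f"dependency group {gi} has {len(group)} member(s); at least 2 required"
            )
        vid = f"__virtual_{gi}"
        while vid in existing:
            vid += "_"
        existing.add(vid)
        nodes.append(NodeRecord(vid, f"virtual regulator {gi}", "virtual"))
        for member, v in group:
            if member not in graph:
                raise GraphValidationError(
                    f"dependency-group member {member!r} absent from graph"
                )
            if v == 0:
                raise GraphValidationError(
                    f"dependency-group member {member!r} has direction 0"
                )
            edges.append(EdgeRecord(vid, member, v))
            directions.pop(member, None)
        directions[vid] = 1
    new_graph = MetaPathwayGraph(nodes, edges, graph.membership, graph.pathway_names)
    new_input = InputSpec(
        directions=directions,
        nonexpressed=input_spec.nonexpressed,
        dependency_groups=(),
    )
    return new_graph, new_input


def apply_nonexpressed(
    graph: MetaPathwayGraph, nonexpressed: Iterable[str]
) -> MetaPathwayGraph:
    """Remove non-expressed nodes and all their incident edges.

    A removed node neither receives nor transmits perturbation, and its
    removal also shrinks the out-degree denominator of its upstream
    neighbours.  Unknown ids are ignored with a warning.
    """
    nonexpressed = set(nonexpressed)
    unknown = sorted(n for n in nonexpressed if n not in graph)
    if unknown:
        warnings.warn(
            f"non-expressed ids not in graph (ignored): {unknown}", stacklevel=2
        )
    drop = nonexpressed - set(unknown)
    if not drop:
        return graph
    nodes = [rec for rec in graph.nodes() if rec.id not in drop]
    edges = [
        rec
        for rec in graph.edges()
        if rec.source not in drop and rec.target not in drop
    ]
    membership = {
        pid: members - drop for pid, members in graph.membership.items()
    }
    return MetaPathwayGraph(nodes, edges, membership, graph.pathway_names)
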
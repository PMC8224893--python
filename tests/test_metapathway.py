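import pytest

from perturbsim import (
    EdgeRecord,
    GraphValidationError,
    InputSpec,
    MetaPathwayGraph,
    NodeRecord,
    ParseError,
    add_dependency_node,
    apply_nonexpressed,
    load_input,
    load_network,
    load_nonexpressed,
    merge_graphs,
    write_network,
)


class TestLoadWrite:
    def test_load_three_node_fork(self, network_files):
        edges, nodes, membership = network_files
        g = load_network(edges, nodes, membership)
        assert g.m == 3
        assert g.weight("a", "b") == 1 and g.weight("a", "c") == -1
        assert g.membership == {"pw1": frozenset({"a", "b"})}
        assert g.node("c").category == "mirna"

    def test_round_trip_is_identity(self, network_files, tmp_path):
        g = load_network(*network_files)
        paths = (tmp_path / "e2.tsv", tmp_path / "n2.tsv", tmp_path / "m2.tsv")
        write_network(g, *paths)
        assert load_network(*paths) == g

    def test_edge_to_unknown_node_rejected(self, network_files, tmp_path):
        edges = tmp_path / "bad_edges.tsv"
        edges.write_text("source\ttarget\tweight\na\tz\t+1\n")
        with pytest.raises(GraphValidationError, match="z"):
            load_network(edges, network_files[1])

    def test_bad_weight_is_parse_error(self, network_files, tmp_path):
        edges = tmp_path / "bad_edges.tsv"
        edges.write_text("source\ttarget\tweight\na\tb\t2\n")
        with pytest.raises(ParseError, match="bad_edges.tsv:2"):
            load_network(edges, network_files[1])

    def test_malformed_row_names_file_and_line(self, network_files, tmp_path):
        edges = tmp_path / "bad_edges.tsv"
        edges.write_text("source\ttarget\tweight\na b +1\n")
        with pytest.raises(ParseError, match="bad_edges.tsv:2"):
            load_network(edges, network_files[1])

    def test_duplicate_edge_rejected(self, network_files, tmp_path):
        edges = tmp_path / "dup.tsv"
        edges.write_text("source\ttarget\tweight\na\tb\t+1\na\tb\t+1\n")
        with pytest.raises(GraphValidationError, match="duplicate"):
            load_network(edges, network_files[1])

    def test_comments_and_blank_lines_ignored(self, network_files, tmp_path):
        edges = tmp_path / "c.tsv"
        edges.write_text("# a comment\nsource\ttarget\tweight\n\na\tb\t1\n")
        g = load_network(edges, network_files[1])
        assert g.weight("a", "b") == 1

    def test_load_input_with_groups(self, tmp_path):
        p = tmp_path / "input.tsv"
        p.write_text(
            "node_id\tdirection\tgroup\n"
            "a\tOVEREXPRESSION\tg1\nb\tUNDEREXPRESSION\tg1\nc\tOVEREXPRESSION\n"
        )
        spec = load_input(p)
        assert spec.directions == {"a": 1, "b": -1, "c": 1}
        assert spec.dependency_groups == ((("a", 1), ("b", -1)),)

    def test_load_input_rejects_bad_direction(self, tmp_path):
        p = tmp_path / "input.tsv"
        p.write_text("node_id\tdirection\na\tUP\n")
        with pytest.raises(ParseError, match="OVEREXPRESSION"):
            load_input(p)

    def test_load_nonexpressed(self, tmp_path):
        p = tmp_path / "ne.txt"
        p.write_text("a\nb\n# comment\n")
        assert load_nonexpressed(p) == {"a", "b"}


class TestGraphModel:
    def test_upstream_downstream(self, fork_graph):
        assert fork_graph.upstream("b") == {"a"}
        assert fork_graph.downstream("a") == {"b", "c"}
        assert fork_graph.upstream("a") == set()

    def test_multiple_upstream(self):
        g = MetaPathwayGraph(
            [NodeRecord("a"), NodeRecord("b"), NodeRecord("c")],
            [EdgeRecord("a", "b", 1), EdgeRecord("c", "b", 1)],
        )
        assert g.upstream("b") == {"a", "c"}

    def test_isolated_node_has_no_neighbours(self):
        g = MetaPathwayGraph([NodeRecord("x")])
        assert g.upstream("x") == set() and g.downstream("x") == set()

    def test_unknown_node_raises(self, fork_graph):
        with pytest.raises(KeyError):
            fork_graph.upstream("zzz")

    def test_weight_must_be_unit(self):
        with pytest.raises(GraphValidationError):
            EdgeRecord("a", "b", 2)

    def test_input_spec_rejects_overlap_with_nonexpressed(self):
        with pytest.raises(GraphValidationError):
            InputSpec(directions={"a": 1}, nonexpressed={"a"})

    def test_input_spec_rejects_bad_direction(self):
        with pytest.raises(GraphValidationError):
            InputSpec(directions={"a": 2})


class TestMerge:
    def test_disjoint_union(self):
        g1 = MetaPathwayGraph(
            [NodeRecord("a"), NodeRecord("b")], [EdgeRecord("a", "b", 1)], {"p1": {"a"}}
        )
        g2 = MetaPathwayGraph(
            [NodeRecord("c"), NodeRecord("d")], [EdgeRecord("c", "d", -1)], {"p2": {"c"}}
        )
        merged = merge_graphs([g1, g2])
        assert merged.m == 4
        assert merged.membership == {"p1": frozenset("a"), "p2": frozenset("c")}

    def test_shared_node_counted_once(self):
        g1 = MetaPathwayGraph([NodeRecord("a"), NodeRecord("b")], [EdgeRecord("a", "b", 1)])
        g2 = MetaPathwayGraph([NodeRecord("b"), NodeRecord("c")], [EdgeRecord("b", "c", 1)])
        assert merge_graphs([g1, g2]).m == 3

    def test_identical_edge_union_is_idempotent(self, fork_graph):
        assert merge_graphs([fork_graph, fork_graph]) == fork_graph

    def test_conflicting_weights_raise(self):
        g1 = MetaPathwayGraph([NodeRecord("a"), NodeRecord("b")], [EdgeRecord("a", "b", 1)])
        g2 = MetaPathwayGraph([NodeRecord("a"), NodeRecord("b")], [EdgeRecord("a", "b", -1)])
        with pytest.raises(GraphValidationError, match="conflicting"):
            merge_graphs([g1, g2])


class TestDependencyNodes:
    def test_group_becomes_virtual_regulator(self, fork_graph):
        spec = InputSpec(
            directions={"a": 1, "b": 1, "c": -1},
            dependency_groups=((("a", 1), ("b", 1), ("c", -1)),),
        )
        g2, spec2 = add_dependency_node(fork_graph, spec)
        virtual = [n for n in g2.nodes() if n.category == "virtual"]
        assert len(virtual) == 1
        vid = virtual[0].id
        assert g2.weight(vid, "a") == 1
        assert g2.weight(vid, "b") == 1
        assert g2.weight(vid, "c") == -1
        assert spec2.directions == {vid: 1}
        assert spec2.dependency_groups == ()
        # original untouched
        assert fork_graph.m == 3

    def test_singleton_group_rejected(self, fork_graph):
        spec = InputSpec(directions={"a": 1}, dependency_groups=((("a", 1),),))
        with pytest.raises(GraphValidationError, match="at least 2"):
            add_dependency_node(fork_graph, spec)

    def test_two_groups_get_distinct_virtual_nodes(self, fork_graph):
        spec = InputSpec(
            directions={"a": 1, "b": 1, "c": -1},
            dependency_groups=((("a", 1), ("b", 1)), (("a", 1), ("c", -1))),
        )
        g2, spec2 = add_dependency_node(fork_graph, spec)
        virtual = [n.id for n in g2.nodes() if n.category == "virtual"]
        assert len(virtual) == 2
        assert all(spec2.directions[v] == 1 for v in virtual)

    def test_group_size_t_adds_one_node_t_edges(self, fork_graph):
        spec = InputSpec(
            directions={"a": 1, "b": -1},
            dependency_groups=((("a", 1), ("b", -1)),),
        )
        g2, _ = add_dependency_node(fork_graph, spec)
        assert g2.m == fork_graph.m + 1
        assert len(g2.edges()) == len(fork_graph.edges()) + 2
        # dropping the virtual node restores the original graph
        restored = apply_nonexpressed(
            g2, {n.id for n in g2.nodes() if n.category == "virtual"}
        )
        assert restored.nodes() == fork_graph.nodes()
        assert restored.edges() == fork_graph.edges()

    def test_member_absent_from_graph(self, fork_graph):
        spec = InputSpec(
            directions={"a": 1, "zz": 1},
            dependency_groups=((("a", 1), ("zz", 1)),),
        )
        with pytest.raises(GraphValidationError, match="zz"):
            add_dependency_node(fork_graph, spec)


class TestNonExpressed:
    def test_chain_break(self, chain_graph):
        g = apply_nonexpressed(chain_graph, {"b"})
        assert g.node_ids == ("a", "c")
        assert g.edges() == []

    def test_empty_set_is_identity(self, chain_graph):
        assert apply_nonexpressed(chain_graph, set()) is chain_graph

    def test_total_removal(self, chain_graph):
        assert apply_nonexpressed(chain_graph, {"a", "b", "c"}).m == 0

    def test_unknown_ids_warn(self, chain_graph):
        with pytest.warns(UserWarning, match="zzz"):
            g = apply_nonexpressed(chain_graph, {"b", "zzz"})
        assert g.node_ids == ("a", "c")

    def test_membership_updated(self, fork_graph):
        g = apply_nonexpressed(fork_graph, {"b"})
        assert g.membership == {"pw1": frozenset({"a"}), "pw2": frozenset({"c"})}
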
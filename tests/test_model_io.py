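"""Rule-file parsing, input completion, round-trips, signed edges, sink removal."""

import pytest

from neuritebool import (
    NetworkFormatError,
    complete_inputs,
    interaction_graph,
    load_neurite_model,
    parse_network,
    remove_sink_nodes,
    truth_table_equal,
    write_network,
)

NEURITE_TARGETS = [
    "neuro_elo", "f_actin", "arp2_3", "wave", "cdc42", "rhoa", "rac1", "rock",
    "pak1", "arhgap15", "shootin1", "cdk5_p35", "limk2", "cfl", "limk1", "ssh1",
]
NEURITE_INPUTS = {
    "profilin", "formin", "tiam1", "arhgef6", "arhgef7", "trio",
    "noma_gap", "ophn1",
}


class TestParseNetwork:
    def test_bundled_model_targets_in_file_order(self):
        net = load_neurite_model(completed=False)
        assert list(net.nodes) == NEURITE_TARGETS

    def test_minimal_two_node_network(self):
        net = parse_network("a, b\nb, !a")
        assert net.nodes == ("a", "b")
        assert net.undefined_names() == frozenset()

    def test_duplicate_target_rejected(self):
        with pytest.raises(NetworkFormatError, match="duplicate"):
            parse_network("a, b\na, c")

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(NetworkFormatError, match="line 2"):
            parse_network("a, b\nno comma here")

    def test_expression_error_reports_line_number(self):
        with pytest.raises(NetworkFormatError, match="line 1"):
            parse_network("a, b &")

    def test_comments_header_and_blank_lines_ignored(self):
        net = parse_network("# comment\ntargets, factors\n\na, a\n")
        assert net.nodes == ("a",)
        assert net.inputs == {"a"}


class TestCompleteInputs:
    def test_bundled_model_gains_eight_identity_inputs(self):
        net = complete_inputs(load_neurite_model(completed=False))
        assert net.n_nodes == 24
        assert net.inputs == NEURITE_INPUTS
        for name in NEURITE_INPUTS:
            rule = net.rule(name)
            assert rule.expression.render() == name

    def test_no_dangling_references_is_identity(self):
        net = parse_network("a, b\nb, !a")
        assert complete_inputs(net) is net

    def test_single_rule_gains_two_inputs(self):
        net = complete_inputs(parse_network("a, b & c"))
        assert net.nodes == ("a", "b", "c")
        assert net.inputs == {"b", "c"}

    def test_completed_network_validates(self, neurite_net):
        neurite_net.validate()


class TestWriteNetwork:
    def test_bundled_model_round_trip_truth_tables(self, neurite_net):
        reparsed = complete_inputs(parse_network(write_network(neurite_net)))
        assert reparsed.nodes == neurite_net.nodes
        for a, b in zip(neurite_net.rules, reparsed.rules):
            assert a.target == b.target
            assert truth_table_equal(a.expression, b.expression)

    def test_identity_input_written_as_self_rule(self):
        net = parse_network("a, a")
        assert "a, a" in write_network(net)

    def test_cfl_rule_round_trip(self, neurite_net):
        line = [l for l in write_network(neurite_net).splitlines()
                if l.startswith("cfl,")][0]
        reparsed = parse_network(line)
        assert truth_table_equal(reparsed.rule("cfl").expression,
                                 neurite_net.rule("cfl").expression)


class TestInteractionGraph:
    def _edge(self, edges, source, target):
        match = [e for e in edges if e.source == source and e.target == target]
        assert len(match) == 1, f"expected exactly one edge {source}->{target}"
        return match[0]

    def test_cfl_rule_polarity(self):
        edges = interaction_graph(parse_network("cfl, ssh1 & !(limk2 | limk1)"))
        assert self._edge(edges, "ssh1", "cfl").sign == "activatory"
        assert self._edge(edges, "limk2", "cfl").sign == "inhibitory"
        assert self._edge(edges, "limk1", "cfl").sign == "inhibitory"

    def test_limk1_rule_polarity(self):
        edges = interaction_graph(parse_network("limk1, pak1 | !ssh1"))
        assert self._edge(edges, "pak1", "limk1").sign == "activatory"
        assert self._edge(edges, "ssh1", "limk1").sign == "inhibitory"

    def test_both_parities_is_ambiguous(self):
        edges = interaction_graph(parse_network("x, a & !a"))
        assert self._edge(edges, "a", "x").sign == "ambiguous"

    def test_identity_inputs_flagged_self_loops(self, neurite_net):
        edges = interaction_graph(neurite_net)
        loops = {e.source for e in edges if e.self_loop}
        assert loops == NEURITE_INPUTS

    def test_edge_sources_equal_rule_variables(self, neurite_net):
        edges = interaction_graph(neurite_net)
        for rule in neurite_net.rules:
            sources = {e.source for e in edges if e.target == rule.target}
            assert sources == set(rule.expression.variables())


class TestRemoveSinkNodes:
    def test_bundled_model_already_simplified(self, neurite_net):
        pruned = remove_sink_nodes(neurite_net)
        assert pruned.nodes == neurite_net.nodes

    def test_simple_sink_removed(self):
        net = parse_network("a, b\nc, b")
        pruned = remove_sink_nodes(complete_inputs(net), keep={"a"})
        assert "c" not in pruned.nodes
        assert "a" in pruned.nodes

    def test_keep_everything_is_identity(self):
        net = complete_inputs(parse_network("a, b\nc, b"))
        assert remove_sink_nodes(net, keep=set(net.nodes)).nodes == net.nodes

    def test_removal_iterates_through_chains(self):
        # b -> c -> d is a sink chain once d goes
        net = complete_inputs(parse_network("a, a\nb, a\nc, b\nd, c"))
        pruned = remove_sink_nodes(net, keep={"a"})
        assert set(pruned.nodes) == {"a"}

    def test_unknown_keep_node_rejected(self, neurite_net):
        with pytest.raises(KeyError):
            remove_sink_nodes(neurite_net, keep={"nonexistent"})
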
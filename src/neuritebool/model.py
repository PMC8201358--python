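"""Boolean network models in the ``targets, factors`` rule-file format.

A network is an ordered list of named nodes, each with a Boolean update rule
over other nodes.  Node order is significant: it defines the bit positions of
the packed integer state codes used by the dynamics and attractor modules
(bit *i* of a state code holds the value of ``nodes[i]``).

Unregulated factors — names that appear on the right-hand side of rules but
never as a target — model boundary conditions (here, constitutively present
GEFs/GAPs such as trio or ophn1).  :func:`complete_inputs` gives each of them
the self-sustaining identity rule ``x, x`` so that their value is conserved
along every trajectory and the state space splits into closed input blocks.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .expr import (
    And,
    BoolExpr,
    Const,
    ExpressionError,
    Not,
    Or,
    Var,
    parse_expression,
)

__all__ = [
    "NodeRule",
    "BooleanNetwork",
    "SignedEdge",
    "NetworkFormatError",
    "parse_network",
    "complete_inputs",
    "write_network",
    "interaction_graph",
    "remove_sink_nodes",
    "edges_to_dataframe",
    "edges_to_graph",
]


class NetworkFormatError(ValueError):
    """Malformed rule file (duplicate target, missing comma, bad expression)."""


@dataclass(frozen=True)
class NodeRule:
    target: str
    expression: BoolExpr


@dataclass(frozen=True)
class SignedEdge:
    """A signed regulatory edge derived from rule polarity.

    ``sign`` is ``activatory`` when the source occurs only at even negation
    depth in the target's rule, ``inhibitory`` when only at odd depth, and
    ``ambiguous`` when at both.  ``self_loop`` flags identity-rule inputs.
    """

    source: str
    target: str
    sign: str  # activatory | inhibitory | ambiguous
    self_loop: bool = False


@dataclass(frozen=True)
class BooleanNetwork:
    """An ordered rule set with a designated phenotypic read-out node."""

    rules: tuple[NodeRule, ...]
    inputs: frozenset[str] = frozenset()
    phenotype_node: str | None = None

    def __post_init__(self):
        seen = set()
        for r in self.rules:
            if r.target in seen:
                raise NetworkFormatError(f"duplicate rule target {r.target!r}")
            seen.add(r.target)
        if self.phenotype_node is not None and self.phenotype_node not in seen:
            raise NetworkFormatError(
                f"phenotype node {self.phenotype_node!r} has no rule")

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(r.target for r in self.rules)

    @property
    def n_nodes(self) -> int:
        return len(self.rules)

    def rule(self, node: str) -> NodeRule:
        for r in self.rules:
            if r.target == node:
                return r
        raise KeyError(f"no such node: {node!r}")

    def node_index(self, node: str) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            raise KeyError(f"no such node: {node!r}") from None

    def referenced_names(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.rules:
            out |= r.expression.variables()
        return frozenset(out)

    def undefined_names(self) -> frozenset[str]:
        return self.referenced_names() - set(self.nodes)

    def validate(self) -> None:
        """Raise if any rule references a name without a rule of its own."""
        missing = self.undefined_names()
        if missing:
            raise NetworkFormatError(
                "rules reference undefined nodes: " + ", ".join(sorted(missing)))

    # -- state packing ------------------------------------------------------

    def encode_state(self, values: dict[str, int] | Sequence[int]) -> int:
        """Pack node values into an integer state code (bit i = nodes[i])."""
        if isinstance(values, dict):
            bits = [int(bool(values[n])) for n in self.nodes]
        else:
            bits = [int(bool(v)) for v in values]
            if len(bits) != self.n_nodes:
                raise ValueError("wrong number of node values")
        code = 0
        for i, b in enumerate(bits):
            code |= b << i
        return code

    def decode_state(self, code: int) -> dict[str, int]:
        if not 0 <= code < (1 << self.n_nodes):
            raise ValueError(f"state code {code} out of range for {self.n_nodes} nodes")
        return {n: (code >> i) & 1 for i, n in enumerate(self.nodes)}

    def with_phenotype(self, node: str) -> "BooleanNetwork":
        if node not in self.nodes:
            raise KeyError(f"no such node: {node!r}")
        return replace(self, phenotype_node=node)


# ---------------------------------------------------------------------------
# Rule-file I/O

_HEADER = "targets, factors"


def parse_network(text: str, phenotype_node: str | None = None) -> BooleanNetwork:
    """Parse a rule file: one ``target, expression`` line per node.

    Blank lines and ``#`` comments are skipped, as is an optional
    ``targets, factors`` header.  Referenced-but-undefined names are left
    unresolved; run :func:`complete_inputs` to turn them into identity-rule
    inputs.  Duplicate targets and malformed lines raise
    :class:`NetworkFormatError` with the offending line number.
    """
    rules: list[NodeRule] = []
    targets_seen: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if lineno == 1 or not rules:
            if line.lower().replace(" ", "") == _HEADER.replace(" ", ""):
                continue
        if "," not in line:
            raise NetworkFormatError(f"line {lineno}: missing comma in {line!r}")
        target, _, body = line.partition(",")
        target = target.strip()
        if not target:
            raise NetworkFormatError(f"line {lineno}: empty target")
        if target in targets_seen:
            raise NetworkFormatError(f"line {lineno}: duplicate target {target!r}")
        try:
            expression = parse_expression(body)
        except ExpressionError as exc:
            raise NetworkFormatError(f"line {lineno}: {exc}") from exc
        targets_seen.add(target)
        rules.append(NodeRule(target, expression))
    if not rules:
        raise NetworkFormatError("no rules found")
    inputs = frozenset(
        r.target for r in rules
        if isinstance(r.expression, Var) and r.expression.name == r.target)
    if phenotype_node is not None and phenotype_node not in targets_seen:
        raise NetworkFormatError(f"phenotype node {phenotype_node!r} has no rule")
    return BooleanNetwork(tuple(rules), inputs=inputs, phenotype_node=phenotype_node)


def complete_inputs(net: BooleanNetwork) -> BooleanNetwork:
    """Give every referenced-but-undefined name a self-sustaining identity rule.

    Appended in first-reference order (scanning rules top to bottom), so node
    order — hence bit positions — is deterministic.  Names that already have
    rules are untouched.
    """
    defined = set(net.nodes)
    missing: list[str] = []
    for r in net.rules:
        for name in sorted(r.expression.variables(),
                           key=lambda n: _first_occurrence(r.expression, n)):
            if name not in defined and name not in missing:
                missing.append(name)
    if not missing:
        return net
    new_rules = net.rules + tuple(NodeRule(n, Var(n)) for n in missing)
    return BooleanNetwork(
        new_rules,
        inputs=net.inputs | frozenset(missing),
        phenotype_node=net.phenotype_node,
    )


def _first_occurrence(expr: BoolExpr, name: str) -> int:
    # position of the variable in a left-to-right traversal, for stable order
    counter = [0]

    def walk(e) -> int | None:
        if isinstance(e, Var):
            counter[0] += 1
            return counter[0] if e.name == name else None
        if isinstance(e, Not):
            return walk(e.child)
        if isinstance(e, (And, Or)):
            for c in e.children:
                r = walk(c)
                if r is not None:
                    return r
        return None

    pos = walk(expr)
    return pos if pos is not None else 1 << 30


def write_network(net: BooleanNetwork) -> str:
    """Render a network back to rule-file text (header + one line per rule)."""
    buf = io.StringIO()
    buf.write(_HEADER + "\n")
    for r in net.rules:
        buf.write(f"{r.target}, {r.expression.render()}\n")
    return buf.getvalue()


def load_network(path, phenotype_node: str | None = None) -> BooleanNetwork:
    with open(path) as fh:
        return parse_network(fh.read(), phenotype_node=phenotype_node)


def save_network(net: BooleanNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_network(net))


# ---------------------------------------------------------------------------
# Signed interaction graph

def _polarities(expr: BoolExpr, parity: int = 0, out=None) -> dict[str, set[int]]:
    """Map variable name -> set of negation parities (0 even, 1 odd)."""
    if out is None:
        out = {}
    if isinstance(expr, Var):
        out.setdefault(expr.name, set()).add(parity)
    elif isinstance(expr, Not):
        _polarities(expr.child, parity ^ 1, out)
    elif isinstance(expr, (And, Or)):
        for c in expr.children:
            _polarities(c, parity, out)
    return out


def interaction_graph(net: BooleanNetwork) -> list[SignedEdge]:
    """One signed edge per (source, target) pair where source regulates target.

    Sign follows negation parity in the target's rule: even depth only →
    activatory, odd only → inhibitory, both → ambiguous.  Identity-rule
    self-loops are included but flagged.
    """
    edges: list[SignedEdge] = []
    for r in net.rules:
        for source, parities in _polarities(r.expression).items():
            if parities == {0}:
                sign = "activatory"
            elif parities == {1}:
                sign = "inhibitory"
            else:
                sign = "ambiguous"
            edges.append(SignedEdge(source, r.target, sign,
                                    self_loop=(source == r.target)))
    return edges


def remove_sink_nodes(net: BooleanNetwork,
                      keep: Iterable[str] = ()) -> BooleanNetwork:
    """Iteratively delete nodes with no outgoing edges (self-loops excluded).

    Mirrors the model-construction step of pruning leaves that regulate
    nothing downstream.  Nodes in ``keep`` and the phenotype node survive.
    Remaining rules are unchanged, so deletion is only legal for true sinks.
    """
    keep = set(keep)
    if net.phenotype_node is not None:
        keep.add(net.phenotype_node)
    unknown = keep - set(net.nodes)
    if unknown:
        raise KeyError("keep contains unknown nodes: " + ", ".join(sorted(unknown)))
    rules = list(net.rules)
    while True:
        targets_of = {r.target: r.expression.variables() for r in rules}
        with_out = set()
        for tgt, sources in targets_of.items():
            for s in sources:
                if s != tgt:
                    with_out.add(s)
        sinks = [r.target for r in rules
                 if r.target not in with_out and r.target not in keep]
        if not sinks:
            break
        doomed = set(sinks)
        rules = [r for r in rules if r.target not in doomed]
        if not rules:
            raise NetworkFormatError("sink removal deleted every node")
    return BooleanNetwork(
        tuple(rules),
        inputs=net.inputs & {r.target for r in rules},
        phenotype_node=net.phenotype_node,
    )


# ---------------------------------------------------------------------------
# Exports

def edges_to_dataframe(edges: list[SignedEdge]):
    import pandas as pd

    return pd.DataFrame(
        [(e.source, e.target, e.sign, e.self_loop) for e in edges],
        columns=["source", "target", "sign", "self_loop"],
    )


def edges_to_graph(edges: list[SignedEdge]):
    """Signed digraph as a networkx DiGraph (for GraphML export etc.)."""
    import networkx as nx

    g = nx.DiGraph()
    for e in edges:
        g.add_edge(e.source, e.target, sign=e.sign, self_loop=e.self_loop)
    return g
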
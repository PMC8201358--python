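"""Random Boolean networks in the study model's structural class, plus a
naive attractor oracle.

The generator emulates sparse signaling logic: a handful of self-sustaining
input nodes, AND/OR/NOT rules of bounded fan-in over uniformly chosen
regulators, and one designated phenotypic sink node that reads the network
out but regulates nothing.  Defaults mirror the bundled neurite model's
shape: 24 nodes, 8 inputs, fan-in ≤ 6, and an activation bias of 0.65 (the
fraction of un-negated regulator occurrences in its printed rules).

:func:`brute_force_attractors` is a deliberately naive per-state simulator
used as an independent oracle against the fast transition-map search; it
shares no code with it.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .attractors import Attractor, AttractorSet
from .expr import And, BoolExpr, Not, Or, Var
from .model import BooleanNetwork, NodeRule, parse_network, write_network

__all__ = [
    "GeneratorSpec",
    "generate_network",
    "brute_force_attractors",
]

ORACLE_LIMIT = 12


@dataclass(frozen=True)
class GeneratorSpec:
    n_nodes: int = 24
    n_inputs: int = 8
    max_fan_in: int = 6
    activation_bias: float = 0.65  # probability a regulator enters un-negated
    expression_shape: str = "random_tree"  # or "random_truth_table"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.n_inputs < self.n_nodes:
            raise ValueError("need 0 < n_inputs < n_nodes")
        if self.max_fan_in < 1:
            raise ValueError("max_fan_in must be >= 1")
        if not 0.0 <= self.activation_bias <= 1.0:
            raise ValueError("activation_bias must lie in [0, 1]")
        if self.expression_shape not in {"random_tree", "random_truth_table"}:
            raise ValueError(f"unknown expression_shape {self.expression_shape!r}")


def _random_tree(rng: random.Random, literals: list[BoolExpr]) -> BoolExpr:
    """Combine the literals into a random AND/OR tree (each used once)."""
    nodes = list(literals)
    rng.shuffle(nodes)
    while len(nodes) > 1:
        k = rng.randint(2, min(3, len(nodes)))
        children = tuple(nodes[:k])
        op = And if rng.random() < 0.5 else Or
        nodes = [op(children)] + nodes[k:]
    return nodes[0]


def _truth_table_dnf(rng: random.Random, parents: list[str]) -> BoolExpr:
    """Random truth table over the parents, rendered as a DNF expression so it
    flows through the one parser/renderer path like any other rule."""
    k = len(parents)
    rows = [bits for bits in range(1 << k) if rng.random() < 0.5]
    if not rows:  # avoid the constant-0 rule: keep at least one ON row
        rows = [rng.randrange(1 << k)]
    if len(rows) == 1 << k:  # constant-1: drop one row to keep dependence
        rows.pop(rng.randrange(len(rows)))
    terms: list[BoolExpr] = []
    for bits in rows:
        lits = [Var(p) if (bits >> i) & 1 else Not(Var(p))
                for i, p in enumerate(parents)]
        terms.append(lits[0] if len(lits) == 1 else And(tuple(lits)))
    return terms[0] if len(terms) == 1 else Or(tuple(terms))


def generate_network(spec: GeneratorSpec) -> BooleanNetwork:
    """Reproducible random network; the same spec yields identical rule text.

    The last node is the phenotypic sink: it is fed by ≥1 regulator and never
    regulates anything.  The result is round-tripped through the rule-file
    parser so every parser invariant holds by construction.
    """
    rng = random.Random(spec.seed)
    names = [f"g{i:02d}" for i in range(spec.n_nodes - 1)] + ["phenotype"]
    input_names = rng.sample(names[:-1], spec.n_inputs)
    inputs = set(input_names)
    regulator_pool = [n for n in names if n != "phenotype"]
    rules: list[NodeRule] = []
    for name in names:
        if name in inputs:
            rules.append(NodeRule(name, Var(name)))
            continue
        pool = [p for p in regulator_pool if p != name]
        fan_in = rng.randint(1, min(spec.max_fan_in, len(pool)))
        parents = rng.sample(pool, fan_in)
        if spec.expression_shape == "random_truth_table":
            expr = _truth_table_dnf(rng, parents)
        else:
            literals: list[BoolExpr] = [
                Var(p) if rng.random() < spec.activation_bias else Not(Var(p))
                for p in parents]
            expr = literals[0] if len(literals) == 1 else _random_tree(rng, literals)
        rules.append(NodeRule(name, expr))
    net = BooleanNetwork(tuple(rules), inputs=frozenset(inputs),
                         phenotype_node="phenotype")
    # emit and re-parse so generated models obey all rule-file invariants
    reparsed = parse_network(write_network(net), phenotype_node="phenotype")
    reparsed.validate()
    return reparsed


# ---------------------------------------------------------------------------
# Independent oracle

def brute_force_attractors(net: BooleanNetwork,
                           limit: int = ORACLE_LIMIT) -> AttractorSet:
    """Naive per-state trajectory simulation with explicit visited-set
    bookkeeping.  Same output contract as the fast exhaustive search, but no
    transition table, no vectorisation, no pointer doubling.
    """
    net.validate()
    n = net.n_nodes
    if n > limit:
        raise ValueError(f"{n} nodes exceeds the oracle limit of {limit}")
    nodes = net.nodes
    exprs = [r.expression for r in net.rules]

    def nxt(state: int) -> int:
        env = {name: (state >> i) & 1 for i, name in enumerate(nodes)}
        out = 0
        for i, e in enumerate(exprs):
            if e.evaluate(env):
                out |= 1 << i
        return out

    attractor_of: dict[int, int] = {}  # state -> attractor id
    cycles: list[tuple[int, ...]] = []
    basin: list[int] = []
    for s0 in range(1 << n):
        path: list[int] = []
        pos: dict[int, int] = {}
        s = s0
        while s not in attractor_of and s not in pos:
            pos[s] = len(path)
            path.append(s)
            s = nxt(s)
        if s in attractor_of:
            aid = attractor_of[s]
        else:
            cyc = path[pos[s]:]
            aid = len(cycles)
            cycles.append(Attractor.canonical(cyc))
            basin.append(0)
        for visited in path:
            attractor_of[visited] = aid
        basin[aid] += len(path)
    attractors = sorted(
        (Attractor(states=c, basin_size=basin[i]) for i, c in enumerate(cycles)),
        key=lambda a: a.states[0])
    return AttractorSet(tuple(attractors), n_nodes=n,
                        search_mode="exhaustive", n_starts=1 << n)
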
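"""Synchronous and asynchronous update semantics over packed integer states.

A state of an N-node network is an integer code below ``2**N``; bit *i*
carries the value of node *i* in the network's node order.  The synchronous
step recomputes every node from the current state simultaneously, so the
dynamics is a deterministic function on the state space and every trajectory
ends in a cycle (an attractor).  The asynchronous step updates one node at a
time, which is provided for completeness; all quantitative results in this
package use the synchronous semantics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import BooleanNetwork

__all__ = [
    "Trajectory",
    "evaluate",
    "step_synchronous",
    "step_asynchronous",
    "async_trajectory",
    "build_transition_map",
    "simulate",
    "trajectory_to_dataframe",
]

#: Networks above this size refuse full transition-map construction.
TRANSITION_MAP_LIMIT = 26


@dataclass(frozen=True)
class Trajectory:
    """A synchronous run: the visited states and why it stopped.

    When ``terminated_by == "revisit"``, ``states[-1] == states[revisit_index]``
    and the terminal cycle is ``states[revisit_index:-1]``.
    """

    states: tuple[int, ...]
    terminated_by: str  # "revisit" | "max_steps"
    revisit_index: int | None = None

    @property
    def cycle(self) -> tuple[int, ...]:
        if self.terminated_by != "revisit":
            raise ValueError("trajectory did not close on a revisit")
        return self.states[self.revisit_index:-1]


def evaluate(expr, net: BooleanNetwork, state: int) -> int:
    """Evaluate an expression under the node values packed in ``state``."""
    return int(bool(expr.evaluate(net.decode_state(state))))


def step_synchronous(net: BooleanNetwork, state: int) -> int:
    """All nodes recompute simultaneously from the current state."""
    env = net.decode_state(state)
    nxt = 0
    for i, rule in enumerate(net.rules):
        if rule.expression.evaluate(env):
            nxt |= 1 << i
    return nxt


def step_asynchronous(net: BooleanNetwork, state: int, node: str) -> int:
    """Update only the named node; every other bit is carried over."""
    i = net.node_index(node)
    env = net.decode_state(state)
    bit = 1 if net.rules[i].expression.evaluate(env) else 0
    return (state & ~(1 << i)) | (bit << i)


def async_trajectory(net: BooleanNetwork, state: int, n_steps: int,
                     seed: int | None = None) -> list[int]:
    """Random-scheduler asynchronous run: each step updates one node chosen
    uniformly at random from a seeded generator."""
    rng = np.random.default_rng(seed)
    nodes = net.nodes
    out = [state]
    for _ in range(n_steps):
        state = step_asynchronous(net, state, nodes[int(rng.integers(len(nodes)))])
        out.append(state)
    return out


def build_transition_map(net: BooleanNetwork,
                         limit: int = TRANSITION_MAP_LIMIT) -> np.ndarray:
    """Synchronous successor of every state, as a ``uint32`` array of length 2^N.

    Built node-by-node with bulk bitwise evaluation over the whole state
    space (one vectorised pass per rule), not by per-state recursion.
    """
    net.validate()
    n = net.n_nodes
    if n > limit:
        raise ValueError(
            f"{n} nodes exceeds the transition-map limit of {limit}; "
            "use sampled attractor search instead")
    codes = np.arange(1 << n, dtype=np.uint32)
    env = {name: ((codes >> np.uint32(i)) & np.uint32(1)).astype(bool)
           for i, name in enumerate(net.nodes)}
    succ = np.zeros(1 << n, dtype=np.uint32)
    for i, rule in enumerate(net.rules):
        val = rule.expression.evaluate(env)
        if isinstance(val, (bool, np.bool_)):  # constant rule
            val = np.full(1 << n, bool(val))
        succ |= val.astype(np.uint32) << np.uint32(i)
    return succ


def simulate(net: BooleanNetwork, initial: int,
             max_steps: int | None = None) -> Trajectory:
    """Run the synchronous dynamics until the first revisited state.

    ``max_steps`` defaults to ``2**min(N, 20)`` — a guardrail only, since a
    revisit is guaranteed within 2^N steps.
    """
    if max_steps is None:
        max_steps = 1 << min(net.n_nodes, 20)
    seen: dict[int, int] = {}
    states = [initial]
    state = initial
    for _ in range(max_steps):
        seen[state] = len(states) - 1
        state = step_synchronous(net, state)
        states.append(state)
        if state in seen:
            return Trajectory(tuple(states), "revisit", revisit_index=seen[state])
    return Trajectory(tuple(states), "max_steps")


def trajectory_to_dataframe(net: BooleanNetwork, traj: Trajectory):
    """One row per step, one 0/1 column per node (CSV-ready)."""
    import pandas as pd

    rows = [net.decode_state(s) for s in traj.states]
    df = pd.DataFrame(rows, columns=list(net.nodes))
    df.insert(0, "step", range(len(rows)))
    return df
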
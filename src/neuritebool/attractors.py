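"""Attractor identification for the synchronous dynamics.

The synchronous update is a function on ``{0,1}^N``; its functional graph
consists of trees hanging off disjoint cycles — the attractors.  The
exhaustive search builds the full successor table and finds every cycle and
exact basin sizes with pointer doubling: after ``N`` squarings of the
successor map, every state points at a state on its terminal cycle, so cycle
membership, attractor identity, and basins all fall out of vectorised
integer operations.

Attractors are canonicalised by rotating the cycle to start at its minimal
state code and are reported sorted by that code, so output order is
deterministic and comparable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import TRANSITION_MAP_LIMIT, build_transition_map, simulate
from .model import BooleanNetwork

__all__ = [
    "Attractor",
    "AttractorSet",
    "find_attractors_exhaustive",
    "find_attractors_sampled",
    "find_attractors_by_input_blocks",
    "phenotype_active_fraction",
    "basin_weighted_active_fraction",
    "attractor_profile",
    "attractors_to_dataframe",
    "attractor_summary",
]


@dataclass(frozen=True)
class Attractor:
    """A cycle of the synchronous dynamics (length 1 = fixed point).

    ``basin_size`` counts every state whose trajectory ends in this cycle,
    attractor states included; in sampled mode it is instead the number of
    random starts that reached the cycle.
    """

    states: tuple[int, ...]
    basin_size: int

    @property
    def length(self) -> int:
        return len(self.states)

    @property
    def kind(self) -> str:
        return "fixed_point" if self.length == 1 else "cyclic"

    @staticmethod
    def canonical(states) -> tuple[int, ...]:
        """Rotate the cycle so it starts at the minimal state code."""
        states = list(states)
        k = states.index(min(states))
        return tuple(states[k:] + states[:k])


@dataclass(frozen=True)
class AttractorSet:
    attractors: tuple[Attractor, ...]
    n_nodes: int
    search_mode: str  # "exhaustive" | "sampled"
    n_starts: int

    def __len__(self):
        return len(self.attractors)

    @property
    def n_attractors(self) -> int:
        return len(self.attractors)

    def cycle_length_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for a in self.attractors:
            hist[a.length] = hist.get(a.length, 0) + 1
        return dict(sorted(hist.items()))


def _collect_cycles(succ: np.ndarray, ptr: np.ndarray):
    """From the successor table and the cycle-pointer array, enumerate every
    cycle exactly once and label cycle states with attractor ids."""
    reps = np.unique(ptr)  # all on cycles; ≥1 representative per cycle
    label = np.full(succ.shape[0], -1, dtype=np.int64)
    cycles: list[tuple[int, ...]] = []
    for r in reps:
        r = int(r)
        if label[r] >= 0:
            continue
        cyc = [r]
        s = int(succ[r])
        while s != r:
            cyc.append(s)
            s = int(succ[s])
        aid = len(cycles)
        for c in cyc:
            label[c] = aid
        cycles.append(Attractor.canonical(cyc))
    return cycles, label


def find_attractors_exhaustive(net: BooleanNetwork,
                               limit: int = TRANSITION_MAP_LIMIT) -> AttractorSet:
    """Every cycle of the successor function, with exact basin sizes.

    Covers all 2^N initial conditions; Σ basin sizes = 2^N by construction.
    """
    succ = build_transition_map(net, limit=limit)
    n = net.n_nodes
    ptr = succ.copy()
    for _ in range(n):  # succ^(2^n): beyond any transient, lands on the cycle
        ptr = ptr[ptr]
    cycles, label = _collect_cycles(succ, ptr)
    basin = np.bincount(label[ptr], minlength=len(cycles))
    attractors = [Attractor(states=c, basin_size=int(basin[i]))
                  for i, c in enumerate(cycles)]
    attractors.sort(key=lambda a: a.states[0])
    return AttractorSet(tuple(attractors), n_nodes=n,
                        search_mode="exhaustive", n_starts=1 << n)


def find_attractors_sampled(net: BooleanNetwork, n_starts: int,
                            seed: int | None = None) -> AttractorSet:
    """Attractors reached from ``n_starts`` seeded random initial states.

    A lower bound on the true attractor set; ``basin_size`` holds reach
    counts, not basin sizes.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    net.validate()
    rng = np.random.default_rng(seed)
    n = net.n_nodes
    starts = rng.integers(0, 1 << n, size=n_starts, dtype=np.uint64)
    found: dict[tuple[int, ...], int] = {}
    state_to_cycle: dict[int, tuple[int, ...]] = {}
    for s0 in starts:
        s0 = int(s0)
        traj = simulate(net, s0, max_steps=1 << min(n, 22))
        cyc = state_to_cycle.get(traj.states[-1])
        if cyc is None:
            cyc = Attractor.canonical(traj.cycle)
            for s in cyc:
                state_to_cycle[s] = cyc
        found[cyc] = found.get(cyc, 0) + 1
    attractors = sorted(
        (Attractor(states=c, basin_size=k) for c, k in found.items()),
        key=lambda a: a.states[0])
    return AttractorSet(tuple(attractors), n_nodes=n,
                        search_mode="sampled", n_starts=n_starts)


def find_attractors_by_input_blocks(net: BooleanNetwork) -> AttractorSet:
    """Exhaustive search via the closed-subspace decomposition over inputs.

    Identity-rule inputs are frozen along every trajectory, so the state
    space splits into ``2^(#inputs)`` closed blocks; searching each block
    independently and pooling the cycles must agree with the direct search.
    Serves as an independent cross-check of :func:`find_attractors_exhaustive`
    and as a lower-memory fallback for larger networks.
    """
    net.validate()
    inputs = sorted(net.inputs, key=net.node_index)
    free_idx = [i for i, n in enumerate(net.nodes) if n not in net.inputs]
    in_idx = [net.node_index(n) for n in inputs]
    n_free = len(free_idx)
    n = net.n_nodes
    all_attractors: list[Attractor] = []
    codes_free = np.arange(1 << n_free, dtype=np.uint64)
    for block in range(1 << len(inputs)):
        base = 0
        for j, bi in enumerate(in_idx):
            base |= ((block >> j) & 1) << bi
        # embed the free-bit counter into full state codes for this block
        full = np.full(1 << n_free, base, dtype=np.uint64)
        for k, fi in enumerate(free_idx):
            full |= ((codes_free >> np.uint64(k)) & np.uint64(1)) << np.uint64(fi)
        env = {name: ((full >> np.uint64(i)) & np.uint64(1)).astype(bool)
               for i, name in enumerate(net.nodes)}
        succ_free = np.zeros(1 << n_free, dtype=np.uint32)
        for k, fi in enumerate(free_idx):
            val = net.rules[fi].expression.evaluate(env)
            if isinstance(val, (bool, np.bool_)):
                val = np.full(1 << n_free, bool(val))
            succ_free |= val.astype(np.uint32) << np.uint32(k)
        ptr = succ_free.copy()
        for _ in range(max(n_free, 1)):
            ptr = ptr[ptr]
        cycles, label = _collect_cycles(succ_free, ptr)
        basin = np.bincount(label[ptr], minlength=len(cycles))
        for i, cyc in enumerate(cycles):
            states_full = []
            for sc in cyc:
                code = base
                for k, fi in enumerate(free_idx):
                    code |= ((sc >> k) & 1) << fi
                states_full.append(code)
            all_attractors.append(
                Attractor(states=Attractor.canonical(states_full),
                          basin_size=int(basin[i])))
    all_attractors.sort(key=lambda a: a.states[0])
    return AttractorSet(tuple(all_attractors), n_nodes=n,
                        search_mode="exhaustive", n_starts=1 << n)


# ---------------------------------------------------------------------------
# Phenotype summaries

def _active_mask(aset: AttractorSet, bit: int, mode: str) -> list[bool]:
    if mode == "all_states":
        return [all((s >> bit) & 1 for s in a.states) for a in aset.attractors]
    if mode == "any_state":
        return [any((s >> bit) & 1 for s in a.states) for a in aset.attractors]
    raise ValueError(f"unknown activity mode {mode!r}")


def phenotype_active_fraction(aset: AttractorSet, net: BooleanNetwork,
                              node: str | None = None,
                              mode: str = "all_states") -> float:
    """Fraction of attractors in which the phenotype node is active.

    ``all_states`` (default) calls an attractor active only if the node is ON
    in every state of the cycle — a node oscillating ON/OFF is conservatively
    inactive.  ``any_state`` requires one ON state.  Unweighted by basin size.
    """
    node = node or net.phenotype_node
    if node is None:
        raise ValueError("no phenotype node given")
    bit = net.node_index(node)
    if not aset.attractors:
        return 0.0
    mask = _active_mask(aset, bit, mode)
    return sum(mask) / len(mask)


def basin_weighted_active_fraction(aset: AttractorSet, net: BooleanNetwork,
                                   node: str | None = None,
                                   mode: str = "all_states") -> float:
    """Like :func:`phenotype_active_fraction` but weighting each attractor by
    its basin size (fraction of state space ending phenotype-active)."""
    node = node or net.phenotype_node
    if node is None:
        raise ValueError("no phenotype node given")
    bit = net.node_index(node)
    total = sum(a.basin_size for a in aset.attractors)
    if total == 0:
        return 0.0
    mask = _active_mask(aset, bit, mode)
    return sum(a.basin_size for a, m in zip(aset.attractors, mask) if m) / total


def attractor_profile(aset: AttractorSet, net: BooleanNetwork, index: int):
    """Node-by-state 0/1 activity matrix of one attractor (heat-map ready).

    Rows are nodes in network order; columns the cycle states in order.
    """
    import pandas as pd

    if not 0 <= index < len(aset.attractors):
        raise IndexError(f"attractor index {index} out of range")
    a = aset.attractors[index]
    data = {f"state_{j}": [(s >> i) & 1 for i in range(net.n_nodes)]
            for j, s in enumerate(a.states)}
    return pd.DataFrame(data, index=list(net.nodes))


def attractors_to_dataframe(aset: AttractorSet, net: BooleanNetwork):
    """Long-format table: attractor_id, cycle_position, state_code, basin_size,
    then one 0/1 column per node."""
    import pandas as pd

    rows = []
    for aid, a in enumerate(aset.attractors):
        for pos, s in enumerate(a.states):
            row = {"attractor_id": aid, "cycle_position": pos,
                   "state_code": s, "length": a.length,
                   "basin_size": a.basin_size}
            row.update(net.decode_state(s))
            rows.append(row)
    return pd.DataFrame(rows)


def attractor_summary(aset: AttractorSet, net: BooleanNetwork,
                      mode: str = "all_states") -> dict:
    """JSON-ready summary: counts, cycle-length histogram, phenotype fractions."""
    out = {
        "n_nodes": aset.n_nodes,
        "search_mode": aset.search_mode,
        "n_starts": aset.n_starts,
        "n_attractors": aset.n_attractors,
        "n_fixed_points": sum(a.kind == "fixed_point" for a in aset.attractors),
        "cycle_length_histogram": {str(k): v for k, v in
                                   aset.cycle_length_histogram().items()},
        "basin_size_total": sum(a.basin_size for a in aset.attractors),
    }
    if net.phenotype_node is not None:
        out["phenotype_node"] = net.phenotype_node
        out["activity_mode"] = mode
        out["phenotype_active_fraction"] = phenotype_active_fraction(
            aset, net, mode=mode)
        out["phenotype_active_fraction_any_state"] = phenotype_active_fraction(
            aset, net, mode="any_state")
        out["basin_weighted_active_fraction"] = basin_weighted_active_fraction(
            aset, net, mode=mode)
    return out
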
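"""In silico knockout / overexpression screening and concordance scoring.

A knockout clamps a node's rule to the constant 0 for the whole simulation
(constitutive activation clamps to 1); the perturbed network is re-analysed
by exhaustive attractor search and the activity of the phenotypic node is
compared with the wild-type baseline.  Knockdowns and dominant negatives are
approximated as knockouts — a two-state logic admits no partial loss of
function — and haploinsufficiency has no Boolean analog, so such expectations
are scored as indeterminate rather than silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from .attractors import (
    AttractorSet,
    basin_weighted_active_fraction,
    find_attractors_exhaustive,
    phenotype_active_fraction,
)
from .expr import Const
from .model import BooleanNetwork, NodeRule

__all__ = [
    "Perturbation",
    "PhenotypeExpectation",
    "MutagenesisResult",
    "apply_perturbation",
    "run_screen",
    "score_concordance",
    "score_direction",
    "screen_to_dataframe",
    "screen_summary",
]

#: Perturbation kinds that have an in silico clamp analog.
CLAMPABLE_KINDS = frozenset({"KO", "KD", "dominant_negative"})


@dataclass(frozen=True)
class Perturbation:
    node: str
    clamp: int = 0  # 0 = knockout, 1 = constitutive activation

    def __post_init__(self):
        if self.clamp not in (0, 1):
            raise ValueError("clamp must be 0 or 1")


@dataclass(frozen=True)
class PhenotypeExpectation:
    """Qualitative direction of an experimental perturbation phenotype."""

    node: str  # model node, or "" when unmappable
    perturbation_kind: str  # KO | KD | dominant_negative | haploinsufficiency
    expected_direction: str  # decrease | increase | no_effect
    source_label: str = ""

    def __post_init__(self):
        if self.expected_direction not in {"decrease", "increase", "no_effect"}:
            raise ValueError(
                f"unknown expected_direction {self.expected_direction!r}")
        if self.perturbation_kind not in CLAMPABLE_KINDS | {"haploinsufficiency"}:
            raise ValueError(
                f"unknown perturbation_kind {self.perturbation_kind!r}")

    @property
    def mappable(self) -> bool:
        return bool(self.node) and self.perturbation_kind in CLAMPABLE_KINDS


@dataclass(frozen=True)
class MutagenesisResult:
    perturbation: Perturbation | None  # None = wild-type baseline row
    n_attractors: int
    active_fraction: float
    wt_active_fraction: float
    basin_weighted_fraction: float = float("nan")
    # same quantities under the alternative activity convention, so either
    # reading of attractor-level activity can be checked without re-searching
    alt_active_fraction: float = float("nan")
    wt_alt_active_fraction: float = float("nan")
    concordance: str | None = None  # concordant | discordant | indeterminate

    @property
    def delta(self) -> float:
        return self.active_fraction - self.wt_active_fraction

    @property
    def alt_delta(self) -> float:
        return self.alt_active_fraction - self.wt_alt_active_fraction


def apply_perturbation(net: BooleanNetwork, p: Perturbation) -> BooleanNetwork:
    """Replace the node's rule by the constant clamp; node order is unchanged."""
    i = net.node_index(p.node)
    if p.node == net.phenotype_node:
        warnings.warn("perturbing the phenotype node itself; the screen "
                      "read-out is then trivially the clamp value",
                      stacklevel=2)
    rules = list(net.rules)
    rules[i] = NodeRule(p.node, Const(bool(p.clamp)))
    return BooleanNetwork(tuple(rules),
                          inputs=net.inputs - {p.node},
                          phenotype_node=net.phenotype_node)


def score_direction(delta: float, expected_direction: str,
                    tol: float = 0.0) -> str:
    """Qualitative agreement of an in silico effect with an expectation.

    ``decrease`` is concordant iff delta < -tol, ``increase`` iff
    delta > +tol, ``no_effect`` iff |delta| <= tol.
    """
    if expected_direction == "decrease":
        return "concordant" if delta < -tol else "discordant"
    if expected_direction == "increase":
        return "concordant" if delta > tol else "discordant"
    if expected_direction == "no_effect":
        return "concordant" if abs(delta) <= tol else "discordant"
    raise ValueError(f"unknown expected_direction {expected_direction!r}")


def score_concordance(result: MutagenesisResult,
                      expectation: PhenotypeExpectation,
                      tol: float = 0.0) -> str:
    """Score a screen row against an expectation for the same node.

    Expectations without a clampable analog (haploinsufficiency) or without a
    model node are indeterminate.
    """
    if result.perturbation is None or result.perturbation.node != expectation.node:
        raise ValueError("result and expectation refer to different nodes")
    if not expectation.mappable:
        return "indeterminate"
    return score_direction(result.delta, expectation.expected_direction, tol)


def run_screen(net: BooleanNetwork,
               perturbations: list[Perturbation] | None = None,
               phenotype_node: str | None = None,
               mode: str = "all_states",
               wt_set: AttractorSet | None = None,
               ) -> tuple[MutagenesisResult, list[MutagenesisResult]]:
    """Exhaustive attractor analysis of WT and each perturbed network.

    Returns ``(wt_result, results)`` with results in input order.  Default
    perturbation list: knockout of every node except the phenotype node.
    Entirely deterministic (integer-only exhaustive search).
    """
    if phenotype_node is not None:
        net = net.with_phenotype(phenotype_node)
    if net.phenotype_node is None:
        raise ValueError("screen needs a phenotype node")
    if perturbations is None:
        perturbations = [Perturbation(n, 0) for n in net.nodes
                         if n != net.phenotype_node]
    alt_mode = "any_state" if mode == "all_states" else "all_states"
    if wt_set is None:
        wt_set = find_attractors_exhaustive(net)
    wt_fraction = phenotype_active_fraction(wt_set, net, mode=mode)
    wt_alt = phenotype_active_fraction(wt_set, net, mode=alt_mode)
    wt = MutagenesisResult(
        perturbation=None,
        n_attractors=wt_set.n_attractors,
        active_fraction=wt_fraction,
        wt_active_fraction=wt_fraction,
        basin_weighted_fraction=basin_weighted_active_fraction(wt_set, net,
                                                               mode=mode),
        alt_active_fraction=wt_alt,
        wt_alt_active_fraction=wt_alt,
    )
    results = []
    for p in perturbations:
        pnet = apply_perturbation(net, p)
        aset = find_attractors_exhaustive(pnet)
        results.append(MutagenesisResult(
            perturbation=p,
            n_attractors=aset.n_attractors,
            active_fraction=phenotype_active_fraction(aset, pnet, mode=mode),
            wt_active_fraction=wt_fraction,
            basin_weighted_fraction=basin_weighted_active_fraction(
                aset, pnet, mode=mode),
            alt_active_fraction=phenotype_active_fraction(aset, pnet,
                                                          mode=alt_mode),
            wt_alt_active_fraction=wt_alt,
        ))
    return wt, results


def screen_to_dataframe(wt: MutagenesisResult,
                        results: list[MutagenesisResult]):
    """Machine-readable screen table: WT row first, then one row per clamp."""
    import pandas as pd

    rows = [{
        "node": "WT", "clamp": "",
        "n_attractors": wt.n_attractors,
        "active_fraction": wt.active_fraction,
        "basin_weighted_fraction": wt.basin_weighted_fraction,
        "delta": 0.0, "concordance": "",
    }]
    for r in results:
        rows.append({
            "node": r.perturbation.node,
            "clamp": r.perturbation.clamp,
            "n_attractors": r.n_attractors,
            "active_fraction": r.active_fraction,
            "basin_weighted_fraction": r.basin_weighted_fraction,
            "delta": r.delta,
            "concordance": r.concordance or "",
        })
    return pd.DataFrame(rows)


def screen_summary(results: list[MutagenesisResult]) -> dict:
    tally = {"concordant": 0, "discordant": 0, "indeterminate": 0, "unscored": 0}
    for r in results:
        tally[r.concordance or "unscored"] += 1
    return tally


def with_concordance(result: MutagenesisResult, call: str) -> MutagenesisResult:
    return replace(result, concordance=call)
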
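"""The bundled neurite-elongation model and its one-call analysis.

The model couples the Rho GTPases (RAC1, RHOA, CDC42) to actin dynamics
through their GEFs/GAPs and the cofilin phosphocycle (PAK1/LIMK/SSH1), with
an abstract ``neuro_elo`` node reading out F-actin assembly as the neurite
elongation phenotype.  Eight constitutively present regulators (profilin,
formin, tiam1, arhgef6, arhgef7, trio, noma_gap, ophn1) are boundary-condition
inputs.  :func:`reproduce_analysis` runs the exhaustive synchronous attractor
search, the phenotype summary, and the full single-knockout screen scored
against the experimental phenotype catalog.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

from .attractors import (
    AttractorSet,
    attractor_summary,
    find_attractors_exhaustive,
    phenotype_active_fraction,
)
from .model import BooleanNetwork, complete_inputs, parse_network
from .mutagenesis import (
    MutagenesisResult,
    Perturbation,
    PhenotypeExpectation,
    run_screen,
    score_concordance,
    score_direction,
    with_concordance,
)

__all__ = [
    "AnalysisReport",
    "CatalogEntry",
    "load_neurite_model",
    "load_phenotype_catalog",
    "default_conventions",
    "reproduce_analysis",
]

PHENOTYPE_NODE = "neuro_elo"

_DATA = importlib.resources.files("neuritebool") / "data"


@dataclass(frozen=True)
class CatalogEntry:
    """One experimental-phenotype row with its model-node mapping."""

    protein: str
    expectation: PhenotypeExpectation
    phenotype_text: str
    reference: str

    @property
    def mappable(self) -> bool:
        return self.expectation.mappable


@dataclass
class AnalysisReport:
    """Bundle of the wild-type analysis, the knockout screen, and the exact
    conventions that determine every number in it."""

    conventions: dict
    wt_summary: dict
    wt_result: MutagenesisResult
    screen: list[MutagenesisResult]
    catalog_calls: list[dict]
    deviations: list[dict] = field(default_factory=list)

    def summary(self) -> dict:
        tally = {"concordant": 0, "discordant": 0, "indeterminate": 0}
        for c in self.catalog_calls:
            tally[c["concordance"]] += 1
        return {
            "conventions": self.conventions,
            "wt": self.wt_summary,
            "concordance_tally": tally,
            "n_deviations": len(self.deviations),
        }


def load_neurite_model(completed: bool = True) -> BooleanNetwork:
    """The bundled 16-rule model; with ``completed`` (default) the 8
    unregulated factors receive identity rules, giving 24 nodes."""
    text = (_DATA / "neurite_elongation.bnet").read_text()
    net = parse_network(text, phenotype_node=PHENOTYPE_NODE)
    return complete_inputs(net) if completed else net


def load_phenotype_catalog(path=None) -> list[CatalogEntry]:
    """The experimental KO/KD phenotype catalog (editable CSV).

    Rows without a surviving model node (PAK2, PAK3) or whose perturbation
    has no Boolean analog (haploinsufficiency) are kept and flagged, never
    dropped.
    """
    import pandas as pd

    if path is None:
        with importlib.resources.as_file(_DATA / "phenotype_catalog.csv") as p:
            df = pd.read_csv(p, keep_default_na=False)
    else:
        df = pd.read_csv(path, keep_default_na=False)
    entries = []
    for row in df.itertuples(index=False):
        entries.append(CatalogEntry(
            protein=row.protein,
            expectation=PhenotypeExpectation(
                node=row.model_node,
                perturbation_kind=row.perturbation_kind,
                expected_direction=row.expected_direction,
                source_label=row.reference,
            ),
            phenotype_text=row.phenotype_text,
            reference=row.reference,
        ))
    return entries


def default_conventions() -> dict:
    return yaml.safe_load((_DATA / "conventions.yaml").read_text())


def reproduce_analysis(conventions: dict | None = None,
                       wt_set: AttractorSet | None = None) -> AnalysisReport:
    """Wild-type attractor analysis plus the full single-knockout screen.

    Deterministic and integer-only: re-running from the recorded conventions
    reproduces the report bit for bit.  ``wt_set`` lets callers reuse a
    previously computed exhaustive wild-type search.
    """
    conv = default_conventions()
    if conventions:
        conv.update(conventions)
    mode = conv["activity_mode"]
    tol = float(conv["tol"])
    clamp = int(conv["clamp"])

    net = load_neurite_model()
    if wt_set is None:
        wt_set = find_attractors_exhaustive(net)
    wt_summary = attractor_summary(wt_set, net, mode=mode)

    # screen every node except the phenotype read-out
    perturbations = [Perturbation(n, clamp) for n in net.nodes
                     if n != net.phenotype_node]
    wt, results = run_screen(net, perturbations, mode=mode, wt_set=wt_set)
    by_node = {r.perturbation.node: r for r in results}

    catalog_calls: list[dict] = []
    deviations: list[dict] = []
    for entry in load_phenotype_catalog():
        exp = entry.expectation
        call_row = {
            "protein": entry.protein,
            "model_node": exp.node or None,
            "perturbation_kind": exp.perturbation_kind,
            "expected_direction": exp.expected_direction,
            "phenotype_text": entry.phenotype_text,
        }
        if not exp.mappable:
            call_row.update(concordance="indeterminate", delta=None,
                            reason="no clampable model analog")
            catalog_calls.append(call_row)
            continue
        result = by_node[exp.node]
        call = score_concordance(result, exp, tol=tol)
        # whether the alternative activity convention would agree, from the
        # alt-mode fractions run_screen computed on the same attractor sets
        alt_call = score_direction(result.alt_delta, exp.expected_direction, tol)
        call_row.update(
            concordance=call,
            delta=result.delta,
            n_attractors=result.n_attractors,
            active_fraction=result.active_fraction,
            concordant_under_alternative_mode=(alt_call == "concordant"),
        )
        catalog_calls.append(call_row)
        if call == "discordant" and alt_call != "concordant":
            deviations.append(dict(call_row))
        by_node[exp.node] = with_concordance(result, call)

    screen = [by_node[p.node] for p in perturbations]
    return AnalysisReport(
        conventions=conv,
        wt_summary=wt_summary,
        wt_result=wt,
        screen=screen,
        catalog_calls=catalog_calls,
        deviations=deviations,
    )
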
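"""In silico knockouts of selected GTPase-pathway nodes.

Clamps each chosen node to 0, re-runs the exhaustive attractor search, and
compares the phenotype-active attractor fraction with the wild type; the
signed change (delta) is then scored against the experimentally observed
direction from the bundled phenotype catalog.
"""

from neuritebool import (
    Perturbation,
    find_attractors_exhaustive,
    load_neurite_model,
    load_phenotype_catalog,
    run_screen,
    score_concordance,
    screen_to_dataframe,
)

net = load_neurite_model()
nodes = ["rhoa", "cdc42", "trio", "cfl"]
wt, results = run_screen(net, [Perturbation(n, 0) for n in nodes])

catalog = {e.expectation.node: e for e in load_phenotype_catalog() if e.mappable}
for r in results:
    e = catalog[r.perturbation.node]
    call = score_concordance(r, e.expectation)
    print(f"KO {r.perturbation.node:6s}: {r.n_attractors:4d} attractors, "
          f"active fraction {r.active_fraction:.3f} "
          f"(WT {r.wt_active_fraction:.3f}, delta {r.delta:+.3f}) "
          f"expected {e.expectation.expected_direction:8s} -> {call}")
# delta < 0 supports an experimentally decreased elongation, delta > 0 an
# increase; the full screen and deviation report come from reproduce_analysis().

print()
print(screen_to_dataframe(wt, results).to_string(index=False))
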
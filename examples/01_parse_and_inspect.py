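"""Load the bundled neurite-elongation model and inspect its structure.

Prints the rule set, the unregulated inputs that were completed with identity
rules, and the signed interaction graph derived from rule polarity (even
negation depth = activatory, odd = inhibitory).
"""

from neuritebool import (
    interaction_graph,
    load_neurite_model,
    write_network,
)

net = load_neurite_model()
print(write_network(net))
print(f"{net.n_nodes} nodes; phenotype node: {net.phenotype_node}")
print("inputs (constitutive regulators):", ", ".join(sorted(net.inputs)))

edges = [e for e in interaction_graph(net) if not e.self_loop]
n_act = sum(e.sign == "activatory" for e in edges)
n_inh = sum(e.sign == "inhibitory" for e in edges)
print(f"\n{len(edges)} regulatory edges: {n_act} activatory, {n_inh} inhibitory")
print("e.g. edges into cofilin (cfl):")
for e in edges:
    if e.target == "cfl":
        print(f"  {e.source:8s} -> cfl  [{e.sign}]")
# ssh1 dephosphorylates (activates) cofilin; the LIM kinases phosphorylate
# (inactivate) it — the signs recover that biology from the logic alone.
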
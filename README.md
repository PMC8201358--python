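# neuritebool

Boolean-network analysis of the Rho-GTPase signaling module that controls
neurite elongation, packaged as a reusable toolkit for logical models of
signaling networks.

## The problem and the model

Neurite outgrowth is driven by actin dynamics under the control of the small
GTPases RAC1, RHOA and CDC42, their activating GEFs (TRIO, TIAM1, ARHGEF6/7)
and inactivating GAPs (OPHN1, ARHGAP15, NOMA-GAP), and the cofilin
phosphocycle (PAK1 → LIMK1/2 ⊣ cofilin ⊣ F-actin, with SSH1 reactivating
cofilin). Mutations throughout this module cause intellectual-disability
phenotypes, which makes its systems-level behaviour worth modelling.

The module is encoded as a Boolean network: each protein is a node with
state 0/1 and an update rule built from AND (`&`), OR (`|`) and NOT (`!`)
over its regulators, written in the standard `targets, factors` rule-file
dialect, e.g.

```
cfl, ssh1 & !(limk2 | limk1)
rhoa, trio | !(ophn1 | tiam1)
```

An abstract read-out node `neuro_elo` (neurite elongation, driven by
F-actin) classifies the network's attractors by phenotype. Under the
synchronous update `x_i(t+1) = f_i(x(t))` the dynamics is a deterministic
map on {0,1}^N whose cycles — fixed points and limit cycles — are the
attractors, interpreted as stable cellular activity configurations. The
eight unregulated regulators are completed with identity rules `x, x`, so
each of the 2^8 boundary conditions is a closed subspace of the 24-node,
2^24-state model.

The toolkit provides:

- a parser/writer for the rule-file format with a typed expression AST
  (`neuritebool.model`, `neuritebool.expr`), signed-interaction-graph
  derivation from rule polarity, and sink-node simplification;
- synchronous/asynchronous dynamics over bit-packed integer states and a
  vectorised full transition map (`neuritebool.dynamics`);
- exhaustive attractor enumeration with exact basin sizes via pointer
  doubling on the successor table, sampled search, and an independent
  input-block decomposition cross-check (`neuritebool.attractors`);
- an in silico knockout screen (clamp a node to 0, or 1 for constitutive
  activation) scored against a bundled catalog of 27 experimental KO/KD
  phenotypes (`neuritebool.mutagenesis`, `neuritebool.neurite`);
- a seeded random-network generator in the study model's structural class
  plus a naive per-state attractor oracle for property testing
  (`neuritebool.synth`);
- a thin CLI: `neuritebool attractors|screen|simulate|random-net|paper`.

## Worked example

```python
from neuritebool import (
    load_neurite_model, find_attractors_exhaustive, phenotype_active_fraction)

net = load_neurite_model()            # 16 printed rules + 8 identity inputs
aset = find_attractors_exhaustive(net)
print(aset.n_attractors)              # 268
print(aset.cycle_length_histogram())  # {1: 172, 7: 72, 8: 24}
print(round(phenotype_active_fraction(aset, net), 3))                     # 0.448
print(round(phenotype_active_fraction(aset, net, mode="any_state"), 3))   # 0.806
```

The exhaustive synchronous search finds 268 attractors: 172 fixed points,
72 seven-cycles and 24 eight-cycles, with basin sizes summing to 2^24.
Under the conservative convention (`all_states`: the read-out must be ON in
every state of the cycle) 44.8% of attractors are elongation-competent;
requiring a single ON state (`any_state`) gives 80.6%.

Knockouts re-run the same analysis on a clamped network
(`examples/03_knockout_screen.py`):

```
KO rhoa :  268 attractors, active fraction 0.000 (WT 0.448, delta -0.448) expected increase -> discordant
KO trio :  134 attractors, active fraction 0.179 (WT 0.448, delta -0.269) expected decrease -> concordant
```

A negative delta means the knockout lowers the fraction of
elongation-competent attractors. Each screened node is scored
concordant/discordant against the catalogued experimental direction;
`reproduce_analysis()` runs the full screen and collects every row that is
discordant under both activity conventions into an explicit deviations
report. See `examples/` for narrative scripts covering each capability.

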
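# Methods

## Model representation

A Boolean network is an ordered list of rules `target, expression` with
expressions over `! & | ( )`, identifiers and the constants `0`/`1`.
Operator precedence is NOT > AND > OR with left associativity (`a & b | c`
parses as `(a & b) | c`); AND/OR are flattened to n-ary nodes. Identifier
case is preserved and matching is case-sensitive, so rule files round-trip
byte-stably in content. The parser is a small hand-written recursive-descent
scanner that reports character positions on syntax errors and line numbers
at the file level.

Node order is load order and defines bit positions: state `s` is an integer
with bit `i` holding node `i`'s value. All dynamics and attractor machinery
operates on these integer codes.

Names referenced but never defined as targets are *unregulated factors*;
`complete_inputs` appends the identity rule `x, x` for each, in
first-reference order. This is the standard convention of the rule-file
dialect: it makes the file executable, conserves input values along every
trajectory, and decomposes the state space into `2^(#inputs)` closed
subspaces, one per boundary condition. An alternative (clamping inputs to a
constant) is available by writing constant rules, but the bundled analysis
uses identity inputs throughout, as recorded in `conventions.yaml`.

The signed interaction graph is derived from rule syntax: source → target is
activatory if the source occurs only at even negation depth in the target's
rule, inhibitory at odd depth, ambiguous if both occur. Identity self-loops
are flagged and ignored by the sink-removal pass, which iteratively deletes
nodes with no outgoing edges (the phenotype node and an explicit keep-set
always survive). Redundancy-based simplification is a curation judgement and
is deliberately not automated.

## Dynamics and attractor search

Synchronous update: every node recomputes from the *current* state, giving a
deterministic successor function. The full transition map is built by bulk
bitwise evaluation — one vectorised numpy pass per rule over all `2^N`
state codes — and refused above N = 26 (the 24-node model needs 64 MiB for
the `uint32` table).

Exhaustive attractor search uses pointer doubling: squaring the successor
map N times yields `succ^(2^N)`, which maps every state onto its terminal
cycle (transients are shorter than `2^N` by construction). The unique values
of that pointer array seed cycle walks that enumerate each cycle once; basin
sizes are a single `bincount` of cycle labels through the pointer array.
Cycles are canonicalised by rotating to their minimal state code (states in
a cycle are distinct, so ties cannot occur) and reported sorted by that
code, making output order deterministic and run-to-run comparable. On the
bundled model the whole search takes a few seconds.

Two independent routes verify the search: a naive per-state simulator with
explicit visited-set bookkeeping (`brute_force_attractors`, capped at
N = 12 so it stays honest — no shared code or optimisation with the fast
path), and the input-block decomposition, which searches each of the
`2^(#inputs)` closed subspaces separately and must pool to the identical
attractor set. The test suite checks exact agreement (states, cycle
lengths, basin sizes) on 200+ seeded random networks, and the acceptance
script re-runs the block cross-check on the bundled model at every
invocation.

Sampled search simulates trajectories from seeded random starts; it reports
reach counts rather than basins and is a lower bound on the attractor set,
monotone in the number of starts. Asynchronous stepping (one node at a
time, uniform random scheduler from a seeded generator) is provided for
completeness; no quantitative result here uses it, and loose asynchronous
attractors are out of scope.

## Phenotype read-out conventions

`phenotype_active_fraction` reports the fraction *of attractors* (not of
states, and unweighted by basin size) in which the read-out node is active.
Two conventions are implemented and always reported side by side:
`all_states` (default: the node must be ON in every state of the cycle — a
node oscillating ON/OFF counts as inactive, matching how whole attractors
are usually labelled in profile figures) and `any_state` (one ON state
suffices). Basin-weighted variants are also computed, since a per-state
reading is the other defensible aggregation. On the bundled wild-type model
these give 0.448 (`all_states`), 0.806 (`any_state`), 0.469 and 0.797
(basin-weighted respectively).

## Knockout screen and concordance

A knockout replaces a node's rule with the constant 0 (constitutive
activation: 1) and re-runs the exhaustive search; the clamped node is
constant in every attractor state, which the tests assert. Knockdowns and
dominant negatives are approximated as knockouts — two-state logic admits
no partial loss — and haploinsufficiency has no Boolean analog, so those
catalog rows are scored *indeterminate* rather than dropped. The shipped
catalog (27 rows) maps each experimental phenotype to a model node where
one survives simplification (PAK2 and PAK3 do not; Cdk5 and p35 share
`cdk5_p35`; ROCK1/ROCK2 share `rock`) and assigns a direction on neurite
elongation (`decrease`, `increase`, `no_effect`) from the reported
phenotype text; the CSV is editable so every curation call is overridable.

Concordance at tolerance `tol` (default 0, exposed as a flag): `decrease`
is concordant iff delta < −tol, `increase` iff delta > +tol, `no_effect`
iff |delta| ≤ tol, where delta is the knockout-minus-wild-type change in
the active-attractor fraction. `reproduce_analysis` scores every row under
the shipped convention, records whether the alternative activity convention
would flip the call, and emits rows discordant under both conventions as an
explicit deviations list. On the bundled model 10 of 23 mappable rows are
concordant under the default convention and 10 are discordant under both —
the screen is reported in full rather than summarised as a success rate,
because several regulators (most visibly cofilin, which appears in the
rules only as an inhibitor of F-actin while its experimental knockout
inhibits outgrowth) act through mechanisms the two-state abstraction of
this rule set does not carry.

## Synthetic networks

The generator emulates the study model's structural class: default 24
nodes, 8 identity-rule inputs, fan-in ≤ 6 uniformly chosen regulators per
rule, and one phenotypic sink fed by ≥ 1 regulator that regulates nothing.
The activation bias (probability a regulator enters un-negated) defaults to
0.65, the observed fraction of un-negated regulator occurrences in the
bundled rules (26 of 40). Two expression shapes are provided: random
AND/OR trees over per-regulator literals, and random truth tables rendered
to DNF so they flow through the one parser path. Generated models are
emitted and re-parsed, so every parser invariant holds by construction.
What the ensemble does *not* emulate: the real module's motif structure
(e.g. the PAK1–ARHGAP15 negative loop), biological edge signs, or any
redundancy pattern — passing the equivalence tests certifies the search
machinery on the structural class, not biological realism of the random
rules.

## Numerical and engineering choices

Everything is integer arithmetic; results are bit-identical across runs and
platforms, and `reproduce_analysis` echoes its conventions into the report
so any number can be regenerated from the record alone. Trajectory
simulation defaults to `max_steps = 2^min(N, 20)` as a guardrail (a
synchronous revisit is guaranteed within `2^N` steps). The brute-force
oracle's N ≤ 12 cap and the transition map's N = 26 cap are memory/honesty
bounds, not semantic limits; the sampled search covers larger networks.
Problem sizes in the test suite follow the study model (full 2^24
enumeration for the bundled analyses; 3–10 nodes for the 200-network oracle
equivalence sweep).

## Known limitations

Two-state logic cannot express partial loss of function, dosage effects, or
kinetic competition; the knockout screen therefore tests direction only.
Asynchronous attractors are not enumerated. The sink-removal operation
reverses only the generic leaf-pruning simplification; redundancy-based
merges performed during model curation are not reconstructible from the
rule file alone.
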
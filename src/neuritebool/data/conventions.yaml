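# Conventions that fully determine the bundled analysis. Echoed verbatim into
# every report so the numbers can be reproduced from the record alone.
input_handling: identity   # unregulated factors get self-sustaining rules x, x
activity_mode: all_states  # an attractor counts as phenotype-active only if
                           # the phenotype node is ON in every state of the cycle
tol: 0.0                   # any signed change in active fraction counts
clamp: 0                   # knockouts clamp to 0
basin_weighting: false     # fractions are per-attractor, not per-state
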
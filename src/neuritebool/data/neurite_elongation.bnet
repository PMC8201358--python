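# Boolean model of the Rho-GTPase network controlling neurite elongation.
# neuro_elo is the abstract phenotypic read-out node. The eight unregulated
# factors (profilin, formin, tiam1, arhgef6, arhgef7, trio, noma_gap, ophn1)
# carry no rule here; complete_inputs() gives them identity rules.
targets, factors
neuro_elo, f_actin
f_actin, (profilin | formin | arp2_3 | shootin1) & !cfl
arp2_3, wave
wave, (rac1 | cdc42) & !cdk5_p35
cdc42, (arhgef6 | arhgef7) & !(noma_gap | ophn1)
rhoa, trio | !(ophn1 | tiam1)
rac1, (tiam1 | arhgef6 | arhgef7 | trio) & !(arhgap15 | ophn1)
rock, rhoa
pak1, (rac1 | cdc42 | arhgef6 | arhgef7) & !(arhgap15 | cdk5_p35)
arhgap15, !pak1
shootin1, pak1
cdk5_p35, f_actin
limk2, rock
cfl, ssh1 & !(limk2 | limk1)
limk1, pak1 | !ssh1
ssh1, f_actin
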
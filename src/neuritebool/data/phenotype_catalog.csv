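protein,model_node,perturbation_kind,expected_direction,phenotype_text,reference
Rac1,rac1,KO,increase,Increased number of primary neurites and secondary branches,B95
RhoA,rhoa,KO,increase,Increased axon length,B368
Cdc42,cdc42,KO,decrease,Defective axon formation,B97
WAVE1,wave,KO,no_effect,No effect on neurite growth,B369
Cdk5,cdk5_p35,dominant_negative,decrease,Inhibition of neurite outgrowth,B370
p35,cdk5_p35,KD,decrease,Inhibition of neurite outgrowth,B370
Arp2/3,arp2_3,KD,decrease,"Increased number of irregular, shorter, and broader neurites",B371
PAK1,pak1,dominant_negative,decrease,Decreased number of dendrites,B361
PAK2,,dominant_negative,no_effect,No effect on the neurite growth,B372
PAK3,,KD,increase,Increased elongation of neuronal processes,B373
LIMK2,limk2,KD,decrease,Reduced number of neurite-bearing cells and the mean neurite length,B222
LIMK1,limk1,KD,decrease,Reduced number of neurite-bearing cells and the mean neurite length,B222
ROCK1,rock,haploinsufficiency,increase,Increased basal and apical dendritic length and dendritic intersections,B374
ROCK2,rock,haploinsufficiency,no_effect,No effect on the neurite growth,B374
SSH1/SSH2,ssh1,KD,decrease,Decreased neurite extension,B222
ArhGEF6,arhgef6,KO,increase,Increased neurite length,B184
ArhGEF7,arhgef7,KO,decrease,Impaired axon formation,B193
ArhGAP15,arhgap15,KO,decrease,Decreased neurite length and branching,B172
TRIO,trio,KO,decrease,Decreased axon length,B376
Tiam1,tiam1,KO,decrease,Decreased neurite length,B211
NOMA-GAP,noma_gap,KO,decrease,Decreased dendritic branching,B176
OPHN1,ophn1,KO,decrease,"Decreased dendritic tree complexity, i.e., branching",B377
Cofilin,cfl,KO,decrease,Inhibited neurite outgrowth,B378
Profilin1,profilin,KD,decrease,Impaired axon elongation,B349
Profilin1,profilin,KD,decrease,Decreased neurite length (actin-binding-domain mutation),B265
Formin,formin,KO,decrease,Impaired axon elongation,B379
Shootin1,shootin1,KD,decrease,Inhibited polarization,B380
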
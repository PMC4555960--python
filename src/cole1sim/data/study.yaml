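# Measured study inputs for the two E. coli DH5alpha strains: harvest times,
# growth rates (from the derivative of the fitted log-OD polynomial),
# generation times, and the qRT-PCR / plasmid-mass derived molecule counts
# (mean +/- SD over three biological replicates).  These numbers drive the
# single-generation simulations (initial plasmid load = half the measured
# copy number) and the T2-anchored parameter fit.
low:
  strain: DH5alpha-pSUP201-3
  plasmid_size_bp: 7896
  timepoints:
    T1: {harvest_h: 5.25,  mu: 0.278, generation_min: 150,
         rnaI: 34,  rnaI_sd: 7,    rnaII: 3,    rnaII_sd: 0.9,
         pcn: 46,   pcn_sd: 26}
    T2: {harvest_h: 8.25,  mu: 0.302, generation_min: 138,
         rnaI: 17,  rnaI_sd: 5,    rnaII: 1,    rnaII_sd: 0.4,
         pcn: 48,   pcn_sd: 30}
    T3: {harvest_h: 10.5,  mu: 0.283, generation_min: 147,
         rnaI: 6,   rnaI_sd: 0.7,  rnaII: 0.44, rnaII_sd: 0.1,
         pcn: 46,   pcn_sd: 17}
high:
  strain: DH5alpha-pCMV-lacZ
  plasmid_size_bp: 7164
  timepoints:
    T1: {harvest_h: 8.17,  mu: 0.305, generation_min: 136,
         rnaI: 541,  rnaI_sd: 51,  rnaII: 22, rnaII_sd: 2,
         pcn: 1514,  pcn_sd: 1301}
    T2: {harvest_h: 11.50, mu: 0.256, generation_min: 162,
         rnaI: 1086, rnaI_sd: 298, rnaII: 64, rnaII_sd: 4,
         pcn: 2403,  pcn_sd: 713}
    T3: {harvest_h: 17.50, mu: 0.090, generation_min: 347,
         rnaI: 345,  rnaI_sd: 203, rnaII: 75, rnaII_sd: 10,
         pcn: 5806,  pcn_sd: 4828}
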
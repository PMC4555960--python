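# Kinetic constants k1..k26 for the ColE1-like replication-control model,
# per plasmid type.  `low` refers to the Rom-carrying low-copy plasmid
# (pSUP 201-3, 7896 bp), `high` to the rom-deleted high-copy plasmid
# (pCMV-lacZ, 7164 bp).  Constants without a high-copy value belong to the
# five Rom-dependent reactions, which are removed from the high-copy
# network.
#
# Units follow the published table.  Two footnotes on usage:
#   - k14 and k16 describe bimolecular association steps and are applied as
#     second-order constants (M^-1 min^-1) even though the source table
#     prints first-order units for them;
#   - k3, k4 and k26 are estimated by fitting the simulated end-of-generation
#     copy number to the measured value at the second harvest time point;
#     the values below are the published point estimates and serve as the
#     optimizer's start/centre.
k:
  1:  {low: 1.7e8,   high: null,    unit: "M-1.min-1"}
  2:  {low: 0.17,    high: null,    unit: "min-1"}
  3:  {low: 1.02e8,  high: 3.05e6,  unit: "M-1.min-1", fitted: true}
  4:  {low: 48.0,    high: 20.0,    unit: "min-1",     fitted: true}
  5:  {low: 12.0,    high: 12.0,    unit: "min-1"}
  6:  {low: 4.3,     high: 4.3,     unit: "min-1"}
  7:  {low: 3.8,     high: 4.19,    unit: "min-1"}
  8:  {low: 4.3,     high: 4.3,     unit: "min-1"}
  9:  {low: 0.25,    high: 0.25,    unit: "M-1.min-1"}
  10: {low: 44.0,    high: 44.0,    unit: "min-1"}
  11: {low: 0.085,   high: 0.085,   unit: "min-1"}
  12: {low: 17.0,    high: 17.0,    unit: "min-1"}
  13: {low: 34.0,    high: null,    unit: "min-1"}
  14: {low: 1.8e5,   high: 1.8e5,   unit: "M-1.min-1"}
  15: {low: 1.8e5,   high: 1.8e5,   unit: "M-1.min-1"}
  16: {low: 12.0,    high: 12.0,    unit: "M-1.min-1"}
  17: {low: 0.25,    high: 0.25,    unit: "min-1"}
  18: {low: 6.0,     high: 6.0,     unit: "min-1"}
  19: {low: 0.25,    high: 0.25,    unit: "min-1"}
  20: {low: 4.0,     high: null,    unit: "min-1"}
  21: {low: 0.35,    high: 0.35,    unit: "min-1"}
  22: {low: 0.35,    high: 0.35,    unit: "min-1"}
  23: {low: 0.14,    high: null,    unit: "min-1"}
  24: {low: 7.99e-6, high: 7.99e-6, unit: "M.min-1"}
  25: {low: 1.02e8,  high: 3.05e6,  unit: "M-1.min-1"}
  26: {low: 0.35,    high: 0.35,    unit: "min-1",     fitted: true}
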
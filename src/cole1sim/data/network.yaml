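# Canonical reaction <-> rate-constant mapping of the ColE1-like plasmid
# replication-control network.
#
# The network couples three regulatory layers around the replication origin:
#   1. antisense inhibition: RNAI binds the plasmid-bound RNAII preprimer
#      (kissing complex) and blocks primer maturation;
#   2. Rom-protein stabilization of the kissing complex (low-copy plasmids
#      only; the rom gene is deleted in high-copy derivatives);
#   3. uncharged tRNA bypass: tRNA bound to RNAII prevents RNAI binding, so
#      the preprimer can still mature into a replication primer.
#
# Every reaction follows mass-action kinetics and references exactly one
# rate constant k1..k26.  This file is the single editable source of the
# mapping: species, stoichiometries and constant assignments can be revised
# here without touching code.  The assignment below was selected so that the
# network reproduces the measured copy-number behaviour of both strains and
# of all three nutrient scenarios once k3, k4 and k26 are calibrated against
# the second harvest time point (see docs/methods.md for the reasoning and
# the alternatives that were rejected).
#
# Conventions:
#   - reactants/products are maps species -> stoichiometry;
#   - zero-reactant reactions are constant-rate syntheses (flux = k, M/min);
#   - catalytic syntheses (plasmid -> plasmid + RNA) are first order in the
#     free-plasmid pool; setting gene_dosage: true switches a synthesis to
#     the summed concentration of all plasmid-bearing species instead;
#   - rom_dependent: true marks the five reactions absent from the
#     high-copy network (their constants have no high-copy value);
#   - the bookkeeping species `replicated_pDNA` counts completed replication
#     events; it takes part in no reaction as a reactant, is not diluted and
#     is excluded from the copy-number readout (each replication already
#     yields two countable pDNA molecules).

species:
  - {name: pDNA,                role: plasmid-bearing}
  - {name: RNAII,               role: free-RNA}
  - {name: RNAI,                role: free-RNA}
  - {name: Rom,                 role: protein}
  - {name: tRNA,                role: tRNA}
  - {name: RNAI_RNAII,          role: complex}
  - {name: RNAII_tRNA,          role: complex}
  - {name: pDNA_RNAII_s,        role: plasmid-bearing}
  - {name: pDNA_RNAII_lo,       role: plasmid-bearing}
  - {name: pDNA_RNAII_primer,   role: plasmid-bearing}
  - {name: pDNA_RNAII_tRNA,     role: plasmid-bearing}
  - {name: pDNA_RNAII_RNAI_u,   role: plasmid-bearing}
  - {name: pDNA_RNAII_RNAI_Rom, role: plasmid-bearing}
  - {name: pDNA_RNAII_RNAI_st,  role: plasmid-bearing}
  - {name: replicated_pDNA,     role: bookkeeping}

reactions:
  # --- Rom control (low-copy only) -------------------------------------
  - id: v1
    k: 1
    reactants: {Rom: 1, pDNA_RNAII_RNAI_u: 1}
    products: {pDNA_RNAII_RNAI_Rom: 1}
    rom_dependent: true
    note: Rom binds the unstable kissing complex.
  - id: v2
    k: 2
    reactants: {pDNA_RNAII_RNAI_Rom: 1}
    products: {Rom: 1, pDNA_RNAII_RNAI_u: 1}
    rom_dependent: true
    note: Rom release from the transient complex.
  - id: v13
    k: 13
    reactants: {pDNA_RNAII_RNAI_Rom: 1}
    products: {pDNA_RNAII_RNAI_st: 1, Rom: 1}
    rom_dependent: true
    note: Rom-mediated conversion into the stable complex; Rom recycles.

  # --- antisense inhibition at the origin ------------------------------
  - id: v3
    k: 3
    reactants: {RNAI: 1, pDNA_RNAII_s: 1}
    products: {pDNA_RNAII_RNAI_u: 1}
    note: RNAI binds the short plasmid-RNAII hybrid (kissing complex).
  - id: v4
    k: 4
    reactants: {pDNA_RNAII_RNAI_u: 1}
    products: {RNAI: 1, pDNA_RNAII_s: 1}
    note: kissing-complex resolution.
  - id: v10
    k: 10
    reactants: {pDNA_RNAII_RNAI_u: 1}
    products: {pDNA_RNAII_RNAI_st: 1}
    note: Rom-independent maturation into the stable complex.
  - id: v12
    k: 12
    reactants: {pDNA_RNAII_RNAI_u: 1}
    products: {pDNA: 1, RNAI_RNAII: 1}
    note: abortive decay of the kissing complex; the plasmid recycles.
  - id: v26
    k: 26
    reactants: {pDNA_RNAII_RNAI_st: 1}
    products: {pDNA: 1, RNAI_RNAII: 1}
    note: decay of the stable complex; plasmid recycles, duplex leaves.
  - id: v11
    k: 11
    reactants: {RNAI_RNAII: 1}
    products: {}
    note: slow degradation of the free RNAI-RNAII duplex.

  # --- primer formation and replication --------------------------------
  - id: v17
    k: 17
    reactants: {pDNA: 1}
    products: {pDNA_RNAII_s: 1}
    note: RNAII transcription initiation; the origin becomes engaged.
  - id: v5
    k: 5
    reactants: {pDNA_RNAII_s: 1}
    products: {pDNA_RNAII_lo: 1}
    note: RNAII elongation past the RNAI-sensitive window (>360 nt).
  - id: v6
    k: 6
    reactants: {pDNA_RNAII_s: 1}
    products: {pDNA: 1}
    note: abortive turnover of the short hybrid; the bound RNAII is lost.
  - id: v8
    k: 8
    reactants: {pDNA_RNAII_lo: 1}
    products: {pDNA_RNAII_primer: 1}
    note: RNase H cleavage exposing the 3'OH primer end.
  - id: v7
    k: 7
    reactants: {pDNA_RNAII_primer: 1}
    products: {pDNA: 2, replicated_pDNA: 1}
    note: DNA polymerase I elongation; the plasmid is doubled.

  # --- uncharged tRNA bypass -------------------------------------------
  - id: v14
    k: 14
    reactants: {tRNA: 1, pDNA_RNAII_s: 1}
    products: {pDNA_RNAII_tRNA: 1}
    note: tRNA binds the plasmid-bound RNAII, shielding it from RNAI.
  - id: v15
    k: 15
    reactants: {tRNA: 1, RNAII: 1}
    products: {RNAII_tRNA: 1}
    note: tRNA binds free RNAII.
  - id: v9
    k: 9
    reactants: {RNAII_tRNA: 1, pDNA: 1}
    products: {pDNA_RNAII_tRNA: 1}
    note: the RNAII-tRNA complex hybridizes with a plasmid origin.
  - id: v16
    k: 16
    reactants: {pDNA_RNAII_tRNA: 1}
    products: {pDNA_RNAII_primer: 1, tRNA: 1}
    note: the shielded hybrid matures into a primer; tRNA recycles.

  # --- synthesis / degradation / free duplex ---------------------------
  - id: v18
    k: 18
    reactants: {pDNA: 1}
    products: {pDNA: 1, RNAI: 1}
    note: RNAI transcription from free plasmid origins.
  - id: v20
    k: 20
    reactants: {pDNA: 1}
    products: {pDNA: 1, Rom: 1}
    rom_dependent: true
    note: Rom synthesis from free plasmid copies.
  - id: v21
    k: 21
    reactants: {RNAII: 1}
    products: {}
    note: free RNAII degradation.
  - id: v22
    k: 22
    reactants: {RNAI: 1}
    products: {}
    note: free RNAI degradation.
  - id: v23
    k: 23
    reactants: {Rom: 1}
    products: {}
    rom_dependent: true
    note: Rom degradation.
  - id: v24
    k: 24
    reactants: {}
    products: {tRNA: 1}
    note: uncharged tRNA synthesis (constant rate, M/min).
  - id: v19
    k: 19
    reactants: {tRNA: 1}
    products: {}
    note: uncharged tRNA removal (degradation / recharging).
  - id: v25
    k: 25
    reactants: {RNAI: 1, RNAII: 1}
    products: {RNAI_RNAII: 1}
    note: free RNAI-RNAII duplex formation.
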
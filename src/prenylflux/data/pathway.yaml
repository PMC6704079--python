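# Mevalonate / prenyl-pyrophosphate pathway of S. cerevisiae as measured
# by the targeted LC-HRMS workflow: eight free-acid compounds, seven
# kinetic pools (IPP and DMAPP are isobaric and chromatographically
# unresolved, so they form one merged pool/signal), and the reaction
# topology used by the labeling simulator.
metabolites:
  - {name: MEV,   formula: C6H12O4,    cas: "150-97-0",   retention_time_min: 1.2, quantifiable_in_ile: false}
  - {name: M5P,   formula: C6H13O7P,   cas: "1189-94-2",  retention_time_min: 1.2, quantifiable_in_ile: true}
  - {name: M5PP,  formula: C6H14O10P2, cas: "4872-34-8",  retention_time_min: 0.9, quantifiable_in_ile: false}
  - {name: IPP,   formula: C5H12O7P2,  cas: "358-71-4",   retention_time_min: 1.2, quantifiable_in_ile: true}
  - {name: DMAPP, formula: C5H12O7P2,  cas: "358-72-5",   retention_time_min: 1.2, quantifiable_in_ile: true}
  - {name: GPP,   formula: C10H20O7P2, cas: "763-10-0",   retention_time_min: 5.7, quantifiable_in_ile: true}
  - {name: FPP,   formula: C15H28O7P2, cas: "13058-04-3", retention_time_min: 7.4, quantifiable_in_ile: true}
  - {name: GGPP,  formula: C20H36O7P2, cas: "6699-20-3",  retention_time_min: 8.7, quantifiable_in_ile: true}

pools:
  - {name: MEV,       members: [MEV],        n_carbons: 6,  quantifiable_in_ile: false}
  - {name: M5P,       members: [M5P],        n_carbons: 6,  quantifiable_in_ile: true}
  - {name: M5PP,      members: [M5PP],       n_carbons: 6,  quantifiable_in_ile: false}
  - {name: IPP+DMAPP, members: [IPP, DMAPP], n_carbons: 5,  quantifiable_in_ile: true}
  - {name: GPP,       members: [GPP],        n_carbons: 10, quantifiable_in_ile: true}
  - {name: FPP,       members: [FPP],        n_carbons: 15, quantifiable_in_ile: true}
  - {name: GGPP,      members: [GGPP],       n_carbons: 20, quantifiable_in_ile: true}

reactions:
  # three acetyl (C2) units condense into mevalonate
  - {kind: source_feed, product: MEV, unit_carbons: 2, n_units: 3}
  - {kind: linear_step, substrate: MEV, product: M5P}
  - {kind: linear_step, substrate: M5P, product: M5PP}
  # decarboxylative elimination: one of six carbons lost
  - {kind: carbon_loss, substrate: M5PP, product: IPP+DMAPP}
  # head-to-tail condensations, each adding one C5 unit
  - {kind: condensation, substrates: [IPP+DMAPP, IPP+DMAPP], product: GPP}
  - {kind: condensation, substrates: [GPP, IPP+DMAPP], product: FPP}
  - {kind: condensation, substrates: [FPP, IPP+DMAPP], product: GGPP}
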
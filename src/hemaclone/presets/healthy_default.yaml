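# Normal hematopoiesis only (six maturation steps); same parameter
# provenance conventions as mds_baseline.yaml.
variant: baseline
feedback:
  k_p: 2.108e-12          # calibrated
  k_a: 1.596e-11          # calibrated
  niche_depth: 3        # paper
  apoptosis_visibility: 1.0   # paper
lineages:
- label: normal
  compartments:
  - {name: LT-HSC,    a_max: 0.70, p_max: 0.02, d: 0.0, divides: true,  in_niche: true,  in_pb: false}  # paper
  - {name: ST-HSC,    a_max: 0.69, p_max: 0.05, d: 0.0, divides: true,  in_niche: true,  in_pb: false}  # reference-model
  - {name: MPP,       a_max: 0.68, p_max: 0.15, d: 0.0, divides: true,  in_niche: true,  in_pb: false}  # reference-model
  - {name: CPC,       a_max: 0.67, p_max: 0.40, d: 0.0, divides: true,  in_niche: false, in_pb: false}  # reference-model
  - {name: precursor, a_max: 0.66, p_max: 1.00, d: 0.0, divides: true,  in_niche: false, in_pb: false}  # reference-model
  - {name: mature,    a_max: 0.0,  p_max: 0.0,  d: 2.0, divides: false, in_niche: false, in_pb: true}   # reference-model
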
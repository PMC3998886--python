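# Alternative MDS variant: the malignant lineage matures fully (six
# compartments) and its mature cells are short-lived in peripheral blood
# (half-life 16 h -> d = ln 2 / (16/24) ~= 1.0397 1/d).  MDS-derived mature
# cells contribute to the proliferation signal pool (assumption; they are
# circulating mature cells).
variant: mds_full_maturation
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
- label: mds
  compartments:
  - {name: MDS-LT-HSC,    a_max: 0.90, p_max: 0.01, d: 0.0, divides: true,  in_niche: true,  in_pb: false}  # paper
  - {name: MDS-ST-HSC,    a_max: 0.7565, p_max: 0.08, d: 0.0, divides: true,  in_niche: true,  in_pb: false}  # calibrated (as baseline)
  - {name: MDS-MPP,       a_max: 0.6120, p_max: 0.1563, d: 0.0, divides: true,  in_niche: true,  in_pb: false}  # calibrated (as baseline)
  - {name: MDS-CPC,       a_max: 0.5972, p_max: 0.1808, d: 0.0, divides: true,  in_niche: false, in_pb: false}  # calibrated (as baseline)
  - {name: MDS-precursor, a_max: 0.56, p_max: 1.00, d: 0.0, divides: true,  in_niche: false, in_pb: false}  # assumption (continues hierarchy)
  - {name: MDS-mature,    a_max: 0.0,  p_max: 0.0,  d: 1.0397207708399179, divides: false, in_niche: false, in_pb: true}  # paper: half-life 16 h
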
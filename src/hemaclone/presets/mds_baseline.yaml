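# Default two-lineage MDS competition scenario.
#
# Provenance of each value:
#   paper           -- printed in the source study (stem-cell extremes,
#                      dysplastic death rate, niche depth, apoptosis window)
#   reference-model -- convention carried over from the predecessor
#                      feedback model of hematopoiesis (signal form,
#                      monotone intermediate hierarchy, mature death rate)
#   calibrated      -- free value fitted once (scratch/calibrate.py) so the
#                      simulated disease course reproduces the reported
#                      timeline (~17 y manifestation, year-17 marrow
#                      composition, apoptotic plateau)
variant: baseline
feedback:
  k_p: 2.108e-12          # calibrated (sets s_p* at the healthy equilibrium)
  k_a: 1.596e-11          # calibrated (sets the absolute niche size)
  niche_depth: 3        # paper (LT-HSC, ST-HSC, MPP occupy the niche)
  apoptosis_visibility: 1.0   # paper ("apoptosis takes 24 h")
lineages:
- label: normal
  compartments:
  - {name: LT-HSC,    a_max: 0.70, p_max: 0.02, d: 0.0, divides: true,  in_niche: true,  in_pb: false}  # paper: once per 50 d, up to 70%
  - {name: ST-HSC,    a_max: 0.69, p_max: 0.05, d: 0.0, divides: true,  in_niche: true,  in_pb: false}  # reference-model (monotone interpolation)
  - {name: MPP,       a_max: 0.68, p_max: 0.15, d: 0.0, divides: true,  in_niche: true,  in_pb: false}  # reference-model
  - {name: CPC,       a_max: 0.67, p_max: 0.40, d: 0.0, divides: true,  in_niche: false, in_pb: false}  # reference-model
  - {name: precursor, a_max: 0.66, p_max: 1.00, d: 0.0, divides: true,  in_niche: false, in_pb: false}  # reference-model
  - {name: mature,    a_max: 0.0,  p_max: 0.0,  d: 2.0, divides: false, in_niche: false, in_pb: true}   # reference-model (mean lifespan 0.5 d)
- label: mds
  compartments:
  - {name: MDS-LT-HSC, a_max: 0.90, p_max: 0.01, d: 0.0, divides: true,  in_niche: true,  in_pb: false}  # paper: once per 100 d, up to 90%
  - {name: MDS-ST-HSC, a_max: 0.7565, p_max: 0.08, d: 0.0, divides: true,  in_niche: true,  in_pb: false}  # calibrated
  - {name: MDS-MPP,    a_max: 0.6120, p_max: 0.1563, d: 0.0, divides: true,  in_niche: true,  in_pb: false}  # calibrated
  - {name: MDS-CPC,    a_max: 0.5972, p_max: 0.1808, d: 0.0, divides: true,  in_niche: false, in_pb: false}  # calibrated
  - {name: dysplastic, a_max: 0.0,  p_max: 0.0,  d: 0.1, divides: false, in_niche: false, in_pb: false}  # paper ("die within 10 days")
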
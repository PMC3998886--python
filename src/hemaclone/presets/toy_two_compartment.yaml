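# Minimal two-compartment analytic test model: one self-regulating stem
# compartment feeding a dying mature pool.  The stem equilibrium is
# c* = (2 a_max - 1)/k_a at s_a* = 1/(2 a_max); the mature pool follows
# from the scalar flux balance.
variant: baseline
feedback:
  k_p: 1.0e-4
  k_a: 1.0e-3
  niche_depth: 1
  apoptosis_visibility: 1.0
lineages:
- label: normal
  compartments:
  - {name: stem,   a_max: 0.7, p_max: 0.1, d: 0.0, divides: true,  in_niche: true,  in_pb: false}
  - {name: mature, a_max: 0.0, p_max: 0.0, d: 0.5, divides: false, in_niche: false, in_pb: true}
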
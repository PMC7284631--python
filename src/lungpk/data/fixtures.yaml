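# Packaged parameter sets: four intravenous model drugs and rat lung physiology.
#
# All kinetic parameters are normalised to body weight (L/h/kg, L/kg).
# Tissue weight fractions are kg tissue per kg body weight; 1 kg of tissue
# is treated as 1 L of distribution volume.
#
# fraction unbound in plasma (fu_plasma) is resolved at load time from the
# recorded anchor (see docs/methods.md): either a free-vs-total EC50 pair for
# the bronchial target tissue, or a printed tracheal absorption half-life
# inverted through t_half = ln2 * V * Kp / (Q * fu).  Linezolid carries no
# physically admissible anchor and defaults to fu = 1 (logged warning).
physiology:
  w_t: 0.0002      # trachea, kg/kg
  w_b: 0.0008      # bronchi, kg/kg
  w_a: 0.004       # alveolar parenchyma, kg/kg (~80% of total lung)
  w_lung: 0.005    # whole lung, kg/kg
  q_t: 0.054       # tracheal blood flow, L/h/kg
  q_b: 0.777       # bronchial blood flow, L/h/kg
  q_a: 10.6        # alveolar (pulmonary) blood flow, L/h/kg
  q_lung: 11.6     # single-compartment whole-lung blood flow, L/h/kg
  bw: 0.28         # mean rat body weight, kg

drugs:
  salmeterol:
    cl: 3.86
    v_c: 0.123
    q_ic: 3.24
    v_p: 3.77
    kp_t: 6.52
    kp_b: 18.6
    kp_a: 39.3
    kp_lung: 37.7
    fu_anchor:
      kind: free_ec50         # fu = ec50_free * kp_b / ec50_total
      ec50_total_nm: 36.0
      ec50_free_nm: 0.0271
  fluticasone:
    cl: 3.37
    v_c: 0.223
    q_ic: 4.72
    v_p: 2.41
    kp_t: 5.21
    kp_b: 6.64
    kp_a: 5.84
    kp_lung: 6.21
    fu_anchor:
      kind: half_life         # fu = ln2 * V * Kp / (Q * t_half)
      tissue: trachea
      t_half_min: 52.4
  linezolid:
    cl: 0.279
    v_c: 0.320
    q_ic: 2.79
    v_p: 0.628
    kp_t: 0.404
    kp_b: 0.534
    kp_a: 0.785
    kp_lung: 0.781
    fu_plasma: 1.0
    fu_assumed: true
  indomethacin:
    cl: 0.0691
    v_c: 0.154
    kp_t: 0.356
    kp_b: 0.249
    kp_a: 0.384
    kp_lung: 0.347
    fu_anchor:
      kind: half_life
      tissue: trachea
      t_half_s: 14.0
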
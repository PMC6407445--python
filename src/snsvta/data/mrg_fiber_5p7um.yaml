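# Double-cable myelinated fibre parameters, 5.7 um diameter class.
# Geometry and electrical constants transcribed from the published
# double-cable model of mammalian motor fibres (explicit node of Ranvier,
# MYSA and FLUT paranodes, six STIN internodal segments per internode).
# Units are stated in each key name.
version: 1
fiber_diameter_um: 5.7
internode_length_um: 500.0        # node-to-node spacing for this diameter class
lamellae: 80                      # myelin wraps; each lamella = 2 membranes
rho_axial_ohm_cm: 70.0            # axoplasmic and periaxonal resistivity
myelin_cm_uf_cm2_per_lamella: 0.1
myelin_gm_s_cm2_per_lamella: 0.001
temperature_c: 36.0
v_rest_mv: -80.0
q10_gates:                        # rate scaling referenced to the tabulated temps
  m: {q10: 2.2, t_ref_c: 20.0}
  h: {q10: 2.9, t_ref_c: 20.0}
  p: {q10: 2.2, t_ref_c: 20.0}
  s: {q10: 3.0, t_ref_c: 36.0}
compartments:
  node:
    length_um: 1.0
    diameter_um: 1.9
    cm_uf_cm2: 2.0
    periaxonal_width_um: 0.002
    # the nodal axolemma faces the extracellular space directly: the
    # second cable layer is shorted with a large sheet conductance
    sheath_g_s_cm2: 1.0e+6
    sheath_c_uf_cm2: 0.0
    channels:
      gnabar_s_cm2: 3.0           # fast sodium
      gnapbar_s_cm2: 0.01         # persistent sodium
      gkbar_s_cm2: 0.08           # slow potassium
      gl_s_cm2: 0.007             # nodal leak
      ena_mv: 50.0
      ek_mv: -90.0
      el_mv: -90.0
  mysa:
    length_um: 3.0
    diameter_um: 1.9
    cm_uf_cm2: 2.0
    gpas_s_cm2: 0.001
    epas_mv: -80.0
    periaxonal_width_um: 0.002
  flut:
    length_um: 35.0
    diameter_um: 3.4
    cm_uf_cm2: 2.0
    gpas_s_cm2: 0.0001
    epas_mv: -80.0
    periaxonal_width_um: 0.004
  stin:
    count: 6                      # STIN length = (internode - node - 2*MYSA - 2*FLUT)/6
    diameter_um: 3.4
    cm_uf_cm2: 2.0
    gpas_s_cm2: 0.0001
    epas_mv: -80.0
    periaxonal_width_um: 0.004
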
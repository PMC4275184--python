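# SW myelinated-axon model (Sweeney/CRRSS mammalian node membrane with
# perfectly insulating myelin): only nodes of Ranvier and the internodal
# axoplasmic resistance are represented.
#
# Membrane kinetics and maximal conductances are the CRRSS values at 37 C;
# voltages in the rate functions are displacements from rest (mV).
version: 1
temperature_c: 37.0
v_rest_mv: -80.0
# nodal membrane
c_m_uF_per_cm2: 2.5
g_na_mS_per_cm2: 1445.0
g_l_mS_per_cm2: 128.0
e_na_rel_mv: 115.0        # reversal relative to rest
e_l_rel_mv: -0.01         # nominal; recalibrated at init for exact rest
# geometry rules (D = outer fiber diameter, um)
axon_diameter_ratio: 0.6  # axon (node) diameter = 0.6 * D
node_length_um: 1.5
internode_length_ratio: 100.0  # internode length = 100 * D
rho_axial_ohm_cm: 54.7
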
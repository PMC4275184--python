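# MRG double-cable myelinated-axon model (McIntyre-Richardson-Grill
# mammalian motor fiber): explicit nodes of Ranvier, paranodal MYSA and
# FLUT sections, internodal STIN sections, finite-impedance myelin sheath
# and a periaxonal conduction pathway.
#
# Electrical parameters at 36 C.  Geometry is diameter-dependent and given
# by the published table below; diameters between/outside the table rows
# are linearly inter-/extrapolated.
version: 1
temperature_c: 36.0
v_rest_mv: -80.0
rho_axial_ohm_cm: 70.0
rho_periaxonal_ohm_cm: 70.0
# nodal membrane
node:
  c_m_uF_per_cm2: 2.0
  g_naf_mS_per_cm2: 3000.0
  g_nap_mS_per_cm2: 10.0
  g_ks_mS_per_cm2: 80.0
  g_l_mS_per_cm2: 7.0
  e_na_mv: 50.0
  e_k_mv: -90.0
  e_l_mv: -90.0
# internodal axolemma (passive)
mysa: {c_m_uF_per_cm2: 2.0, g_pas_mS_per_cm2: 1.0}
flut: {c_m_uF_per_cm2: 2.0, g_pas_mS_per_cm2: 0.1}
stin: {c_m_uF_per_cm2: 2.0, g_pas_mS_per_cm2: 0.1}
# myelin sheath, per lamella membrane (2*nl membranes in series)
myelin: {c_m_uF_per_cm2: 0.1, g_m_mS_per_cm2: 1.0}
# periaxonal space widths (um)
space: {node: 0.002, mysa: 0.002, flut: 0.004, stin: 0.004}
# fixed section lengths (um)
node_length_um: 1.0
mysa_length_um: 3.0
n_stin: 6
# geometry table: fiber D, axon D, node D, MYSA D, FLUT D, internode length,
# FLUT length, myelin lamellae count   (all lengths um)
geometry_table:
  columns: [fiber_d, axon_d, node_d, mysa_d, flut_d, internode_len, flut_len, n_lamellae]
  rows:
    - [5.7,  3.4,  1.9, 1.9,  3.4,  500,  35,  80]
    - [7.3,  4.6,  2.4, 2.4,  4.6,  750,  38, 100]
    - [8.7,  5.8,  2.8, 2.8,  5.8, 1000,  40, 110]
    - [10.0, 6.9,  3.3, 3.3,  6.9, 1150,  46, 120]
    - [11.5, 8.1,  3.7, 3.7,  8.1, 1250,  50, 130]
    - [12.8, 8.8,  4.2, 4.2,  8.8, 1350,  54, 135]
    - [14.0, 10.4, 4.7, 4.7, 10.4, 1400,  56, 140]
    - [15.0, 11.5, 5.0, 5.0, 11.5, 1450,  58, 145]
    - [16.0, 12.7, 5.5, 5.5, 12.7, 1500,  60, 150]
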
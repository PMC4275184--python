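# Electrode design catalogue.
#
# Dimensions of the commercial leads are manufacturer-datasheet-typical
# values (they are overridable per run); the angular-tripole (AT) is a
# design concept: a percutaneous shaft carrying arc contacts at distinct
# azimuths so that a cord-facing cathode can be flanked by anodes that
# steer current away from the cord.
#
# kinds:
#   cylindrical: annular contacts stacked along a cylindrical shaft
#   paddle:      rectangular contacts abreast on a planar carrier
#   azimuthal:   arc contacts at distinct azimuths on a cylindrical shaft
#
# All lengths in mm, angles in degrees.  ies = inter-electrode spacing
# (edge-to-edge gap between adjacent contacts).

ADTECH:
  kind: cylindrical
  shaft_diameter: 1.1
  shaft_length: 30.0
  contact_length: 2.41
  ies: 2.59            # 5 mm centre-to-centre pitch
  n_contacts: 3

LT15:
  kind: cylindrical
  shaft_diameter: 1.3
  shaft_length: 30.0
  contact_length: 1.5
  ies: 1.5
  n_contacts: 3

LT6:
  kind: cylindrical
  shaft_diameter: 1.3
  shaft_length: 40.0
  contact_length: 3.0
  ies: 6.0
  n_contacts: 3

TT1:
  kind: paddle
  paddle_width: 8.0
  paddle_length: 20.0
  paddle_thickness: 2.0
  contact_width: 1.0   # mediolateral
  contact_length: 3.0  # rostrocaudal
  ies: 1.0
  n_contacts: 3

TT3:
  kind: paddle
  paddle_width: 10.0
  paddle_length: 20.0
  paddle_thickness: 2.0
  contact_width: 1.0
  contact_length: 3.0
  ies: 3.0
  n_contacts: 3

AT:
  kind: azimuthal
  shaft_diameter: 1.4
  shaft_length: 30.0
  contact_length: 3.0
  contact_arc_deg: 60.0
  contact_azimuths_deg: [0.0, 120.0, -120.0]  # 0 = cord-facing (cathode)
  n_contacts: 3
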
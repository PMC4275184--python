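# Tissue conductivities (S/m) for the spinal volume conductor.
# White matter is anisotropic: the longitudinal value applies along the
# rostrocaudal (cord) axis, the transverse value along both perpendicular axes.
# Sources: classic measured values used throughout the SCS modelling
# literature (Ranck & BeMent white matter; Baumann CSF; Struijk dura; etc.).
white_matter_longitudinal: 0.60
white_matter_transverse: 0.083
grey_matter: 0.23
csf: 1.8
dura: 0.030
extradural_space: 0.20
vertebral_bone: 0.02
intervertebral_disc: 0.65
muscle: 0.20
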
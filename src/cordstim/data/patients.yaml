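# Per-patient spinal cord / CSF-space cross-section dimensions (mm, full
# widths measured on transverse MRI at the stimulated level) and the position
# of the cord within the dural sac.  "center": cord centred in the sac;
# "ventral": cord centre twice as far from the dorsal interior dura surface
# as from the ventral interior surface.
patient_1: {cord_ml: 7, cord_vd: 6, csf_ml: 19, csf_vd: 16, cord_placement: center}
patient_2: {cord_ml: 8, cord_vd: 7, csf_ml: 21, csf_vd: 18, cord_placement: ventral}
patient_3: {cord_ml: 8, cord_vd: 6, csf_ml: 20, csf_vd: 14, cord_placement: center}
patient_4: {cord_ml: 9, cord_vd: 6, csf_ml: 18, csf_vd: 13, cord_placement: center}
patient_5: {cord_ml: 8, cord_vd: 6, csf_ml: 18, csf_vd: 15, cord_placement: ventral}
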
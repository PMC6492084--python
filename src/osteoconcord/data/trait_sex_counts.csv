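trait,sex,n_correct,n_incorrect,n_indeterminate
ventral_arc,male,27,2,2
ischiopubic_ramus,male,27,0,5
subpubic_concavity,male,27,0,0
sciatic_notch,male,36,2,6
arc_compose,male,41,0,0
preauricular_sulcus,male,29,13,0
subpubic_angle,male,17,0,2
ilium_shape,male,28,4,3
nuchal_crest,male,26,2,5
mastoid_process,male,40,4,17
glabella,male,23,4,4
supraorbital_margin,male,34,19,12
frontal_bossing,male,11,8,8
zygomatic_arch_extension,male,45,5,8
forehead_inclination,male,21,3,2
mental_eminence,male,22,1,10
gonial_flaring,male,37,10,5
overall_mandible_shape,male,14,3,2
ventral_arc,female,21,0,0
ischiopubic_ramus,female,16,0,0
subpubic_concavity,female,19,0,0
sciatic_notch,female,25,1,5
arc_compose,female,18,7,4
preauricular_sulcus,female,24,6,0
subpubic_angle,female,18,0,0
ilium_shape,female,21,6,0
nuchal_crest,female,8,7,6
mastoid_process,female,26,6,11
glabella,female,13,4,4
supraorbital_margin,female,21,7,10
frontal_bossing,female,11,2,4
zygomatic_arch_extension,female,13,13,16
forehead_inclination,female,9,6,3
mental_eminence,female,18,0,4
gonial_flaring,female,15,13,12
overall_mandible_shape,female,13,4,1
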
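trait,sex,s1,s2,s3,s4,s5
ventral_arc,female,100.0,,0.0,,0.0
ventral_arc,male,5.0,,10.0,,85.0
ischiopubic_ramus,female,100.0,,0.0,,0.0
ischiopubic_ramus,male,0.0,,19.0,,81.0
subpubic_concavity,female,100.0,,0.0,,0.0
subpubic_concavity,male,0.0,,0.0,,100.0
sciatic_notch,female,26.3,52.6,15.8,0.0,5.3
sciatic_notch,male,0.0,7.4,14.8,48.1,29.6
arc_compose,female,38.9,22.2,11.1,11.1,16.7
arc_compose,male,0.0,0.0,0.0,4.3,95.7
preauricular_sulcus,female,15.8,21.1,5.3,42.1,15.8
preauricular_sulcus,male,0.0,3.8,0.0,26.9,69.2
subpubic_angle,female,80.0,20.0,0.0,0.0,0.0
subpubic_angle,male,0.0,0.0,8.3,8.3,83.3
ilium_shape,female,61.1,11.1,5.6,16.7,5.6
ilium_shape,male,0.0,8.7,13.0,17.4,60.9
nuchal_crest,female,19.0,14.3,33.3,33.3,0.0
nuchal_crest,male,0.0,6.1,15.2,57.6,21.2
mastoid_process,female,13.6,45.5,27.3,13.6,0.0
mastoid_process,male,0.0,6.0,24.3,39.3,30.4
glabella,female,19.0,42.9,19.0,19.0,0.0
glabella,male,0.0,12.9,12.9,48.4,25.8
supraorbital_margin,female,9.5,42.9,23.8,23.8,0.0
supraorbital_margin,male,4.3,30.4,26.1,69.6,13.0
frontal_bossing,female,64.7,,23.5,,11.8
frontal_bossing,male,29.6,,29.4,,40.7
zygomatic_arch_extension,female,4.8,23.8,42.9,19.0,9.5
zygomatic_arch_extension,male,6.7,3.3,16.7,40.0,33.3
forehead_inclination,female,50.0,,16.7,,33.3
forehead_inclination,male,11.5,,7.7,,80.8
mental_eminence,female,18.2,63.6,18.2,0.0,0.0
mental_eminence,male,0.0,3.4,34.5,41.4,34.5
gonial_flaring,female,9.5,28.6,28.6,33.3,0.0
gonial_flaring,male,0.0,21.4,10.7,42.9,25.0
overall_mandible_shape,female,72.2,,5.6,,22.2
overall_mandible_shape,male,12.0,,8.0,,80.0
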
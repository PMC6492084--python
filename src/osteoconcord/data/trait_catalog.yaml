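# Default 18-trait catalogue: element, native scoring scale, Phenice flag
# and the preauricular-sulcus presence/absence classification.
traits:
  ventral_arc:              {element: os_coxae, scale: three_point, phenice: true}
  ischiopubic_ramus:        {element: os_coxae, scale: three_point, phenice: true}
  subpubic_concavity:       {element: os_coxae, scale: three_point, phenice: true}
  preauricular_sulcus:      {element: os_coxae, scale: five_point, presence_map: true}
  sciatic_notch:            {element: os_coxae, scale: five_point}
  subpubic_angle:           {element: os_coxae, scale: five_point}
  arc_compose:              {element: os_coxae, scale: wea_five_point}
  ilium_shape:              {element: os_coxae, scale: wea_five_point}
  nuchal_crest:             {element: skull, scale: five_point}
  mastoid_process:          {element: skull, scale: five_point}
  glabella:                 {element: skull, scale: five_point}
  supraorbital_margin:      {element: skull, scale: five_point}
  mental_eminence:          {element: skull, scale: five_point}
  zygomatic_arch_extension: {element: skull, scale: five_point}
  frontal_bossing:          {element: skull, scale: three_point}
  forehead_inclination:     {element: skull, scale: three_point}
  overall_mandible_shape:   {element: skull, scale: three_point}
  gonial_flaring:           {element: skull, scale: wea_five_point}
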
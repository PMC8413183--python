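{
  "version": "1.0",
  "findings": [
    {"code": "anterior_chamber_cells", "gradable": true,
     "description": "Cells in the anterior chamber"},
    {"code": "vitreous_cells_anterior", "gradable": true,
     "description": "Cells in the anterior vitreous"},
    {"code": "stellate_keratic_precipitates", "gradable": false,
     "description": "Stellate keratic precipitates on the corneal endothelium"},
    {"code": "heterochromia", "gradable": false,
     "description": "Iris heterochromia"},
    {"code": "diffuse_iris_atrophy", "gradable": false,
     "description": "Diffuse (unilateral) iris atrophy"},
    {"code": "endotheliitis", "gradable": false,
     "description": "Corneal endotheliitis"},
    {"code": "coin_shaped_endothelial_lesions", "gradable": false,
     "description": "Nodular, coin-shaped endothelial lesions"},
    {"code": "active_retinitis", "gradable": false,
     "description": "Any active retinitis"},
    {"code": "necrotizing_retinitis_peripheral", "gradable": false,
     "description": "Necrotizing retinitis involving the peripheral retina"},
    {"code": "confluent_retinitis", "gradable": false,
     "description": "Circumferential or confluent retinitis"},
    {"code": "retinal_vascular_sheathing_or_occlusion", "gradable": false,
     "description": "Retinal vascular sheathing and/or occlusion"},
    {"code": "more_than_minimal_vitritis", "gradable": false,
     "description": "More than minimal vitreous inflammation"},
    {"code": "morphologic_evidence_multiple_infections", "gradable": false,
     "description": "Morphologic evidence of more than one intraocular infection"},
    {"code": "posterior_synechiae", "gradable": false,
     "description": "Posterior synechiae (generic descriptor)"},
    {"code": "macular_edema", "gradable": false,
     "description": "Macular edema (generic descriptor)"},
    {"code": "ocular_hypertension", "gradable": false,
     "description": "Elevated intraocular pressure (generic descriptor)"}
  ],
  "tests": [
    {"code": "hla_b27", "description": "HLA-B27 typing"},
    {"code": "asas_spondyloarthritis",
     "description": "ASAS-defined spondyloarthritis, axial or peripheral"},
    {"code": "syphilis_serology_treponemal",
     "description": "Treponemal syphilis serology"},
    {"code": "pcr_aqueous_cmv", "description": "Aqueous humor PCR for CMV"},
    {"code": "pcr_aqueous_hsv", "description": "Aqueous humor PCR for HSV"},
    {"code": "pcr_aqueous_vzv", "description": "Aqueous humor PCR for VZV"},
    {"code": "pcr_vitreous_hsv", "description": "Vitreous specimen PCR for HSV"},
    {"code": "pcr_vitreous_vzv", "description": "Vitreous specimen PCR for VZV"},
    {"code": "pcr_intraocular_cmv", "description": "Intraocular specimen PCR for CMV"},
    {"code": "pcr_intraocular_toxoplasma",
     "description": "Intraocular specimen PCR for Toxoplasma gondii"},
    {"code": "pcr_intraocular_hsv", "description": "Intraocular specimen PCR for HSV"},
    {"code": "pcr_intraocular_vzv", "description": "Intraocular specimen PCR for VZV"},
    {"code": "chest_xray_bilateral_hilar_adenopathy",
     "description": "Bilateral hilar adenopathy on chest x-ray"},
    {"code": "biopsy_noncaseating_granulomas",
     "description": "Tissue biopsy demonstrating noncaseating granulomas"},
    {"code": "immunocompromised", "description": "Immunocompromise of the host"}
  ]
}
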
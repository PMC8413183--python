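{
  "disease_id": "fuchs_uveitis",
  "disease_name": "Fuchs uveitis syndrome",
  "anatomic_class": "anterior",
  "criteria": {
    "and": [
      {
        "label": "1",
        "and": [
          {"label": "1a", "finding": "anterior_chamber_cells", "is": "present"},
          {
            "label": "1b",
            "or": [
              {"finding": "vitreous_cells_anterior", "is": "absent"},
              {"finding": "anterior_chamber_cells", "is": "present"}
            ]
          },
          {"label": "1c", "finding": "active_retinitis", "is": "absent"}
        ]
      },
      {"label": "2", "laterality_in": ["unilateral"]},
      {
        "label": "3",
        "or": [
          {"label": "3a", "finding": "heterochromia", "is": "present"},
          {
            "label": "3b",
            "and": [
              {"finding": "diffuse_iris_atrophy", "is": "present"},
              {"finding": "stellate_keratic_precipitates", "is": "present"}
            ]
          }
        ]
      },
      {
        "label": "4",
        "and": [
          {"finding": "endotheliitis", "is": "absent"},
          {"finding": "coin_shaped_endothelial_lesions", "is": "absent"}
        ]
      }
    ]
  },
  "exclusions": [
    {"label": "E1", "test": "syphilis_serology_treponemal", "is": "positive"},
    {
      "label": "E2",
      "or": [
        {"test": "chest_xray_bilateral_hilar_adenopathy", "is": "positive"},
        {"test": "biopsy_noncaseating_granulomas", "is": "positive"}
      ]
    },
    {
      "label": "E3",
      "or": [
        {"test": "pcr_aqueous_cmv", "is": "positive"},
        {"test": "pcr_aqueous_hsv", "is": "positive"},
        {"test": "pcr_aqueous_vzv", "is": "positive"}
      ]
    }
  ],
  "provenance": "SUN Working Group classification criteria, anterior uveitis stratum"
}
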
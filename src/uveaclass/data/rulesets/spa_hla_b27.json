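{
  "disease_id": "spa_hla_b27",
  "disease_name": "Spondyloarthritis/HLA-B27-associated anterior uveitis",
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
              {"grade_lt": ["vitreous_cells_anterior", "anterior_chamber_cells"]}
            ]
          }
        ]
      },
      {
        "or": [
          {
            "and": [
              {
                "label": "2",
                "or": [
                  {
                    "label": "2a",
                    "and": [
                      {"course_in": ["acute", "recurrent_acute"]},
                      {"laterality_in": ["unilateral", "alternating_unilateral"]}
                    ]
                  },
                  {
                    "label": "2b",
                    "and": [
                      {"course_in": ["chronic_after_recurrent_acute"]},
                      {"laterality_in": ["unilateral", "alternating_unilateral"]}
                    ]
                  }
                ]
              },
              {
                "label": "3",
                "or": [
                  {"test": "asas_spondyloarthritis", "is": "positive"},
                  {"test": "hla_b27", "is": "positive"}
                ]
              }
            ]
          },
          {
            "label": "4",
            "and": [
              {"course_in": ["chronic", "chronic_after_recurrent_acute"]},
              {"test": "asas_spondyloarthritis", "is": "positive"},
              {"test": "hla_b27", "is": "positive"}
            ]
          }
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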
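{
  "disease_id": "arn",
  "disease_name": "Acute retinal necrosis",
  "anatomic_class": "infectious_post_pan",
  "criteria": {
    "and": [
      {"label": "1", "finding": "necrotizing_retinitis_peripheral", "is": "present"},
      {
        "or": [
          {
            "label": "2",
            "or": [
              {"test": "pcr_aqueous_hsv", "is": "positive"},
              {"test": "pcr_aqueous_vzv", "is": "positive"},
              {"test": "pcr_vitreous_hsv", "is": "positive"},
              {"test": "pcr_vitreous_vzv", "is": "positive"}
            ]
          },
          {
            "label": "3",
            "and": [
              {"label": "3a", "finding": "confluent_retinitis", "is": "present"},
              {"label": "3b", "finding": "retinal_vascular_sheathing_or_occlusion", "is": "present"},
              {"label": "3c", "finding": "more_than_minimal_vitritis", "is": "present"}
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
      "and": [
        {
          "or": [
            {"test": "pcr_intraocular_cmv", "is": "positive"},
            {"test": "pcr_intraocular_toxoplasma", "is": "positive"}
          ]
        },
        {
          "not": {
            "and": [
              {"test": "immunocompromised", "is": "positive"},
              {"finding": "morphologic_evidence_multiple_infections", "is": "present"},
              {"finding": "confluent_retinitis", "is": "present"},
              {"finding": "retinal_vascular_sheathing_or_occlusion", "is": "present"},
              {"finding": "more_than_minimal_vitritis", "is": "present"},
              {
                "or": [
                  {"test": "pcr_intraocular_hsv", "is": "positive"},
                  {"test": "pcr_intraocular_vzv", "is": "positive"}
                ]
              }
            ]
          }
        }
      ]
    }
  ],
  "provenance": "SUN Working Group classification criteria, infectious posterior/panuveitis stratum"
}
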
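"""Clinical vignette fixtures: at least one positive and one negative case
per numbered criteria item and per exclusion item of the three shipped rule
sets.  Each vignette asserts the verdict of exactly one rule set.
"""

from uveaclass.clinical_vocab import (
    AnatomicClass,
    CaseRecord,
    Course,
    Finding,
    Laterality,
    TestResult,
    TestState,
    TriState,
)

_COUNTER = [0]


def make_case(
    anatomic: str = "anterior",
    course: str = "unknown",
    laterality: str = "unknown",
    findings: dict | None = None,
    tests: dict | None = None,
) -> CaseRecord:
    """Build a case from compact state maps.  Finding states: "present",
    "absent", or ("present", grade); test states: "positive"/"negative".
    Unmentioned fields stay unknown."""
    fs = {}
    for code, state in (findings or {}).items():
        if isinstance(state, tuple):
            fs[code] = Finding(code, TriState.PRESENT, state[1])
        else:
            fs[code] = Finding(code, TriState(state))
    ts = {code: TestResult(code, TestState(v)) for code, v in (tests or {}).items()}
    _COUNTER[0] += 1
    return CaseRecord(
        f"vignette-{_COUNTER[0]:03d}",
        AnatomicClass(anatomic),
        Course(course),
        Laterality(laterality),
        fs,
        ts,
    )


def _spa(**over):
    base = dict(
        course="recurrent_acute",
        laterality="unilateral",
        findings={
            "anterior_chamber_cells": ("present", 2),
            "vitreous_cells_anterior": "absent",
        },
        tests={
            "hla_b27": "positive",
            "asas_spondyloarthritis": "negative",
            "syphilis_serology_treponemal": "negative",
            "chest_xray_bilateral_hilar_adenopathy": "negative",
            "biopsy_noncaseating_granulomas": "negative",
            "pcr_aqueous_cmv": "negative",
            "pcr_aqueous_hsv": "negative",
            "pcr_aqueous_vzv": "negative",
        },
    )
    for key in ("findings", "tests"):
        if key in over:
            merged = dict(base[key])
            merged.update(over.pop(key))
            base[key] = merged
    base.update(over)
    return make_case(anatomic="anterior", **base)


def _fuchs(**over):
    base = dict(
        course="chronic",
        laterality="unilateral",
        findings={
            "anterior_chamber_cells": ("present", 1),
            "vitreous_cells_anterior": "absent",
            "active_retinitis": "absent",
            "heterochromia": "present",
            "endotheliitis": "absent",
            "coin_shaped_endothelial_lesions": "absent",
        },
        tests={
            "syphilis_serology_treponemal": "negative",
            "chest_xray_bilateral_hilar_adenopathy": "negative",
            "biopsy_noncaseating_granulomas": "negative",
            "pcr_aqueous_cmv": "negative",
            "pcr_aqueous_hsv": "negative",
            "pcr_aqueous_vzv": "negative",
        },
    )
    for key in ("findings", "tests"):
        if key in over:
            merged = dict(base[key])
            merged.update(over.pop(key))
            base[key] = merged
    base.update(over)
    return make_case(anatomic="anterior", **base)


def _arn(**over):
    # item-3 clinical-picture fields deliberately left unknown in the base:
    # a positive PCR classifies on its own
    base = dict(
        findings={"necrotizing_retinitis_peripheral": "present"},
        tests={
            "pcr_aqueous_hsv": "positive",
            "pcr_aqueous_vzv": "negative",
            "pcr_vitreous_hsv": "negative",
            "pcr_vitreous_vzv": "negative",
            "syphilis_serology_treponemal": "negative",
            "pcr_intraocular_cmv": "negative",
            "pcr_intraocular_toxoplasma": "negative",
        },
    )
    for key in ("findings", "tests"):
        if key in over:
            merged = dict(base[key])
            merged.update(over.pop(key))
            base[key] = merged
    base.update(over)
    return make_case(anatomic="infectious_post_pan", **base)


# (ruleset_id, item, expected_verdict, case)
VIGNETTES = [
    # ---------------- SpA/HLA-B27 anterior uveitis ----------------
    ("spa_hla_b27", "1a+", "classified", _spa()),
    ("spa_hla_b27", "1a-", "criteria_not_met",
     _spa(findings={"anterior_chamber_cells": "absent"})),
    ("spa_hla_b27", "1b+", "classified",
     _spa(findings={"vitreous_cells_anterior": ("present", 1)})),
    ("spa_hla_b27", "1b-", "criteria_not_met",
     _spa(findings={"vitreous_cells_anterior": ("present", 3)})),
    ("spa_hla_b27", "2a+", "classified", _spa(course="acute")),
    ("spa_hla_b27", "2a-", "criteria_not_met",
     _spa(course="chronic")),  # chronic + HLA-B27 alone reaches neither #2 nor #4
    ("spa_hla_b27", "2b+", "classified",
     _spa(course="chronic_after_recurrent_acute", laterality="alternating_unilateral")),
    ("spa_hla_b27", "2b-", "criteria_not_met",
     _spa(course="chronic_after_recurrent_acute", laterality="bilateral")),
    ("spa_hla_b27", "3+", "classified",
     _spa(tests={"hla_b27": "negative", "asas_spondyloarthritis": "positive"})),
    ("spa_hla_b27", "3-", "criteria_not_met",
     _spa(tests={"hla_b27": "negative", "asas_spondyloarthritis": "negative"})),
    ("spa_hla_b27", "4+", "classified",
     _spa(course="chronic", laterality="bilateral",
          tests={"asas_spondyloarthritis": "positive"})),
    ("spa_hla_b27", "4-", "criteria_not_met",
     _spa(course="chronic", laterality="bilateral",
          tests={"asas_spondyloarthritis": "negative"})),
    ("spa_hla_b27", "E1+", "excluded",
     _spa(tests={"syphilis_serology_treponemal": "positive"})),
    ("spa_hla_b27", "E1-", "classified", _spa()),
    ("spa_hla_b27", "E2+", "excluded",
     _spa(tests={"chest_xray_bilateral_hilar_adenopathy": "positive"})),
    ("spa_hla_b27", "E2+biopsy", "excluded",
     _spa(tests={"biopsy_noncaseating_granulomas": "positive"})),
    ("spa_hla_b27", "E2-", "classified", _spa()),
    ("spa_hla_b27", "E3+", "excluded", _spa(tests={"pcr_aqueous_hsv": "positive"})),
    ("spa_hla_b27", "E3-", "classified", _spa()),
    # ---------------- Fuchs uveitis syndrome ----------------
    ("fuchs_uveitis", "1a+", "classified", _fuchs()),
    ("fuchs_uveitis", "1a-", "criteria_not_met",
     _fuchs(findings={"anterior_chamber_cells": "absent"})),
    ("fuchs_uveitis", "1b+", "classified",
     _fuchs(findings={"vitreous_cells_anterior": ("present", 1)})),
    ("fuchs_uveitis", "1b-", "criteria_not_met",
     _fuchs(findings={"anterior_chamber_cells": "absent",
                      "vitreous_cells_anterior": ("present", 2)})),
    ("fuchs_uveitis", "1c+", "classified", _fuchs()),
    ("fuchs_uveitis", "1c-", "criteria_not_met",
     _fuchs(findings={"active_retinitis": "present"})),
    ("fuchs_uveitis", "2+", "classified", _fuchs(laterality="unilateral")),
    ("fuchs_uveitis", "2-", "criteria_not_met", _fuchs(laterality="bilateral")),
    # heterochromia alone classifies even with the iris-atrophy/KP branch unknown
    ("fuchs_uveitis", "3a+", "classified", _fuchs()),
    ("fuchs_uveitis", "3a-", "criteria_not_met",
     _fuchs(findings={"heterochromia": "absent", "diffuse_iris_atrophy": "absent"})),
    ("fuchs_uveitis", "3b+", "classified",
     _fuchs(findings={"heterochromia": "absent", "diffuse_iris_atrophy": "present",
                      "stellate_keratic_precipitates": "present"})),
    ("fuchs_uveitis", "3b-", "criteria_not_met",
     _fuchs(findings={"heterochromia": "absent", "diffuse_iris_atrophy": "present",
                      "stellate_keratic_precipitates": "absent"})),
    ("fuchs_uveitis", "4+", "classified", _fuchs()),
    ("fuchs_uveitis", "4-endotheliitis", "criteria_not_met",
     _fuchs(findings={"endotheliitis": "present"})),
    ("fuchs_uveitis", "4-coin", "criteria_not_met",
     _fuchs(findings={"coin_shaped_endothelial_lesions": "present"})),
    ("fuchs_uveitis", "E1+", "excluded",
     _fuchs(tests={"syphilis_serology_treponemal": "positive"})),
    ("fuchs_uveitis", "E1-", "classified", _fuchs()),
    ("fuchs_uveitis", "E2+", "excluded",
     _fuchs(tests={"chest_xray_bilateral_hilar_adenopathy": "positive"})),
    ("fuchs_uveitis", "E2-", "classified", _fuchs()),
    ("fuchs_uveitis", "E3+", "excluded", _fuchs(tests={"pcr_aqueous_cmv": "positive"})),
    ("fuchs_uveitis", "E3-", "classified", _fuchs()),
    # ---------------- Acute retinal necrosis ----------------
    ("arn", "1+", "classified", _arn()),
    ("arn", "1-", "criteria_not_met",
     _arn(findings={"necrotizing_retinitis_peripheral": "absent"})),
    # positive PCR classifies even with item-3 clinical fields unknown
    ("arn", "2+", "classified", _arn()),
    ("arn", "2+vitreous", "classified",
     _arn(tests={"pcr_aqueous_hsv": "negative", "pcr_vitreous_vzv": "positive"})),
    ("arn", "2-", "criteria_not_met",
     _arn(tests={"pcr_aqueous_hsv": "negative"},
          findings={"confluent_retinitis": "absent",
                    "retinal_vascular_sheathing_or_occlusion": "absent",
                    "more_than_minimal_vitritis": "absent"})),
    ("arn", "3a+", "classified",
     _arn(tests={"pcr_aqueous_hsv": "negative"},
          findings={"confluent_retinitis": "present",
                    "retinal_vascular_sheathing_or_occlusion": "present",
                    "more_than_minimal_vitritis": "present"})),
    ("arn", "3a-", "criteria_not_met",
     _arn(tests={"pcr_aqueous_hsv": "negative"},
          findings={"confluent_retinitis": "absent",
                    "retinal_vascular_sheathing_or_occlusion": "present",
                    "more_than_minimal_vitritis": "present"})),
    ("arn", "3b-", "criteria_not_met",
     _arn(tests={"pcr_aqueous_hsv": "negative"},
          findings={"confluent_retinitis": "present",
                    "retinal_vascular_sheathing_or_occlusion": "absent",
                    "more_than_minimal_vitritis": "present"})),
    ("arn", "3c-", "criteria_not_met",
     _arn(tests={"pcr_aqueous_hsv": "negative"},
          findings={"confluent_retinitis": "present",
                    "retinal_vascular_sheathing_or_occlusion": "present",
                    "more_than_minimal_vitritis": "absent"})),
    ("arn", "E1+", "excluded",
     _arn(tests={"syphilis_serology_treponemal": "positive"})),
    ("arn", "E1-", "classified", _arn()),
    ("arn", "E2+cmv", "excluded",
     _arn(tests={"pcr_intraocular_cmv": "positive", "immunocompromised": "negative"})),
    ("arn", "E2+toxo", "excluded",
     _arn(tests={"pcr_intraocular_toxoplasma": "positive",
                 "immunocompromised": "negative"})),
    # escape clause: immunocompromised host, >1 infection morphologically,
    # characteristic clinical picture, intraocular HSV/VZV PCR positive
    ("arn", "E2-escape", "classified",
     _arn(tests={"pcr_intraocular_cmv": "positive",
                 "immunocompromised": "positive",
                 "pcr_intraocular_hsv": "positive"},
          findings={"morphologic_evidence_multiple_infections": "present",
                    "confluent_retinitis": "present",
                    "retinal_vascular_sheathing_or_occlusion": "present",
                    "more_than_minimal_vitritis": "present"})),
    ("arn", "E2-", "classified", _arn()),
]
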
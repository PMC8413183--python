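import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uveaclass.clinical_vocab import TriState
from uveaclass.criteria_engine import (
    And,
    DomainTooLargeError,
    DslError,
    FindingIs,
    K,
    Not,
    Or,
    TestIs,
    Verdict,
    case_from_assignment,
    classify_case,
    enumerate_assignments,
    eval_expr,
    expr_equivalent,
    expr_from_dict,
    expr_to_dict,
    k_and,
    k_not,
    k_or,
    load_ruleset,
    referenced_fields,
    ruleset_from_dict,
    ruleset_to_dict,
    save_ruleset,
)

from strategies import exprs as expr_strategy
from strategies import rulesets as ruleset_strategy
from vignettes import make_case


class TestKleene:
    """Strong Kleene truth tables."""

    def test_or_t_u_is_t(self):
        assert k_or([K.T, K.U]) is K.T

    def test_and_t_u_is_u(self):
        assert k_and([K.T, K.U]) is K.U

    def test_not_u_is_u(self):
        assert k_not(K.U) is K.U

    @pytest.mark.parametrize("a", list(K))
    @pytest.mark.parametrize("b", list(K))
    def test_de_morgan(self, a, b):
        assert k_not(k_and([a, b])) is k_or([k_not(a), k_not(b)])

    def test_unknown_leaf_yields_u(self):
        case = make_case()
        assert eval_expr(FindingIs("heterochromia", "present"), case) is K.U

    def test_all_unknown_case_evaluates_u(self, spa, fuchs, arn):
        case = make_case()
        for rs in (spa, fuchs, arn):
            assert eval_expr(rs.criteria, case) is K.U


class TestClassify:
    def test_spa_classic_presentation(self, spa):
        case = make_case(
            course="recurrent_acute",
            laterality="unilateral",
            findings={"anterior_chamber_cells": ("present", 2),
                      "vitreous_cells_anterior": "absent"},
            tests={"hla_b27": "positive",
                   "syphilis_serology_treponemal": "negative",
                   "chest_xray_bilateral_hilar_adenopathy": "negative",
                   "biopsy_noncaseating_granulomas": "negative",
                   "pcr_aqueous_cmv": "negative",
                   "pcr_aqueous_hsv": "negative",
                   "pcr_aqueous_vzv": "negative"},
        )
        result = classify_case(case, [spa])
        assert result.final_labels == {"spa_hla_b27"}

    def test_fuchs_heterochromia_branch(self, fuchs):
        case = make_case(
            laterality="unilateral",
            findings={"anterior_chamber_cells": ("present", 1),
                      "vitreous_cells_anterior": "absent",
                      "active_retinitis": "absent",
                      "heterochromia": "present",
                      "endotheliitis": "absent",
                      "coin_shaped_endothelial_lesions": "absent"},
            tests={"syphilis_serology_treponemal": "negative",
                   "chest_xray_bilateral_hilar_adenopathy": "negative",
                   "biopsy_noncaseating_granulomas": "negative",
                   "pcr_aqueous_cmv": "negative",
                   "pcr_aqueous_hsv": "negative",
                   "pcr_aqueous_vzv": "negative"},
        )
        assert classify_case(case, [fuchs]).final_labels == {"fuchs_uveitis"}

    def test_arn_pcr_route_with_item3_unknown(self, arn):
        case = make_case(
            anatomic="infectious_post_pan",
            findings={"necrotizing_retinitis_peripheral": "present"},
            tests={"pcr_aqueous_hsv": "positive",
                   "syphilis_serology_treponemal": "negative",
                   "pcr_intraocular_cmv": "negative",
                   "pcr_intraocular_toxoplasma": "negative"},
        )
        assert classify_case(case, [arn]).final_labels == {"arn"}

    def test_spa_syphilis_exclusion_dominates(self, spa):
        case = make_case(
            course="acute",
            laterality="unilateral",
            findings={"anterior_chamber_cells": ("present", 2),
                      "vitreous_cells_anterior": "absent"},
            tests={"hla_b27": "positive",
                   "syphilis_serology_treponemal": "positive"},
        )
        assert classify_case(case, [spa]).verdicts["spa_hla_b27"] is Verdict.EXCLUDED

    def test_arn_cmv_exclusion_in_immunocompetent(self, arn):
        case = make_case(
            anatomic="infectious_post_pan",
            findings={"necrotizing_retinitis_peripheral": "present"},
            tests={"pcr_aqueous_hsv": "positive",
                   "pcr_intraocular_cmv": "positive",
                   "immunocompromised": "negative"},
        )
        assert classify_case(case, [arn]).verdicts["arn"] is Verdict.EXCLUDED

    def test_empty_case_never_classifies(self, all_rulesets):
        result = classify_case(make_case(), all_rulesets)
        assert result.final_labels == frozenset()
        for verdict in result.verdicts.values():
            assert verdict in (Verdict.INDETERMINATE, Verdict.CRITERIA_NOT_MET)

    def test_trace_covers_labeled_items(self, spa):
        result = classify_case(make_case(), [spa])
        trace = result.trace["spa_hla_b27"]
        for item in ("1", "1a", "1b", "2", "3", "4", "E1", "E2", "E3"):
            assert item in trace["items"]

    def test_determinism(self, all_rulesets):
        case = make_case(findings={"heterochromia": "present"})
        r1 = classify_case(case, all_rulesets)
        r2 = classify_case(case, all_rulesets)
        assert r1.verdicts == r2.verdicts and r1.trace == r2.trace


class TestDsl:
    def test_shipped_spa_structure(self, spa):
        assert isinstance(spa.criteria, And)
        assert len(spa.exclusions) == 3

    def test_roundtrip_shipped(self, tmp_path, all_rulesets):
        for rs in all_rulesets:
            path = tmp_path / f"{rs.disease_id}.json"
            save_ruleset(rs, path)
            assert load_ruleset(path) == rs

    def test_unknown_code_rejected_with_path(self, spa):
        doc = ruleset_to_dict(spa)
        doc["criteria"]["and"][0]["and"][0]["finding"] = "made_up_sign"
        with pytest.raises(DslError, match=r"\$\.criteria.*made_up_sign"):
            ruleset_from_dict(doc)

    def test_malformed_connective_rejected(self, vocab):
        with pytest.raises(DslError, match="non-empty"):
            expr_from_dict({"and": []}, vocab)

    def test_unrecognized_node_rejected(self, vocab):
        with pytest.raises(DslError, match="unrecognized"):
            expr_from_dict({"frobnicate": 1}, vocab)


class TestEquivalence:
    def test_absorption_law(self):
        x = FindingIs("heterochromia", "present")
        y = FindingIs("endotheliitis", "present")
        assert expr_equivalent(Or((x, And((x, y)))), x)

    def test_negation_not_equivalent(self):
        x = TestIs("hla_b27", "positive")
        assert not expr_equivalent(x, Not(x))

    def test_spa_main_connective_vs_hand_dnf(self, spa):
        # criteria = item1 AND ((item2 AND item3) OR item4)
        item1, alternatives = spa.criteria.children
        both, item4 = alternatives.children
        dnf = Or((And((item1,) + both.children), And((item1, item4))))
        assert expr_equivalent(spa.criteria, dnf)

    def test_domain_too_large_refused(self):
        domain = {("test", f"t{i}"): ("positive", "negative", "unknown") for i in range(20)}
        with pytest.raises(DomainTooLargeError, match="assignments"):
            list(enumerate_assignments(domain, max_assignments=1000))


class TestProperties:
    def test_exclusion_dominance(self, all_rulesets):
        """Turning any exclusion true never leaves a case classified."""
        from vignettes import VIGNETTES

        excl_triggers = {
            "spa_hla_b27": ("syphilis_serology_treponemal", "pcr_aqueous_vzv"),
            "fuchs_uveitis": ("syphilis_serology_treponemal", "biopsy_noncaseating_granulomas"),
            "arn": ("syphilis_serology_treponemal",),
        }
        by_id = {rs.disease_id: rs for rs in all_rulesets}
        for rs_id, _, expected, case in VIGNETTES:
            if expected != "classified":
                continue
            for trigger in excl_triggers[rs_id]:
                mutated = make_case(
                    anatomic=case.anatomic_class.value,
                    course=case.course.value,
                    laterality=case.laterality.value,
                    findings={c: (f.value.value if f.grade is None else (f.value.value, f.grade))
                              for c, f in case.findings.items()
                              if f.value is not TriState.UNKNOWN},
                    tests={**{c: t.value.value for c, t in case.tests.items()
                              if t.value.value != "unknown"},
                           trigger: "positive"},
                )
                verdict = classify_case(mutated, [by_id[rs_id]]).verdicts[rs_id]
                assert verdict is Verdict.EXCLUDED

    @pytest.mark.parametrize("rs_name", ["spa", "fuchs", "arn"])
    def test_kleene_monotonicity_of_criteria(self, rs_name, request):
        """Resolving unknowns never flips a definite criteria value
        (the shipped criteria trees are negation-free)."""
        import numpy as np

        rs = request.getfixturevalue(rs_name)
        domain = referenced_fields(rs.criteria)
        keys = list(domain)
        rng = np.random.default_rng(42)
        for _ in range(300):
            partial, resolved = {}, {}
            for key in keys:
                states = domain[key]
                chosen = states[rng.integers(len(states))]
                if rng.random() < 0.4:
                    partial[key] = "unknown"
                    definite = [s for s in states if s != "unknown"]
                    resolved[key] = definite[rng.integers(len(definite))]
                else:
                    partial[key] = chosen
                    resolved[key] = chosen
            v1 = eval_expr(rs.criteria, case_from_assignment(partial, rs.anatomic_class))
            v2 = eval_expr(rs.criteria, case_from_assignment(resolved, rs.anatomic_class))
            if v1 is K.T:
                assert v2 is K.T
            if v1 is K.F:
                assert v2 is K.F


@settings(max_examples=100, deadline=None)
@given(expr=expr_strategy)
def test_expr_dict_roundtrip(expr):
    vocab = __import__("uveaclass.clinical_vocab", fromlist=["default_vocabulary"]).default_vocabulary()
    assert expr_from_dict(expr_to_dict(expr), vocab) == expr


@settings(max_examples=50, deadline=None)
@given(rs=ruleset_strategy, data=st.data())
def test_random_ruleset_verdict_matches_bruteforce(rs, data):
    """classify_case agrees with the independent truth-table oracle on
    randomly drawn rule sets and random cases."""
    from _bruteforce import bf_verdict

    doc = ruleset_to_dict(rs)
    domain = referenced_fields(rs.criteria, *rs.exclusions)
    assignment = {
        key: data.draw(st.sampled_from(states), label=str(key))
        for key, states in domain.items()
    }
    case = case_from_assignment(assignment, rs.anatomic_class)
    verdict = classify_case(case, [rs]).verdicts[rs.disease_id]
    assert verdict.value == bf_verdict(doc, assignment)
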
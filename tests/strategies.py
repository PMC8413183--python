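"""Hypothesis strategies for random rule expressions and rule sets."""

from hypothesis import strategies as st

from uveaclass.clinical_vocab import AnatomicClass, Course, Laterality, default_vocabulary
from uveaclass.criteria_engine import (
    And,
    Const,
    CourseIn,
    FindingIn,
    FindingIs,
    GradeGe,
    GradeLt,
    LateralityIn,
    Not,
    Or,
    RuleSet,
    TestIn,
    TestIs,
)

_VOCAB = default_vocabulary()
_FINDINGS = list(_VOCAB.finding_codes)
_TESTS = list(_VOCAB.test_codes)
_GRADABLE = sorted(_VOCAB.gradable)
_COURSES = [c.value for c in Course]
_LATERALITIES = [l.value for l in Laterality]

labels = st.none() | st.text("abcdefgh123", min_size=1, max_size=3)


def _subset(values):
    return st.lists(st.sampled_from(values), min_size=1, unique=True).map(tuple)


predicates = st.one_of(
    st.builds(FindingIs, st.sampled_from(_FINDINGS), st.sampled_from(["present", "absent"]), labels),
    st.builds(TestIs, st.sampled_from(_TESTS), st.sampled_from(["positive", "negative"]), labels),
    st.builds(CourseIn, _subset(_COURSES), st.booleans(), labels),
    st.builds(LateralityIn, _subset(_LATERALITIES), st.booleans(), labels),
    st.builds(GradeLt, st.sampled_from(_GRADABLE), st.sampled_from(_GRADABLE), labels),
    st.builds(GradeGe, st.sampled_from(_GRADABLE), st.integers(0, 4), labels),
    st.builds(FindingIn, st.sampled_from(_FINDINGS), _subset(["present", "absent", "unknown"]), labels),
    st.builds(TestIn, st.sampled_from(_TESTS), _subset(["positive", "negative", "unknown"]), labels),
    st.builds(Const, st.booleans(), labels),
)

exprs = st.recursive(
    predicates,
    lambda children: st.one_of(
        st.builds(And, st.lists(children, min_size=1, max_size=3).map(tuple), labels),
        st.builds(Or, st.lists(children, min_size=1, max_size=3).map(tuple), labels),
        st.builds(Not, children, labels),
    ),
    max_leaves=8,
)

rulesets = st.builds(
    RuleSet,
    disease_id=st.text("abcdefghij_", min_size=1, max_size=12),
    disease_name=st.text(min_size=0, max_size=20),
    anatomic_class=st.sampled_from(list(AnatomicClass)),
    criteria=exprs,
    exclusions=st.lists(exprs, max_size=3).map(tuple),
    provenance=st.text(max_size=30),
)
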
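"""Synthetic labeled case collections.

The real multi-disease uveitis case database behind the published
criteria is not public, so this module generates labeled cohorts from
rule sets: each case is constructed from a satisfying assignment of the
generating rule set's criteria tree (choosing OR branches uniformly at
random), with every exclusion-trigger atom forced negative, unreferenced
vocabulary fields drawn from configurable background frequencies, and
optional symmetric flip noise / missingness applied afterwards.

At ``flip_noise=0, missing_rate=0`` every generated case is classified
to its ``true_label`` by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .clinical_vocab import (
    CaseRecord,
    Cohort,
    Course,
    Finding,
    Laterality,
    TestResult,
    TestState,
    TriState,
    Vocabulary,
    default_vocabulary,
)
from .criteria_engine import (
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
    iter_predicates,
)
from .clinical_vocab import AnatomicClass

__all__ = [
    "CohortSpec",
    "UnsatisfiableRuleSetError",
    "sample_case",
    "generate_cohort",
    "demo_viral_anterior_ruleset",
]

_CONCRETE_COURSES = tuple(c.value for c in Course if c is not Course.UNKNOWN)
_CONCRETE_LATERALITIES = tuple(
    l.value for l in Laterality if l is not Laterality.UNKNOWN
)


class UnsatisfiableRuleSetError(ValueError):
    """The criteria tree admits no satisfying assignment."""


@dataclass
class CohortSpec:
    """Recipe for a synthetic cohort."""

    diseases: list[tuple[RuleSet, float]]
    n_cases: int
    flip_noise: float = 0.0
    missing_rate: float = 0.0
    train_fraction: float = 0.7
    seed: int = 0
    background_rate: float = 0.05
    background_overrides: dict[str, float] = dc_field(default_factory=dict)

    def validate(self) -> None:
        if not self.diseases:
            raise ValueError("at least one disease rule set is required")
        for rs, w in self.diseases:
            if not (np.isfinite(w) and w > 0):
                raise ValueError(f"weight for {rs.disease_id!r} must be positive/finite")
        for name in ("flip_noise", "missing_rate", "background_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError(
                f"train_fraction must lie strictly in (0, 1), got {self.train_fraction}"
            )
        if self.n_cases < 0:
            raise ValueError("n_cases must be non-negative")


# ---------------------------------------------------------------------------
# satisfying-assignment sampling
#
# Constraint context maps field keys (as in criteria_engine.referenced_fields)
# to required states.  Finding states: "present" | "absent" | "unknown" |
# ("present", grade).


def _merge(ctx: dict, key: tuple, state) -> Optional[dict]:
    cur = ctx.get(key)
    if cur is None:
        out = dict(ctx)
        out[key] = state
        return out
    if cur == state:
        return ctx
    # "present" is compatible with ("present", g) in either direction
    if key[0] == "finding":
        if cur == "present" and isinstance(state, tuple):
            out = dict(ctx)
            out[key] = state
            return out
        if isinstance(cur, tuple) and state == "present":
            return ctx
    return None


def _grade_of_state(state) -> Optional[int]:
    if state == "absent":
        return 0
    if isinstance(state, tuple):
        return state[1]
    return None  # "present" without grade yet, or "unknown"


def _satisfy(expr, ctx: dict, rng: np.random.Generator, want: bool) -> Optional[dict]:
    """Extend ctx so expr evaluates to T (want) / F (not want), or None."""
    if isinstance(expr, And):
        children = expr.children
        if want:
            for c in children:
                ctx = _satisfy(c, ctx, rng, True)
                if ctx is None:
                    return None
            return ctx
        for i in rng.permutation(len(children)):
            out = _satisfy(children[i], ctx, rng, False)
            if out is not None:
                return out
        return None
    if isinstance(expr, Or):
        children = expr.children
        if want:
            for i in rng.permutation(len(children)):
                out = _satisfy(children[i], ctx, rng, True)
                if out is not None:
                    return out
            return None
        for c in children:
            ctx = _satisfy(c, ctx, rng, False)
            if ctx is None:
                return None
        return ctx
    if isinstance(expr, Not):
        return _satisfy(expr.child, ctx, rng, not want)
    if isinstance(expr, FindingIs):
        target = expr.state if want else ("absent" if expr.state == "present" else "present")
        return _merge(ctx, ("finding", expr.code), target)
    if isinstance(expr, TestIs):
        target = expr.state if want else (
            "negative" if expr.state == "positive" else "positive"
        )
        return _merge(ctx, ("test", expr.code), target)
    if isinstance(expr, CourseIn):
        return _pick_enum(ctx, ("course",), expr.values, _CONCRETE_COURSES, rng, want)
    if isinstance(expr, LateralityIn):
        return _pick_enum(
            ctx, ("laterality",), expr.values, _CONCRETE_LATERALITIES, rng, want
        )
    if isinstance(expr, GradeLt):
        return _satisfy_grade_lt(expr, ctx, rng, want)
    if isinstance(expr, GradeGe):
        key = ("finding", expr.code)
        if want:
            g = max(expr.threshold, 1)
            if g > 4:
                return None
            return _merge(ctx, key, ("present", g))
        if expr.threshold <= 0:
            return None
        return _merge(ctx, key, "absent")
    if isinstance(expr, FindingIn):
        pool = expr.states if want else tuple(
            s for s in ("present", "absent", "unknown") if s not in expr.states
        )
        return _pick_state(ctx, ("finding", expr.code), pool, rng)
    if isinstance(expr, TestIn):
        pool = expr.states if want else tuple(
            s for s in ("positive", "negative", "unknown") if s not in expr.states
        )
        return _pick_state(ctx, ("test", expr.code), pool, rng)
    if isinstance(expr, Const):
        return ctx if expr.value == want else None
    raise TypeError(f"not a rule expression: {expr!r}")


def _pick_enum(ctx, key, values, concrete, rng, want) -> Optional[dict]:
    pool = tuple(values) if want else tuple(v for v in concrete if v not in values)
    if not pool:
        return None
    cur = ctx.get(key)
    if cur is not None:
        return ctx if cur in pool else None
    out = dict(ctx)
    out[key] = pool[rng.integers(len(pool))]
    return out


def _pick_state(ctx, key, pool, rng) -> Optional[dict]:
    if not pool:
        return None
    cur = ctx.get(key)
    if cur is not None:
        cur_plain = "present" if isinstance(cur, tuple) else cur
        return ctx if cur_plain in pool else None
    out = dict(ctx)
    out[key] = pool[rng.integers(len(pool))]
    return out


def _satisfy_grade_lt(expr: GradeLt, ctx, rng, want) -> Optional[dict]:
    lo_key, hi_key = ("finding", expr.lower), ("finding", expr.higher)
    if want:
        hi_state = ctx.get(hi_key)
        g_hi = _grade_of_state(hi_state) if hi_state is not None else None
        if hi_state in ("absent", "unknown"):
            return None
        if g_hi is None:
            g_hi = int(rng.integers(2, 4))  # 2 or 3
            ctx = _merge(ctx, hi_key, ("present", g_hi))
            if ctx is None:
                return None
        elif g_hi < 1:
            return None
        lo_state = ctx.get(lo_key)
        if lo_state is None:
            if rng.integers(2) == 0:
                return _merge(ctx, lo_key, "absent")
            return _merge(ctx, lo_key, ("present", int(rng.integers(1, g_hi))))
        if lo_state == "unknown":
            return None
        g_lo = _grade_of_state(lo_state)
        if g_lo is None:  # "present" without grade: assign one below g_hi
            if g_hi <= 1:
                return None
            return _merge(ctx, lo_key, ("present", int(rng.integers(1, g_hi))))
        return ctx if g_lo < g_hi else None
    # falsify: lower >= higher; simplest consistent choice is both absent
    ctx2 = _merge(ctx, lo_key, "absent")
    if ctx2 is not None:
        ctx2 = _merge(ctx2, hi_key, "absent")
        if ctx2 is not None:
            return ctx2
    ctx2 = _merge(ctx, lo_key, ("present", 2))
    if ctx2 is None:
        return None
    return _merge(ctx2, hi_key, ("present", 1))


def _suppress_exclusions(rs: RuleSet, ctx: dict) -> dict:
    """Force every positive-polarity exclusion-trigger atom negative, where
    not already pinned by the criteria assignment."""
    for excl in rs.exclusions:
        for pred, polarity in iter_predicates(excl):
            if polarity <= 0:
                continue
            if isinstance(pred, FindingIs):
                key = ("finding", pred.code)
                target = "absent" if pred.state == "present" else "present"
            elif isinstance(pred, TestIs):
                key = ("test", pred.code)
                target = "negative" if pred.state == "positive" else "positive"
            elif isinstance(pred, FindingIn):
                key = ("finding", pred.code)
                rest = [s for s in ("absent", "present") if s not in pred.states]
                if not rest:
                    continue
                target = rest[0]
            elif isinstance(pred, TestIn):
                key = ("test", pred.code)
                rest = [s for s in ("negative", "positive") if s not in pred.states]
                if not rest:
                    continue
                target = rest[0]
            else:
                continue  # course/laterality/grade exclusions: leave untouched
            if key not in ctx:
                ctx[key] = target
    return ctx


def sample_case(
    rs: RuleSet,
    rng: np.random.Generator,
    vocab: Optional[Vocabulary] = None,
    case_id: str = "case",
    background_rate: float = 0.05,
    background_overrides: Optional[dict[str, float]] = None,
) -> CaseRecord:
    """Draw one case satisfying ``rs`` (classified, pre-noise)."""
    vocab = vocab or default_vocabulary()
    overrides = background_overrides or {}
    # OR branches are chosen at random without full backtracking across
    # siblings, so retry with fresh draws before declaring unsatisfiability.
    ctx = None
    for _ in range(50):
        ctx = _satisfy(rs.criteria, {}, rng, True)
        if ctx is not None:
            break
    if ctx is None:
        raise UnsatisfiableRuleSetError(
            f"criteria of rule set {rs.disease_id!r} admit no satisfying assignment"
        )
    ctx = _suppress_exclusions(rs, dict(ctx))

    findings: dict[str, Finding] = {}
    tests: dict[str, TestResult] = {}
    for code in vocab.finding_codes:
        state = ctx.get(("finding", code))
        if state is None:
            rate = overrides.get(code, background_rate)
            state = "present" if rng.random() < rate else "absent"
        if isinstance(state, tuple):
            findings[code] = Finding(code, TriState.PRESENT, state[1])
        elif state == "present" and vocab.is_gradable(code):
            findings[code] = Finding(code, TriState.PRESENT, int(rng.integers(1, 4)))
        else:
            findings[code] = Finding(code, TriState(state))
    for code in vocab.test_codes:
        state = ctx.get(("test", code))
        if state is None:
            rate = overrides.get(code, background_rate)
            state = "positive" if rng.random() < rate else "negative"
        tests[code] = TestResult(code, TestState(state))

    course = ctx.get(("course",))
    if course is None:
        course = _CONCRETE_COURSES[rng.integers(len(_CONCRETE_COURSES))]
    lat = ctx.get(("laterality",))
    if lat is None:
        lat = _CONCRETE_LATERALITIES[rng.integers(len(_CONCRETE_LATERALITIES))]

    return CaseRecord(
        case_id=case_id,
        anatomic_class=rs.anatomic_class,
        course=Course(course),
        laterality=Laterality(lat),
        findings=findings,
        tests=tests,
        true_label=rs.disease_id,
    )


def _apply_noise(
    case: CaseRecord,
    rng: np.random.Generator,
    vocab: Vocabulary,
    flip_noise: float,
    missing_rate: float,
) -> CaseRecord:
    findings: dict[str, Finding] = {}
    for code, f in case.findings.items():
        value, grade = f.value, f.grade
        if flip_noise > 0 and value is not TriState.UNKNOWN and rng.random() < flip_noise:
            if value is TriState.PRESENT:
                value, grade = TriState.ABSENT, None
            else:
                value = TriState.PRESENT
                grade = int(rng.integers(1, 4)) if vocab.is_gradable(code) else None
        if missing_rate > 0 and rng.random() < missing_rate:
            value, grade = TriState.UNKNOWN, None
        findings[code] = Finding(code, value, grade)
    tests: dict[str, TestResult] = {}
    for code, t in case.tests.items():
        value = t.value
        if flip_noise > 0 and value is not TestState.UNKNOWN and rng.random() < flip_noise:
            value = (
                TestState.NEGATIVE if value is TestState.POSITIVE else TestState.POSITIVE
            )
        if missing_rate > 0 and rng.random() < missing_rate:
            value = TestState.UNKNOWN
        tests[code] = TestResult(code, value)
    return CaseRecord(
        case.case_id,
        case.anatomic_class,
        case.course,
        case.laterality,
        findings,
        tests,
        case.true_label,
    )


def generate_cohort(spec: CohortSpec, vocab: Optional[Vocabulary] = None) -> Cohort:
    """Generate a labeled cohort with a stratified train/validation split.

    Deterministic given ``spec.seed`` (integer-state generator; no reliance
    on hash ordering).
    """
    spec.validate()
    vocab = vocab or default_vocabulary()
    rng = np.random.default_rng(spec.seed)
    weights = np.array([w for _, w in spec.diseases], dtype=float)
    weights /= weights.sum()

    cases: list[CaseRecord] = []
    for i in range(spec.n_cases):
        idx = int(rng.choice(len(spec.diseases), p=weights))
        rs = spec.diseases[idx][0]
        case = sample_case(
            rs,
            rng,
            vocab,
            case_id=f"case-{i:05d}",
            background_rate=spec.background_rate,
            background_overrides=spec.background_overrides,
        )
        if spec.flip_noise > 0 or spec.missing_rate > 0:
            case = _apply_noise(case, rng, vocab, spec.flip_noise, spec.missing_rate)
        cases.append(case)

    split: dict[str, str] = {}
    by_label: dict[str, list[int]] = {}
    for i, c in enumerate(cases):
        by_label.setdefault(c.true_label, []).append(i)
    for label in sorted(by_label):
        idxs = by_label[label]
        order = rng.permutation(len(idxs))
        n_train = int(round(spec.train_fraction * len(idxs)))
        for rank, j in enumerate(order):
            split[cases[idxs[j]].case_id] = "train" if rank < n_train else "validation"

    cohort = Cohort(cases, split if cases else None)
    cohort.validate()
    return cohort


def derivation_demo_spec(
    n_cases: int = 600,
    seed: int = 0,
    flip_noise: float = 0.0,
    missing_rate: float = 0.0,
    train_fraction: float = 0.7,
    vocab: Optional[Vocabulary] = None,
) -> CohortSpec:
    """Three-class anterior cohort recipe for exercising the derivation
    pipeline (SpA/HLA-B27, Fuchs, demo viral anterior uveitis).

    Background frequencies are chosen so that, at zero noise, the classes
    are separable while every criteria atom stays informative: atoms a rule
    requires *positive* get zero background elsewhere (no mimics by
    chance), and atoms a rule requires *absent* keep a visible background
    so their indicator columns vary across classes.  These distributions
    are a testing device, not calibrated to any patient database.
    """
    from .criteria_engine import shipped_ruleset

    overrides = {
        # positively-required atoms: never present/positive by chance
        "anterior_chamber_cells": 0.0,
        "vitreous_cells_anterior": 0.0,
        "heterochromia": 0.0,
        "diffuse_iris_atrophy": 0.0,
        "stellate_keratic_precipitates": 0.0,
        "hla_b27": 0.0,
        "asas_spondyloarthritis": 0.0,
        "pcr_aqueous_hsv": 0.0,
        "pcr_aqueous_vzv": 0.0,
        "pcr_aqueous_cmv": 0.0,
        # absent-required atoms: visible background so columns vary
        "active_retinitis": 0.25,
        "endotheliitis": 0.25,
        "coin_shaped_endothelial_lesions": 0.25,
    }
    return CohortSpec(
        diseases=[
            (shipped_ruleset("spa_hla_b27", vocab), 1.0),
            (shipped_ruleset("fuchs_uveitis", vocab), 1.0),
            (demo_viral_anterior_ruleset(vocab), 1.0),
        ],
        n_cases=n_cases,
        flip_noise=flip_noise,
        missing_rate=missing_rate,
        train_fraction=train_fraction,
        seed=seed,
        background_rate=0.05,
        background_overrides=overrides,
    )


def demo_viral_anterior_ruleset(vocab: Optional[Vocabulary] = None) -> RuleSet:
    """A deliberately simple *demonstration* rule set for a third anterior
    disease (PCR-proven viral anterior uveitis), used to exercise the
    derivation pipeline on a three-class anterior stratum.

    Its content is invented for testing and is not a published criteria set.
    """
    return RuleSet(
        disease_id="viral_anterior_demo",
        disease_name="PCR-proven viral anterior uveitis (demo)",
        anatomic_class=AnatomicClass.ANTERIOR,
        criteria=And(
            (
                Or(
                    (
                        TestIs("pcr_aqueous_hsv", "positive"),
                        TestIs("pcr_aqueous_vzv", "positive"),
                    ),
                    label="1",
                ),
                CourseIn(("acute", "recurrent_acute"), label="2"),
            )
        ),
        exclusions=(TestIs("syphilis_serology_treponemal", "positive", label="E1"),),
        provenance="synthetic demonstration rule set (not a published criteria set)",
    )
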
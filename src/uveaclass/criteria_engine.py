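"""Boolean criteria engine with Kleene three-valued semantics.

Classification criteria are expression trees over tri-state clinical
atoms.  Evaluation follows strong Kleene logic (AND = min, OR = max under
F < U < T, NOT swaps T/F and fixes U) so that unknown findings propagate
rather than silently defaulting.  A :class:`RuleSet` pairs a criteria
tree with an ordered list of exclusion expressions; a true exclusion
dominates the verdict.

Verdict semantics (exclusions demand positive evidence, criteria demand
definite evidence):

* ``excluded``          -- some exclusion evaluates T
* ``classified``        -- not excluded and criteria evaluate T
* ``indeterminate``     -- not excluded and criteria evaluate U
* ``criteria_not_met``  -- not excluded and criteria evaluate F

Rule sets serialize to a small JSON DSL (see ``data/schemas/``); the
three rule sets printed for SpA/HLA-B27-associated anterior uveitis,
Fuchs uveitis syndrome and acute retinal necrosis ship as package data.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional, Union

from .clinical_vocab import (
    AnatomicClass,
    CaseRecord,
    Course,
    Finding,
    Laterality,
    TestResult,
    TestState,
    TriState,
    Vocabulary,
    default_vocabulary,
)

__all__ = [
    "K",
    "k_and",
    "k_or",
    "k_not",
    "FindingIs",
    "TestIs",
    "CourseIn",
    "LateralityIn",
    "GradeLt",
    "GradeGe",
    "FindingIn",
    "TestIn",
    "Const",
    "And",
    "Or",
    "Not",
    "RuleExpr",
    "RuleSet",
    "Verdict",
    "ClassificationResult",
    "DslError",
    "DomainTooLargeError",
    "eval_expr",
    "classify_case",
    "load_ruleset",
    "save_ruleset",
    "ruleset_from_dict",
    "ruleset_to_dict",
    "expr_from_dict",
    "expr_to_dict",
    "shipped_ruleset",
    "shipped_rulesets",
    "SHIPPED_RULESET_IDS",
    "expr_equivalent",
    "referenced_fields",
    "enumerate_assignments",
    "case_from_assignment",
    "iter_predicates",
]


class DslError(ValueError):
    """Rule DSL document violates the schema; message carries a JSON path."""


class DomainTooLargeError(ValueError):
    """Exhaustive enumeration refused because the domain is too large."""


class K(Enum):
    """Kleene truth value, ordered F < U < T."""

    F = 0
    U = 1
    T = 2


def k_and(values) -> K:
    return min(values, key=lambda v: v.value, default=K.T)


def k_or(values) -> K:
    return max(values, key=lambda v: v.value, default=K.F)


def k_not(v: K) -> K:
    return K(2 - v.value)


def _from_bool(b: bool) -> K:
    return K.T if b else K.F


# ---------------------------------------------------------------------------
# expression nodes
#
# Every node carries an optional `label` used only for the evaluation trace
# (so printed table item numbers like "1b" can be referenced in verdicts).


@dataclass(frozen=True)
class FindingIs:
    """Finding has a definite value; unknown yields U."""

    code: str
    state: str  # "present" | "absent"
    label: Optional[str] = None


@dataclass(frozen=True)
class TestIs:
    code: str
    state: str  # "positive" | "negative"
    label: Optional[str] = None


@dataclass(frozen=True)
class CourseIn:
    values: tuple[str, ...]
    closed: bool = False  # closed world: unknown is just another value
    label: Optional[str] = None


@dataclass(frozen=True)
class LateralityIn:
    values: tuple[str, ...]
    closed: bool = False
    label: Optional[str] = None


@dataclass(frozen=True)
class GradeLt:
    """Severity of `lower` is strictly less than severity of `higher`.

    Effective grades: recorded grade when present, 0 when absent, undefined
    (U) when the finding or its grade is unknown.
    """

    lower: str
    higher: str
    label: Optional[str] = None


@dataclass(frozen=True)
class GradeGe:
    """Closed-world ordinal threshold: effective grade >= threshold.

    Undefined grades count as 0, mirroring the cumulative grade encoding of
    the feature matrix; evaluation is always determinate.
    """

    code: str
    threshold: int
    label: Optional[str] = None


@dataclass(frozen=True)
class FindingIn:
    """Closed-world membership over {present, absent, unknown}; never U."""

    code: str
    states: tuple[str, ...]
    label: Optional[str] = None


@dataclass(frozen=True)
class TestIn:
    code: str
    states: tuple[str, ...]
    label: Optional[str] = None


@dataclass(frozen=True)
class Const:
    value: bool
    label: Optional[str] = None


@dataclass(frozen=True)
class And:
    children: tuple["RuleExpr", ...]
    label: Optional[str] = None


@dataclass(frozen=True)
class Or:
    children: tuple["RuleExpr", ...]
    label: Optional[str] = None


@dataclass(frozen=True)
class Not:
    child: "RuleExpr"
    label: Optional[str] = None


Predicate = Union[
    FindingIs, TestIs, CourseIn, LateralityIn, GradeLt, GradeGe, FindingIn, TestIn, Const
]
RuleExpr = Union[Predicate, And, Or, Not]

_PRED_TYPES = (
    FindingIs,
    TestIs,
    CourseIn,
    LateralityIn,
    GradeLt,
    GradeGe,
    FindingIn,
    TestIn,
    Const,
)


# ---------------------------------------------------------------------------
# evaluation


def eval_expr(
    expr: RuleExpr, case: CaseRecord, trace: Optional[dict[str, K]] = None
) -> K:
    """Evaluate an expression over a case under strong Kleene semantics."""
    if isinstance(expr, And):
        v = k_and(eval_expr(c, case, trace) for c in expr.children)
    elif isinstance(expr, Or):
        v = k_or(eval_expr(c, case, trace) for c in expr.children)
    elif isinstance(expr, Not):
        v = k_not(eval_expr(expr.child, case, trace))
    elif isinstance(expr, FindingIs):
        fv = case.finding_value(expr.code)
        v = K.U if fv is TriState.UNKNOWN else _from_bool(fv.value == expr.state)
    elif isinstance(expr, TestIs):
        tv = case.test_value(expr.code)
        v = K.U if tv is TestState.UNKNOWN else _from_bool(tv.value == expr.state)
    elif isinstance(expr, CourseIn):
        if case.course is Course.UNKNOWN and not expr.closed:
            v = K.U
        else:
            v = _from_bool(case.course.value in expr.values)
    elif isinstance(expr, LateralityIn):
        if case.laterality is Laterality.UNKNOWN and not expr.closed:
            v = K.U
        else:
            v = _from_bool(case.laterality.value in expr.values)
    elif isinstance(expr, GradeLt):
        lo = case.grade_of(expr.lower)
        hi = case.grade_of(expr.higher)
        v = K.U if lo is None or hi is None else _from_bool(lo < hi)
    elif isinstance(expr, GradeGe):
        g = case.grade_of(expr.code)
        v = _from_bool((g or 0) >= expr.threshold)
    elif isinstance(expr, FindingIn):
        v = _from_bool(case.finding_value(expr.code).value in expr.states)
    elif isinstance(expr, TestIn):
        v = _from_bool(case.test_value(expr.code).value in expr.states)
    elif isinstance(expr, Const):
        v = _from_bool(expr.value)
    else:  # pragma: no cover - exhaustive over node types
        raise TypeError(f"not a rule expression: {expr!r}")
    if trace is not None and expr.label is not None:
        trace[expr.label] = v
    return v


# ---------------------------------------------------------------------------
# rule sets and classification


@dataclass(frozen=True)
class RuleSet:
    """Named disease criteria: a criteria tree plus exclusion expressions."""

    disease_id: str
    disease_name: str
    anatomic_class: AnatomicClass
    criteria: RuleExpr
    exclusions: tuple[RuleExpr, ...] = ()
    provenance: str = ""


class Verdict(str, Enum):
    CLASSIFIED = "classified"
    CRITERIA_NOT_MET = "criteria_not_met"
    EXCLUDED = "excluded"
    INDETERMINATE = "indeterminate"


@dataclass
class ClassificationResult:
    """Per-case verdicts for a list of rule sets, with evaluation traces."""

    case_id: str
    verdicts: dict[str, Verdict]
    trace: dict[str, dict]
    final_labels: frozenset[str]


def classify_case(case: CaseRecord, rulesets: list[RuleSet]) -> ClassificationResult:
    """Evaluate every rule set; a true exclusion dominates the verdict."""
    verdicts: dict[str, Verdict] = {}
    traces: dict[str, dict] = {}
    for rs in rulesets:
        item_trace: dict[str, K] = {}
        crit = eval_expr(rs.criteria, case, item_trace)
        excl = [eval_expr(e, case, item_trace) for e in rs.exclusions]
        if any(v is K.T for v in excl):
            verdict = Verdict.EXCLUDED
        elif crit is K.T:
            verdict = Verdict.CLASSIFIED
        elif crit is K.U:
            verdict = Verdict.INDETERMINATE
        else:
            verdict = Verdict.CRITERIA_NOT_MET
        verdicts[rs.disease_id] = verdict
        traces[rs.disease_id] = {
            "criteria": crit.name,
            "exclusions": [v.name for v in excl],
            "items": {lbl: v.name for lbl, v in item_trace.items()},
        }
    final = frozenset(d for d, v in verdicts.items() if v is Verdict.CLASSIFIED)
    return ClassificationResult(case.case_id, verdicts, traces, final)


# ---------------------------------------------------------------------------
# DSL (JSON) serialization

_TRI_FINDING = ("present", "absent", "unknown")
_TRI_TEST = ("positive", "negative", "unknown")


def expr_from_dict(d: dict, vocab: Vocabulary, path: str = "$") -> RuleExpr:
    if not isinstance(d, dict):
        raise DslError(f"{path}: expected object, got {type(d).__name__}")
    label = d.get("label")
    if label is not None and not isinstance(label, str):
        raise DslError(f"{path}.label: must be a string")
    keys = set(d) - {"label", "closed"}
    if "and" in keys or "or" in keys:
        op = "and" if "and" in keys else "or"
        if keys != {op}:
            raise DslError(f"{path}: unexpected keys {sorted(keys - {op})}")
        children = d[op]
        if not isinstance(children, list) or not children:
            raise DslError(f"{path}.{op}: must be a non-empty array")
        parsed = tuple(
            expr_from_dict(c, vocab, f"{path}.{op}[{i}]") for i, c in enumerate(children)
        )
        node = And(parsed, label) if op == "and" else Or(parsed, label)
        return node
    if "not" in keys:
        if keys != {"not"}:
            raise DslError(f"{path}: unexpected keys {sorted(keys - {'not'})}")
        return Not(expr_from_dict(d["not"], vocab, f"{path}.not"), label)
    if "finding" in keys:
        code, state = d["finding"], d.get("is")
        _require_finding(code, vocab, f"{path}.finding")
        if state not in ("present", "absent"):
            raise DslError(f"{path}.is: expected 'present' or 'absent', got {state!r}")
        return FindingIs(code, state, label)
    if "test" in keys:
        code, state = d["test"], d.get("is")
        _require_test(code, vocab, f"{path}.test")
        if state not in ("positive", "negative"):
            raise DslError(f"{path}.is: expected 'positive' or 'negative', got {state!r}")
        return TestIs(code, state, label)
    if "course_in" in keys:
        vals = _require_enum_list(d["course_in"], Course, f"{path}.course_in")
        return CourseIn(vals, bool(d.get("closed", False)), label)
    if "laterality_in" in keys:
        vals = _require_enum_list(d["laterality_in"], Laterality, f"{path}.laterality_in")
        return LateralityIn(vals, bool(d.get("closed", False)), label)
    if "grade_lt" in keys:
        pair = d["grade_lt"]
        if not (isinstance(pair, list) and len(pair) == 2):
            raise DslError(f"{path}.grade_lt: expected [lower, higher]")
        for c in pair:
            _require_finding(c, vocab, f"{path}.grade_lt")
            if not vocab.is_gradable(c):
                raise DslError(f"{path}.grade_lt: code {c!r} is not gradable")
        return GradeLt(pair[0], pair[1], label)
    if "grade_ge" in keys:
        pair = d["grade_ge"]
        if not (isinstance(pair, list) and len(pair) == 2 and isinstance(pair[1], int)):
            raise DslError(f"{path}.grade_ge: expected [code, threshold]")
        _require_finding(pair[0], vocab, f"{path}.grade_ge")
        if not vocab.is_gradable(pair[0]):
            raise DslError(f"{path}.grade_ge: code {pair[0]!r} is not gradable")
        return GradeGe(pair[0], pair[1], label)
    if "finding_in" in keys:
        code, states = _require_membership(d["finding_in"], _TRI_FINDING, f"{path}.finding_in")
        _require_finding(code, vocab, f"{path}.finding_in")
        return FindingIn(code, states, label)
    if "test_in" in keys:
        code, states = _require_membership(d["test_in"], _TRI_TEST, f"{path}.test_in")
        _require_test(code, vocab, f"{path}.test_in")
        return TestIn(code, states, label)
    if "const" in keys:
        if not isinstance(d["const"], bool):
            raise DslError(f"{path}.const: expected boolean")
        return Const(d["const"], label)
    raise DslError(f"{path}: unrecognized node with keys {sorted(d)}")


def _require_finding(code, vocab: Vocabulary, path: str) -> None:
    if not isinstance(code, str) or not vocab.is_finding(code):
        raise DslError(f"{path}: unknown finding code {code!r}")


def _require_test(code, vocab: Vocabulary, path: str) -> None:
    if not isinstance(code, str) or not vocab.is_test(code):
        raise DslError(f"{path}: unknown test code {code!r}")


def _require_enum_list(vals, enum_cls, path: str) -> tuple[str, ...]:
    if not isinstance(vals, list) or not vals:
        raise DslError(f"{path}: expected a non-empty array")
    allowed = {e.value for e in enum_cls}
    for v in vals:
        if v not in allowed:
            raise DslError(f"{path}: invalid value {v!r}")
    return tuple(vals)


def _require_membership(spec, allowed, path: str) -> tuple[str, tuple[str, ...]]:
    if not (isinstance(spec, list) and len(spec) == 2 and isinstance(spec[1], list)):
        raise DslError(f"{path}: expected [code, [states...]]")
    code, states = spec
    for s in states:
        if s not in allowed:
            raise DslError(f"{path}: invalid state {s!r}")
    return code, tuple(states)


def expr_to_dict(expr: RuleExpr) -> dict:
    d: dict
    if isinstance(expr, And):
        d = {"and": [expr_to_dict(c) for c in expr.children]}
    elif isinstance(expr, Or):
        d = {"or": [expr_to_dict(c) for c in expr.children]}
    elif isinstance(expr, Not):
        d = {"not": expr_to_dict(expr.child)}
    elif isinstance(expr, FindingIs):
        d = {"finding": expr.code, "is": expr.state}
    elif isinstance(expr, TestIs):
        d = {"test": expr.code, "is": expr.state}
    elif isinstance(expr, CourseIn):
        d = {"course_in": list(expr.values)}
        if expr.closed:
            d["closed"] = True
    elif isinstance(expr, LateralityIn):
        d = {"laterality_in": list(expr.values)}
        if expr.closed:
            d["closed"] = True
    elif isinstance(expr, GradeLt):
        d = {"grade_lt": [expr.lower, expr.higher]}
    elif isinstance(expr, GradeGe):
        d = {"grade_ge": [expr.code, expr.threshold]}
    elif isinstance(expr, FindingIn):
        d = {"finding_in": [expr.code, list(expr.states)]}
    elif isinstance(expr, TestIn):
        d = {"test_in": [expr.code, list(expr.states)]}
    elif isinstance(expr, Const):
        d = {"const": expr.value}
    else:  # pragma: no cover
        raise TypeError(f"not a rule expression: {expr!r}")
    if expr.label is not None:
        d["label"] = expr.label
    return d


def ruleset_from_dict(doc: dict, vocab: Optional[Vocabulary] = None) -> RuleSet:
    vocab = vocab or default_vocabulary()
    if not isinstance(doc, dict):
        raise DslError("$: expected object")
    for key in ("disease_id", "disease_name", "anatomic_class", "criteria"):
        if key not in doc:
            raise DslError(f"$.{key}: missing required key")
    try:
        anat = AnatomicClass(doc["anatomic_class"])
    except ValueError:
        raise DslError(f"$.anatomic_class: invalid value {doc['anatomic_class']!r}") from None
    exclusions = doc.get("exclusions", [])
    if not isinstance(exclusions, list):
        raise DslError("$.exclusions: expected array")
    return RuleSet(
        disease_id=str(doc["disease_id"]),
        disease_name=str(doc["disease_name"]),
        anatomic_class=anat,
        criteria=expr_from_dict(doc["criteria"], vocab, "$.criteria"),
        exclusions=tuple(
            expr_from_dict(e, vocab, f"$.exclusions[{i}]") for i, e in enumerate(exclusions)
        ),
        provenance=str(doc.get("provenance", "")),
    )


def ruleset_to_dict(rs: RuleSet) -> dict:
    return {
        "disease_id": rs.disease_id,
        "disease_name": rs.disease_name,
        "anatomic_class": rs.anatomic_class.value,
        "criteria": expr_to_dict(rs.criteria),
        "exclusions": [expr_to_dict(e) for e in rs.exclusions],
        "provenance": rs.provenance,
    }


def load_ruleset(path: str | Path, vocab: Optional[Vocabulary] = None) -> RuleSet:
    with open(path, "r", encoding="utf-8") as fh:
        return ruleset_from_dict(json.load(fh), vocab)


def save_ruleset(rs: RuleSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(ruleset_to_dict(rs), fh, indent=2)
        fh.write("\n")


SHIPPED_RULESET_IDS = ("spa_hla_b27", "fuchs_uveitis", "arn")


def shipped_ruleset(disease_id: str, vocab: Optional[Vocabulary] = None) -> RuleSet:
    """Load one of the rule sets shipped as package data."""
    if disease_id not in SHIPPED_RULESET_IDS:
        raise KeyError(f"no shipped rule set {disease_id!r}")
    text = (
        resources.files("uveaclass")
        .joinpath(f"data/rulesets/{disease_id}.json")
        .read_text("utf-8")
    )
    return ruleset_from_dict(json.loads(text), vocab)


def shipped_rulesets(vocab: Optional[Vocabulary] = None) -> list[RuleSet]:
    return [shipped_ruleset(d, vocab) for d in SHIPPED_RULESET_IDS]


# ---------------------------------------------------------------------------
# structural helpers and exhaustive equivalence


def iter_predicates(expr: RuleExpr, polarity: int = 1) -> Iterator[tuple[Predicate, int]]:
    """Yield (leaf predicate, polarity) pairs; polarity flips under NOT."""
    if isinstance(expr, (And, Or)):
        for c in expr.children:
            yield from iter_predicates(c, polarity)
    elif isinstance(expr, Not):
        yield from iter_predicates(expr.child, -polarity)
    else:
        yield expr, polarity


# Field keys: ("finding", code), ("test", code), ("course",), ("laterality",).
# Finding states are "present"/"absent"/"unknown" or ("present", grade) for
# gradable codes taking part in a grade comparison.


def referenced_fields(
    *exprs: RuleExpr, grades: tuple[int, ...] = (1, 2)
) -> dict[tuple, tuple]:
    """Domain of fields an expression reads, suitable for enumeration."""
    graded: set[str] = set()
    fields: dict[tuple, tuple] = {}
    for expr in exprs:
        for pred, _ in iter_predicates(expr):
            if isinstance(pred, (FindingIs, FindingIn)):
                fields.setdefault(("finding", pred.code), ())
            elif isinstance(pred, (TestIs, TestIn)):
                fields[("test", pred.code)] = ("positive", "negative", "unknown")
            elif isinstance(pred, CourseIn):
                fields[("course",)] = tuple(c.value for c in Course)
            elif isinstance(pred, LateralityIn):
                fields[("laterality",)] = tuple(l.value for l in Laterality)
            elif isinstance(pred, GradeLt):
                graded.update((pred.lower, pred.higher))
                fields.setdefault(("finding", pred.lower), ())
                fields.setdefault(("finding", pred.higher), ())
            elif isinstance(pred, GradeGe):
                graded.add(pred.code)
                fields.setdefault(("finding", pred.code), ())
    for key in list(fields):
        if key[0] == "finding":
            if key[1] in graded:
                fields[key] = ("unknown", "absent") + tuple(
                    ("present", g) for g in grades
                )
            else:
                fields[key] = ("present", "absent", "unknown")
    return fields


def case_from_assignment(
    assignment: dict[tuple, object],
    anatomic_class: AnatomicClass = AnatomicClass.ANTERIOR,
    case_id: str = "enum",
) -> CaseRecord:
    """Build a minimal case from a field assignment (enumeration helper)."""
    findings: dict[str, Finding] = {}
    tests: dict[str, TestResult] = {}
    course = Course.UNKNOWN
    lat = Laterality.UNKNOWN
    for key, state in assignment.items():
        if key[0] == "finding":
            code = key[1]
            if isinstance(state, tuple):  # ("present", grade)
                findings[code] = Finding(code, TriState.PRESENT, state[1])
            else:
                findings[code] = Finding(code, TriState(state))
        elif key[0] == "test":
            tests[key[1]] = TestResult(key[1], TestState(state))
        elif key[0] == "course":
            course = Course(state)
        elif key[0] == "laterality":
            lat = Laterality(state)
    return CaseRecord(case_id, anatomic_class, course, lat, findings, tests)


def enumerate_assignments(
    domain: dict[tuple, tuple], max_assignments: int = 2_000_000
) -> Iterator[dict[tuple, object]]:
    """All assignments of the domain, refusing oversized enumerations."""
    total = 1
    for states in domain.values():
        total *= max(len(states), 1)
    if total > max_assignments:
        raise DomainTooLargeError(
            f"domain has {total} assignments, exceeding the bound {max_assignments}"
        )
    keys = list(domain)
    for combo in itertools.product(*(domain[k] for k in keys)):
        yield dict(zip(keys, combo))


def expr_equivalent(
    a: RuleExpr,
    b: RuleExpr,
    domain: Optional[dict[tuple, tuple]] = None,
    max_assignments: int = 2_000_000,
) -> bool:
    """True iff a and b evaluate identically on every assignment of the
    (finite) domain, by exhaustive enumeration."""
    if domain is None:
        domain = referenced_fields(a, b)
    for assignment in enumerate_assignments(domain, max_assignments):
        case = case_from_assignment(assignment)
        if eval_expr(a, case) is not eval_expr(b, case):
            return False
    return True


def strip_labels(expr: RuleExpr) -> RuleExpr:
    """Structural copy with all trace labels removed (for equality checks)."""
    if isinstance(expr, (And, Or)):
        children = tuple(strip_labels(c) for c in expr.children)
        return replace(expr, children=children, label=None)
    if isinstance(expr, Not):
        return replace(expr, child=strip_labels(expr.child), label=None)
    return replace(expr, label=None)
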
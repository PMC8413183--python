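"""Distillation of a fitted model into a human-readable logical rule system.

The fitted multinomial model is a black box; this module derives one
boolean rule expression per class that makes the same decision as the
model on the cohort it is distilled from.  A decision-tree student is
grown without pruning on the model's argmax predictions (teacher
labels), each class's leaves are converted to a disjunctive normal form
over closed-world membership predicates, and the DNF is simplified by
subsumption without changing any decision on the cohort.

Because teacher labels are a deterministic function of the feature
vector and the tree is grown to purity, the distilled rules agree with
the model on every case they were distilled from; any residual
disagreement (e.g. when distilling from the training split only) is
reported, never hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .clinical_vocab import Cohort, Course, Laterality, Vocabulary, default_vocabulary
from .criteria_engine import (
    And,
    Const,
    CourseIn,
    FindingIn,
    GradeGe,
    LateralityIn,
    Not,
    Or,
    RuleExpr,
    TestIn,
    eval_expr,
    iter_predicates,
    K,
)
from .ml_derivation import FittedModel, predict, recode

__all__ = [
    "DistillationReport",
    "distill",
    "check_agreement",
    "rule_decision",
    "atom_count",
]


@dataclass
class DistillationReport:
    """Per-class rules with their agreement statistics against the model."""

    rulesets: dict[str, RuleExpr]
    agreement: dict[str, float]  # keys: "train", "validation", "overall"
    disagreements: list[str] = field(default_factory=list)
    complexity: dict[str, int] = field(default_factory=dict)
    n_evaluated: int = 0


def atom_count(expr: RuleExpr) -> int:
    return sum(1 for _ in iter_predicates(expr))


# ---------------------------------------------------------------------------
# feature literal -> closed-world predicate

_ALL_COURSES = tuple(c.value for c in Course)
_ALL_LATERALITIES = tuple(l.value for l in Laterality)


def _literal_predicate(name: str, value: int, vocab: Vocabulary) -> RuleExpr:
    """Predicate equivalent to ``column == value`` for a binary feature
    column, using closed-world membership so evaluation is determinate."""
    if ">=" in name:
        code, g = name.split(">=")
        pred = GradeGe(code, int(g))
        return pred if value else Not(pred)
    base, state = name.split("=", 1)
    if base == "course":
        members = (state,) if value else tuple(c for c in _ALL_COURSES if c != state)
        return CourseIn(members, closed=True)
    if base == "laterality":
        members = (state,) if value else tuple(
            l for l in _ALL_LATERALITIES if l != state
        )
        return LateralityIn(members, closed=True)
    if vocab.is_finding(base):
        if value:
            return FindingIn(base, (state,))
        return FindingIn(base, tuple(s for s in ("present", "absent", "unknown") if s != state))
    if vocab.is_test(base):
        if value:
            return TestIn(base, (state,))
        return TestIn(base, tuple(s for s in ("positive", "negative", "unknown") if s != state))
    raise ValueError(f"cannot map feature {name!r} to a predicate")


# ---------------------------------------------------------------------------
# tree -> DNF


def _tree_paths(tree, feature_names: list[str]):
    """Yield (class_index, [(feature_name, 0|1), ...]) per leaf."""
    t = tree.tree_
    classes = tree.classes_

    def walk(node: int, lits: list):
        if t.children_left[node] == -1:
            yield int(classes[int(np.argmax(t.value[node]))]), list(lits)
            return
        name = feature_names[t.feature[node]]
        lits.append((name, 0))
        yield from walk(t.children_left[node], lits)
        lits.pop()
        lits.append((name, 1))
        yield from walk(t.children_right[node], lits)
        lits.pop()

    yield from walk(0, [])


def _dnf_for_class(paths, cls: int, vocab: Vocabulary) -> RuleExpr:
    conjunctions = []
    for leaf_cls, lits in paths:
        if leaf_cls != cls:
            continue
        if not lits:
            return Const(True)
        seen = {}
        for name, val in lits:
            seen[(name, val)] = _literal_predicate(name, val, vocab)
        conjunctions.append(tuple(seen.values()))
    if not conjunctions:
        return Const(False)
    if len(conjunctions) == 1:
        terms = conjunctions[0]
        return terms[0] if len(terms) == 1 else And(terms)
    return Or(tuple(t[0] if len(t) == 1 else And(t) for t in conjunctions))


def _simplify_subsumption(expr: RuleExpr) -> RuleExpr:
    """Drop OR terms whose literal set is a superset of another term's
    (absorption/subsumption); decision-preserving for DNF."""
    if not isinstance(expr, Or):
        return expr

    def literal_set(term) -> frozenset:
        if isinstance(term, And):
            return frozenset(repr(c) for c in term.children)
        return frozenset([repr(term)])

    terms = list(expr.children)
    sets = [literal_set(t) for t in terms]
    keep = []
    for i, si in enumerate(sets):
        subsumed = any(
            j != i and sets[j] < si or (sets[j] == si and j < i) for j in range(len(sets))
        )
        if not subsumed:
            keep.append(terms[i])
    if len(keep) == 1:
        return keep[0]
    return Or(tuple(keep))


# ---------------------------------------------------------------------------
# decisions and agreement


def rule_decision(rules: dict[str, RuleExpr], case, class_order: list[str]):
    """First class (in model class order) whose rule evaluates T, else None."""
    for cls in class_order:
        if eval_expr(rules[cls], case) is K.T:
            return cls
    return None


def _split_of(cohort: Cohort, case_id: str) -> str:
    if cohort.split is None:
        return "train"
    return cohort.split[case_id]


def _agreement_stats(
    rules: dict[str, RuleExpr],
    teacher: dict[str, str],
    cohort: Cohort,
    case_ids,
) -> tuple[dict[str, float], list[str]]:
    match: dict[str, list[int]] = {"train": [], "validation": []}
    disagreements: list[str] = []
    by_id = {c.case_id: c for c in cohort.cases}
    for cid in case_ids:
        case = by_id[cid]
        ok = rule_decision(rules, case, list(rules)) == teacher[cid]
        match[_split_of(cohort, cid)].append(int(ok))
        if not ok:
            disagreements.append(cid)
    agreement = {}
    total = []
    for split, vals in match.items():
        if vals:
            agreement[split] = float(np.mean(vals))
        total += vals
    agreement["overall"] = float(np.mean(total)) if total else 1.0
    return agreement, disagreements


def distill(
    model: FittedModel,
    cohort: Cohort,
    vocab: Vocabulary | None = None,
    fit_on: str = "all",
    seed: int = 0,
) -> DistillationReport:
    """Derive per-class rules that replicate the model's decisions.

    ``fit_on="all"`` grows the student on the teacher labels of the whole
    cohort, which guarantees identical decisions on both splits (teacher
    labels are a function of the features and the tree is grown to purity);
    ``fit_on="train"`` uses the training split only, so validation
    disagreements are possible and reported.
    """
    vocab = vocab or default_vocabulary()
    if fit_on not in ("all", "train"):
        raise ValueError(f"fit_on must be 'all' or 'train', got {fit_on!r}")
    fm = recode(cohort, vocab).restrict(model.feature_names)
    _, teacher_labels = predict(model, fm)
    teacher = dict(zip(fm.case_ids, teacher_labels))
    y = np.array([model.classes.index(lbl) for lbl in teacher_labels])

    if fit_on == "train":
        mask = np.array([_split_of(cohort, cid) == "train" for cid in fm.case_ids])
    else:
        mask = np.ones(len(fm.case_ids), dtype=bool)
    tree = DecisionTreeClassifier(random_state=seed)  # unpruned, grown to purity
    tree.fit(fm.X[mask], y[mask])

    paths = list(_tree_paths(tree, fm.feature_names))
    rules: dict[str, RuleExpr] = {}
    for k, cls in enumerate(model.classes):
        raw = _dnf_for_class(paths, k, vocab)
        simplified = _simplify_subsumption(raw)
        rules[cls] = simplified

    # simplification soundness: decisions must be unchanged case by case
    raw_rules = {cls: _dnf_for_class(paths, k, vocab) for k, cls in enumerate(model.classes)}
    for case in cohort.cases:
        if rule_decision(rules, case, model.classes) != rule_decision(
            raw_rules, case, model.classes
        ):  # pragma: no cover - subsumption is decision-preserving
            rules = raw_rules
            break

    agreement, disagreements = _agreement_stats(
        {c: rules[c] for c in model.classes}, teacher, cohort, fm.case_ids
    )
    return DistillationReport(
        rulesets=rules,
        agreement=agreement,
        disagreements=disagreements,
        complexity={cls: atom_count(r) for cls, r in rules.items()},
        n_evaluated=len(fm.case_ids),
    )


def check_agreement(
    rules: dict[str, RuleExpr],
    model: FittedModel,
    cohort: Cohort,
    vocab: Vocabulary | None = None,
    sample_fraction: float = 1.0,
    seed: int = 0,
) -> DistillationReport:
    """Exact agreement statistics between a rule system and the model.

    ``sample_fraction=0.1`` mimics a 10% random audit subsample.
    """
    vocab = vocab or default_vocabulary()
    if not (0.0 < sample_fraction <= 1.0):
        raise ValueError("sample_fraction must lie in (0, 1]")
    fm = recode(cohort, vocab).restrict(model.feature_names)
    _, teacher_labels = predict(model, fm)
    teacher = dict(zip(fm.case_ids, teacher_labels))
    ids = list(fm.case_ids)
    if sample_fraction < 1.0:
        rng = np.random.default_rng(seed)
        k = int(round(sample_fraction * len(ids)))
        ids = [ids[i] for i in sorted(rng.choice(len(ids), size=k, replace=False))]
    ordered = {cls: rules[cls] for cls in model.classes}
    agreement, disagreements = _agreement_stats(ordered, teacher, cohort, ids)
    return DistillationReport(
        rulesets=ordered,
        agreement=agreement,
        disagreements=disagreements,
        complexity={cls: atom_count(r) for cls, r in ordered.items()},
        n_evaluated=len(ids),
    )
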
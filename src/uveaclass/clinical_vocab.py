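"""Standardized case data model and vocabulary for uveitis case records.

A :class:`CaseRecord` captures one patient case as a set of tri-state
clinical findings and laboratory/imaging test results drawn from a
controlled vocabulary (:class:`Vocabulary`), together with the anatomic
uveitis class and course/laterality descriptors.  Collections of cases
(:class:`Cohort`) round-trip through CSV and JSON.

Tri-state convention: every finding is *present*, *absent* or *unknown*;
every test result is *positive*, *negative* or *unknown*.  An empty CSV
cell means unknown.  Gradable findings (cell grades) carry an optional
0--4 ordinal severity, serialized as e.g. ``present:2``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

__all__ = [
    "TriState",
    "TestState",
    "AnatomicClass",
    "Course",
    "Laterality",
    "Finding",
    "TestResult",
    "CaseRecord",
    "Cohort",
    "Vocabulary",
    "VocabularyError",
    "CohortError",
    "default_vocabulary",
    "validate_case",
    "read_cases",
    "write_cases",
]


class VocabularyError(ValueError):
    """A code or token outside the controlled vocabulary was used."""


class CohortError(ValueError):
    """A case collection violates a structural invariant (e.g. duplicate ids)."""


class TriState(str, Enum):
    PRESENT = "present"
    ABSENT = "absent"
    UNKNOWN = "unknown"


class TestState(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


class AnatomicClass(str, Enum):
    ANTERIOR = "anterior"
    INTERMEDIATE = "intermediate"
    POSTERIOR = "posterior"
    PANUVEITIS = "panuveitis"
    INFECTIOUS_POST_PAN = "infectious_post_pan"


class Course(str, Enum):
    ACUTE = "acute"
    RECURRENT_ACUTE = "recurrent_acute"
    CHRONIC = "chronic"
    CHRONIC_AFTER_RECURRENT_ACUTE = "chronic_after_recurrent_acute"
    UNKNOWN = "unknown"


class Laterality(str, Enum):
    UNILATERAL = "unilateral"
    ALTERNATING_UNILATERAL = "alternating_unilateral"
    BILATERAL = "bilateral"
    UNKNOWN = "unknown"


GRADE_MIN = 0
GRADE_MAX = 4


@dataclass(frozen=True)
class Finding:
    """One tri-state clinical finding, optionally graded 0-4."""

    code: str
    value: TriState = TriState.UNKNOWN
    grade: Optional[int] = None


@dataclass(frozen=True)
class TestResult:
    """One tri-state laboratory or imaging result."""

    code: str
    value: TestState = TestState.UNKNOWN


class Vocabulary:
    """Registry of finding and test codes.

    The registry is data-driven (a JSON document) so additional disease
    rule sets can extend it without code changes.
    """

    def __init__(self, document: Mapping) -> None:
        self.finding_codes: tuple[str, ...] = tuple(
            f["code"] for f in document["findings"]
        )
        self.test_codes: tuple[str, ...] = tuple(t["code"] for t in document["tests"])
        self.gradable: frozenset[str] = frozenset(
            f["code"] for f in document["findings"] if f.get("gradable", False)
        )
        dup = _first_duplicate(self.finding_codes + self.test_codes)
        if dup is not None:
            raise VocabularyError(f"duplicate vocabulary code {dup!r}")
        self._findings = frozenset(self.finding_codes)
        self._tests = frozenset(self.test_codes)

    @classmethod
    def from_file(cls, path: str | Path) -> "Vocabulary":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(json.load(fh))

    def is_finding(self, code: str) -> bool:
        return code in self._findings

    def is_test(self, code: str) -> bool:
        return code in self._tests

    def is_gradable(self, code: str) -> bool:
        return code in self.gradable

    def __contains__(self, code: str) -> bool:
        return code in self._findings or code in self._tests


def _first_duplicate(items: Iterable[str]) -> Optional[str]:
    seen = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


_DEFAULT_VOCAB: Optional[Vocabulary] = None


def default_vocabulary() -> Vocabulary:
    """The vocabulary shipped with the package (terms of the three rule sets
    plus generic uveitis descriptors)."""
    global _DEFAULT_VOCAB
    if _DEFAULT_VOCAB is None:
        text = (
            resources.files("uveaclass").joinpath("data/vocabulary.json").read_text("utf-8")
        )
        _DEFAULT_VOCAB = Vocabulary(json.loads(text))
    return _DEFAULT_VOCAB


@dataclass
class CaseRecord:
    """One patient case.

    ``findings`` and ``tests`` are keyed by vocabulary code, enforcing the
    at-most-one-entry-per-code invariant structurally.  Codes missing from
    the maps are equivalent to explicit ``unknown`` entries; equality is
    defined on that canonical form.
    """

    case_id: str
    anatomic_class: AnatomicClass
    course: Course = Course.UNKNOWN
    laterality: Laterality = Laterality.UNKNOWN
    findings: dict[str, Finding] = field(default_factory=dict)
    tests: dict[str, TestResult] = field(default_factory=dict)
    true_label: Optional[str] = None

    # -- accessors -------------------------------------------------------
    def finding_value(self, code: str) -> TriState:
        f = self.findings.get(code)
        return f.value if f is not None else TriState.UNKNOWN

    def grade_of(self, code: str) -> Optional[int]:
        """Effective severity grade: the recorded grade when present, 0 when
        the finding is absent, None when unknown or ungraded."""
        f = self.findings.get(code)
        if f is None or f.value is TriState.UNKNOWN:
            return None
        if f.value is TriState.ABSENT:
            return 0
        return f.grade

    def test_value(self, code: str) -> TestState:
        t = self.tests.get(code)
        return t.value if t is not None else TestState.UNKNOWN

    # -- canonical equality ---------------------------------------------
    def _canonical(self):
        fs = {
            c: (f.value, f.grade)
            for c, f in self.findings.items()
            if f.value is not TriState.UNKNOWN
        }
        ts = {c: t.value for c, t in self.tests.items() if t.value is not TestState.UNKNOWN}
        return (
            self.case_id,
            self.anatomic_class,
            self.course,
            self.laterality,
            fs,
            ts,
            self.true_label,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, CaseRecord):
            return NotImplemented
        return self._canonical() == other._canonical()


@dataclass
class Cohort:
    """Ordered collection of cases with an optional train/validation split."""

    cases: list[CaseRecord] = field(default_factory=list)
    split: Optional[dict[str, str]] = None  # case_id -> "train" | "validation"

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)

    def case_ids(self) -> list[str]:
        return [c.case_id for c in self.cases]

    def subset(self, which: str) -> "Cohort":
        """Cases assigned to the given split partition."""
        if self.split is None:
            raise CohortError("cohort has no split assignment")
        return Cohort([c for c in self.cases if self.split[c.case_id] == which])

    def validate(self) -> None:
        dup = _first_duplicate(self.case_ids())
        if dup is not None:
            raise CohortError(f"duplicate case_id {dup!r}")
        if self.split is not None:
            ids = set(self.case_ids())
            assigned = set(self.split)
            if assigned != ids:
                missing = sorted(ids - assigned)[:3]
                extra = sorted(assigned - ids)[:3]
                raise CohortError(
                    f"split must cover every case exactly once "
                    f"(missing={missing}, extraneous={extra})"
                )
            bad = {v for v in self.split.values()} - {"train", "validation"}
            if bad:
                raise CohortError(f"invalid split labels {sorted(bad)}")


# ---------------------------------------------------------------------------
# validation


def validate_case(case: CaseRecord, vocab: Optional[Vocabulary] = None) -> list[str]:
    """Check all type invariants; violations are returned as data, not raised."""
    vocab = vocab or default_vocabulary()
    out: list[str] = []
    for code, f in case.findings.items():
        if code != f.code:
            out.append(f"findings[{code}]: key does not match Finding.code {f.code!r}")
        if not vocab.is_finding(code):
            out.append(f"findings[{code}]: code not in vocabulary")
            continue
        if not isinstance(f.value, TriState):
            out.append(f"findings[{code}]: value {f.value!r} is not a tri-state")
            continue
        if f.grade is not None:
            if not vocab.is_gradable(code):
                out.append(f"findings[{code}]: grade given but code is not gradable")
            elif not (GRADE_MIN <= f.grade <= GRADE_MAX):
                out.append(f"findings[{code}]: grade {f.grade} outside 0-4")
            elif f.grade > 0 and f.value is not TriState.PRESENT:
                out.append(f"findings[{code}]: grade>0 requires value=present")
            elif f.grade == 0 and f.value is not TriState.ABSENT:
                out.append(f"findings[{code}]: grade=0 requires value=absent")
    for code, t in case.tests.items():
        if code != t.code:
            out.append(f"tests[{code}]: key does not match TestResult.code {t.code!r}")
        if not vocab.is_test(code):
            out.append(f"tests[{code}]: code not in vocabulary")
        elif not isinstance(t.value, TestState):
            out.append(f"tests[{code}]: value {t.value!r} is not a tri-state")
    if not isinstance(case.anatomic_class, AnatomicClass):
        out.append(f"anatomic_class: {case.anatomic_class!r} invalid")
    if not isinstance(case.course, Course):
        out.append(f"course: {case.course!r} invalid")
    if not isinstance(case.laterality, Laterality):
        out.append(f"laterality: {case.laterality!r} invalid")
    return out


# ---------------------------------------------------------------------------
# serialization

_FIXED_COLUMNS = ["case_id", "anatomic_class", "course", "laterality", "true_label"]


def _parse_tristate(token: str, states, *, where: str):
    token = token.strip().lower()
    if token == "":
        return states("unknown")
    try:
        return states(token)
    except ValueError:
        raise VocabularyError(f"{where}: malformed tri-state token {token!r}") from None


def _finding_from_token(code: str, token: str, vocab: Vocabulary, where: str) -> Finding:
    token = token.strip().lower()
    grade: Optional[int] = None
    if ":" in token:
        token, grade_s = token.split(":", 1)
        try:
            grade = int(grade_s)
        except ValueError:
            raise VocabularyError(f"{where}: malformed grade {grade_s!r}") from None
        if not vocab.is_gradable(code):
            raise VocabularyError(f"{where}: grade given for non-gradable code {code!r}")
    value = _parse_tristate(token, TriState, where=where)
    return Finding(code, value, grade)


def _finding_to_token(f: Finding) -> str:
    if f.value is TriState.UNKNOWN:
        return ""
    if f.grade is not None:
        return f"{f.value.value}:{f.grade}"
    return f.value.value


def read_cases(
    path: str | Path, format: str = "csv", vocab: Optional[Vocabulary] = None
) -> Cohort:
    """Read a case collection from ``cases.csv`` or ``cases.json``.

    Empty CSV cells denote *unknown*; explicit tokens are accepted
    case-insensitively.  Row order is preserved and duplicate case ids are
    rejected.
    """
    vocab = vocab or default_vocabulary()
    if format == "csv":
        cohort = _read_csv(Path(path), vocab)
    elif format == "json":
        cohort = _read_json(Path(path), vocab)
    else:
        raise ValueError(f"unsupported format {format!r}")
    cohort.validate()
    for i, case in enumerate(cohort.cases):
        violations = validate_case(case, vocab)
        if violations:
            raise VocabularyError(f"case {case.case_id!r} (row {i + 1}): {violations[0]}")
    return cohort


def _read_csv(path: Path, vocab: Vocabulary) -> Cohort:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in _FIXED_COLUMNS:
            if col not in header:
                raise VocabularyError(f"missing required column {col!r}")
        has_split = "split" in header
        for col in header:
            if col in _FIXED_COLUMNS or col == "split":
                continue
            if col not in vocab:
                raise VocabularyError(f"unknown vocabulary code in header: {col!r}")
        cases: list[CaseRecord] = []
        split: dict[str, str] = {}
        for rownum, row in enumerate(reader, start=2):
            where = f"row {rownum}"
            case_id = (row.get("case_id") or "").strip()
            if not case_id:
                raise VocabularyError(f"{where}: empty case_id")
            try:
                anat = AnatomicClass((row.get("anatomic_class") or "").strip().lower())
            except ValueError:
                raise VocabularyError(
                    f"{where}: invalid anatomic_class {row.get('anatomic_class')!r}"
                ) from None
            course = _parse_tristate(row.get("course") or "", Course, where=where)
            lat = _parse_tristate(row.get("laterality") or "", Laterality, where=where)
            findings: dict[str, Finding] = {}
            tests: dict[str, TestResult] = {}
            for col in header:
                if col in _FIXED_COLUMNS or col == "split":
                    continue
                token = row.get(col) or ""
                if vocab.is_finding(col):
                    findings[col] = _finding_from_token(col, token, vocab, f"{where} [{col}]")
                else:
                    tests[col] = TestResult(
                        col, _parse_tristate(token, TestState, where=f"{where} [{col}]")
                    )
            label = (row.get("true_label") or "").strip() or None
            cases.append(
                CaseRecord(case_id, anat, course, lat, findings, tests, label)
            )
            if has_split:
                sv = (row.get("split") or "").strip().lower()
                if sv:
                    split[case_id] = sv
    return Cohort(cases, split or None)


def _read_json(path: Path, vocab: Vocabulary) -> Cohort:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if isinstance(doc, list):  # bare array of cases
        doc = {"cases": doc, "split": None}
    cases = [_case_from_doc(d, vocab, i) for i, d in enumerate(doc["cases"])]
    return Cohort(cases, doc.get("split") or None)


def _case_from_doc(d: Mapping, vocab: Vocabulary, idx: int) -> CaseRecord:
    where = f"case #{idx}"
    findings: dict[str, Finding] = {}
    for code, v in (d.get("findings") or {}).items():
        if not vocab.is_finding(code):
            raise VocabularyError(f"{where}: unknown finding code {code!r}")
        if isinstance(v, str):
            findings[code] = Finding(code, _parse_tristate(v, TriState, where=where))
        else:
            findings[code] = Finding(
                code,
                _parse_tristate(v.get("value", ""), TriState, where=where),
                v.get("grade"),
            )
    tests: dict[str, TestResult] = {}
    for code, v in (d.get("tests") or {}).items():
        if not vocab.is_test(code):
            raise VocabularyError(f"{where}: unknown test code {code!r}")
        tests[code] = TestResult(code, _parse_tristate(v, TestState, where=where))
    try:
        anat = AnatomicClass(d["anatomic_class"])
    except (KeyError, ValueError):
        raise VocabularyError(f"{where}: invalid anatomic_class") from None
    return CaseRecord(
        case_id=str(d["case_id"]),
        anatomic_class=anat,
        course=Course(d.get("course", "unknown")),
        laterality=Laterality(d.get("laterality", "unknown")),
        findings=findings,
        tests=tests,
        true_label=d.get("true_label"),
    )


def write_cases(
    cohort: Cohort,
    path: str | Path,
    format: str = "csv",
    vocab: Optional[Vocabulary] = None,
) -> None:
    """Write a cohort so that :func:`read_cases` reproduces it field-for-field."""
    vocab = vocab or default_vocabulary()
    cohort.validate()
    path = Path(path)
    if format == "csv":
        _write_csv(cohort, path, vocab)
    elif format == "json":
        _write_json(cohort, path)
    else:
        raise ValueError(f"unsupported format {format!r}")


def _write_csv(cohort: Cohort, path: Path, vocab: Vocabulary) -> None:
    codes = list(vocab.finding_codes) + list(vocab.test_codes)
    header = list(_FIXED_COLUMNS)
    if cohort.split is not None:
        header.append("split")
    header += codes
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for case in cohort.cases:
            row = [
                case.case_id,
                case.anatomic_class.value,
                "" if case.course is Course.UNKNOWN else case.course.value,
                "" if case.laterality is Laterality.UNKNOWN else case.laterality.value,
                case.true_label or "",
            ]
            if cohort.split is not None:
                row.append(cohort.split.get(case.case_id, ""))
            for code in codes:
                if vocab.is_finding(code):
                    f = case.findings.get(code)
                    row.append(_finding_to_token(f) if f is not None else "")
                else:
                    t = case.tests.get(code)
                    row.append(
                        "" if t is None or t.value is TestState.UNKNOWN else t.value.value
                    )
            writer.writerow(row)


def _case_to_doc(case: CaseRecord) -> dict:
    findings = {}
    for code, f in case.findings.items():
        if f.value is TriState.UNKNOWN:
            continue
        if f.grade is not None:
            findings[code] = {"value": f.value.value, "grade": f.grade}
        else:
            findings[code] = f.value.value
    tests = {
        code: t.value.value
        for code, t in case.tests.items()
        if t.value is not TestState.UNKNOWN
    }
    doc = {
        "case_id": case.case_id,
        "anatomic_class": case.anatomic_class.value,
        "course": case.course.value,
        "laterality": case.laterality.value,
        "findings": findings,
        "tests": tests,
    }
    if case.true_label is not None:
        doc["true_label"] = case.true_label
    return doc


def _write_json(cohort: Cohort, path: Path) -> None:
    doc = {
        "cases": [_case_to_doc(c) for c in cohort.cases],
        "split": cohort.split,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
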
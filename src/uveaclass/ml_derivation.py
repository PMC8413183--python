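"""Feature recoding, shadow-feature selection and multinomial lasso.

The derivation pipeline recodes case records into a binary feature
matrix, selects decisive features by comparing real-feature importances
against column-permuted "shadow" copies, and fits a per-stratum
multinomial logistic regression with an L1 penalty on the coefficients
(intercepts unpenalized):

    minimize  (1/n) * sum_i -log softmax(b0 + B^T x_i)[y_i]  +  lam * ||B||_1

The solver is an accelerated proximal-gradient method (FISTA with
adaptive restart) with exact soft-thresholding, so coefficients shrunk
to zero are exactly zero and the full-shrinkage threshold
:func:`lambda_max` is sharp.

Encoding conventions (documented, deterministic column order):

* tri-state fields expand to two indicators, ``code=present`` (or
  ``=positive``) and ``code=unknown``; *absent* is both zero;
* gradable findings additionally expand to cumulative ordinal
  indicators ``code>=g`` for g in 1..4 (zero when the grade is unknown);
* course and laterality expand to one-hot indicators including an
  explicit ``=unknown`` level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier

from .clinical_vocab import (
    Cohort,
    Course,
    Laterality,
    TestState,
    TriState,
    Vocabulary,
    default_vocabulary,
)
from .criteria_engine import (
    CourseIn,
    FindingIn,
    FindingIs,
    GradeGe,
    GradeLt,
    LateralityIn,
    RuleSet,
    TestIn,
    TestIs,
    iter_predicates,
)

__all__ = [
    "FeatureMatrix",
    "FittedModel",
    "recode",
    "feature_names_for",
    "boruta_select",
    "lambda_max",
    "fit_multinomial_lasso",
    "predict",
    "required_atoms",
    "atoms_recovered",
]

GRADE_LEVELS = (1, 2, 3, 4)


@dataclass
class FeatureMatrix:
    """Binary design matrix aligned with case ids and feature names."""

    case_ids: list[str]
    feature_names: list[str]
    X: np.ndarray  # n x p, {0,1}
    labels: np.ndarray  # n, int class index
    classes: list[str]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def restrict(self, feature_names: list[str]) -> "FeatureMatrix":
        """Column subset in the given order; unknown names raise KeyError."""
        index = {name: j for j, name in enumerate(self.feature_names)}
        try:
            cols = [index[name] for name in feature_names]
        except KeyError as e:
            raise KeyError(f"feature {e.args[0]!r} not present in matrix") from None
        return FeatureMatrix(
            self.case_ids, list(feature_names), self.X[:, cols], self.labels, self.classes
        )


def feature_names_for(vocab: Vocabulary) -> list[str]:
    names: list[str] = []
    names += [f"course={c.value}" for c in Course]
    names += [f"laterality={l.value}" for l in Laterality]
    for code in vocab.finding_codes:
        names += [f"{code}=present", f"{code}=unknown"]
        if vocab.is_gradable(code):
            names += [f"{code}>={g}" for g in GRADE_LEVELS]
    for code in vocab.test_codes:
        names += [f"{code}=positive", f"{code}=unknown"]
    return names


def recode(cohort: Cohort, vocab: Optional[Vocabulary] = None) -> FeatureMatrix:
    """Recode a labeled cohort into the binary feature matrix."""
    vocab = vocab or default_vocabulary()
    for c in cohort.cases:
        if c.true_label is None:
            raise ValueError(f"case {c.case_id!r} lacks true_label (supervised step)")
    names = feature_names_for(vocab)
    col = {name: j for j, name in enumerate(names)}
    n = len(cohort.cases)
    X = np.zeros((n, len(names)), dtype=np.int8)
    for i, case in enumerate(cohort.cases):
        X[i, col[f"course={case.course.value}"]] = 1
        X[i, col[f"laterality={case.laterality.value}"]] = 1
        for code in vocab.finding_codes:
            v = case.finding_value(code)
            if v is TriState.PRESENT:
                X[i, col[f"{code}=present"]] = 1
            elif v is TriState.UNKNOWN:
                X[i, col[f"{code}=unknown"]] = 1
            if vocab.is_gradable(code):
                g = case.grade_of(code)
                if g:
                    for lvl in GRADE_LEVELS:
                        if g >= lvl:
                            X[i, col[f"{code}>={lvl}"]] = 1
        for code in vocab.test_codes:
            v = case.test_value(code)
            if v is TestState.POSITIVE:
                X[i, col[f"{code}=positive"]] = 1
            elif v is TestState.UNKNOWN:
                X[i, col[f"{code}=unknown"]] = 1
    classes = sorted({c.true_label for c in cohort.cases})
    cls_index = {c: k for k, c in enumerate(classes)}
    labels = np.array([cls_index[c.true_label] for c in cohort.cases], dtype=np.int64)
    return FeatureMatrix(cohort.case_ids(), names, X, labels, classes)


# ---------------------------------------------------------------------------
# Boruta-style shadow-feature selection


def boruta_select(
    fm: FeatureMatrix,
    n_iter: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    n_estimators: int = 500,
) -> dict[str, str]:
    """Status per feature: ``confirmed``, ``rejected`` or ``tentative``.

    Each iteration appends column-permuted shadow copies of every feature,
    fits a random-forest importance scorer, and scores a *hit* for each
    real feature whose importance exceeds the maximum shadow importance.
    Hit counts are tested against Binomial(n_iter, 1/2) at ``alpha`` with
    Bonferroni correction across features.
    """
    if fm.n < 20:
        raise ValueError(f"need at least 20 cases, got {fm.n}")
    if len(np.unique(fm.labels)) < 2:
        raise ValueError("labels are degenerate (single class)")
    rng = np.random.default_rng(seed)
    X = fm.X.astype(np.float64)
    n, p = X.shape
    hits = np.zeros(p, dtype=np.int64)
    for it in range(n_iter):
        shadow = X.copy()
        for j in range(p):
            shadow[:, j] = shadow[rng.permutation(n), j]
        forest = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(np.hstack([X, shadow]), fm.labels)
        imp = forest.feature_importances_
        threshold = imp[p:].max()
        hits += imp[:p] > threshold
    cutoff = alpha / p  # Bonferroni across features
    statuses: dict[str, str] = {}
    for j, name in enumerate(fm.feature_names):
        if n_iter == 0:
            statuses[name] = "tentative"
        elif binom.sf(hits[j] - 1, n_iter, 0.5) < cutoff:
            statuses[name] = "confirmed"
        elif binom.cdf(hits[j], n_iter, 0.5) < cutoff:
            statuses[name] = "rejected"
        else:
            statuses[name] = "tentative"
    return statuses


# ---------------------------------------------------------------------------
# multinomial lasso (FISTA)


@dataclass
class FittedModel:
    """Multinomial lasso fit: softmax(intercepts + beta^T x)."""

    classes: list[str]
    feature_names: list[str]
    beta: np.ndarray  # p x K
    intercepts: np.ndarray  # K
    lam: float

    @property
    def selected_features(self) -> list[str]:
        """Features with at least one nonzero coefficient."""
        keep = np.abs(self.beta).sum(axis=1) > 0
        return [n for n, k in zip(self.feature_names, keep) if k]

    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.beta))

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "feature_names": self.feature_names,
            "beta": self.beta.tolist(),
            "intercepts": self.intercepts.tolist(),
            "lambda": self.lam,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(
            classes=list(d["classes"]),
            feature_names=list(d["feature_names"]),
            beta=np.asarray(d["beta"], dtype=float),
            intercepts=np.asarray(d["intercepts"], dtype=float),
            lam=float(d["lambda"]),
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "FittedModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


class ConvergenceError(RuntimeError):
    """Solver failed to reach tolerance within the iteration cap."""


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


def _objective(X, Y, B, b0, lam) -> float:
    P = _softmax(b0 + X @ B)
    nll = -np.log(np.clip((P * Y).sum(axis=1), 1e-300, None)).mean()
    return nll + lam * np.abs(B).sum()


def _onehot(y: np.ndarray, K: int) -> np.ndarray:
    Y = np.zeros((y.shape[0], K))
    Y[np.arange(y.shape[0]), y] = 1.0
    return Y


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty above which all coefficients are exactly zero."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    K = int(y.max()) + 1
    Y = _onehot(y, K)
    freq = Y.mean(axis=0, keepdims=True)
    G = X.T @ (freq - Y) / n
    return float(np.abs(G).max())


def fit_multinomial_lasso(
    X: np.ndarray,
    y: np.ndarray,
    classes: list[str],
    feature_names: list[str],
    lam: Union[float, str] = "cv",
    tol: float = 1e-7,
    max_iter: int = 100_000,
    cv_folds: int = 5,
    n_lambdas: int = 20,
    seed: int = 0,
) -> FittedModel:
    """Fit the penalized multinomial model; ``lam="cv"`` selects the penalty
    by stratified k-fold cross-validated deviance with the one-standard-error
    rule."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    if len(classes) < 2 or len(np.unique(y)) < 2:
        raise ValueError("need at least two classes present")
    if lam == "cv":
        lam = _cv_lambda(X, y, len(classes), cv_folds, n_lambdas, seed, tol, max_iter)
    lam = float(lam)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    B, b0 = _fista(X, y, len(classes), lam, tol, max_iter)
    return FittedModel(list(classes), list(feature_names), B, b0, lam)


def _fista(
    X: np.ndarray,
    y: np.ndarray,
    K: int,
    lam: float,
    tol: float,
    max_iter: int,
    warm: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    n, p = X.shape
    Y = _onehot(y, K)
    # Lipschitz bound for the softmax NLL gradient over the augmented design
    Xa = np.hstack([X, np.ones((n, 1))])
    smax = np.linalg.norm(Xa, 2)
    L = 0.5 * smax**2 / n + 1e-12
    step = 1.0 / L

    if warm is not None:
        B, b0 = warm[0].copy(), warm[1].copy()
    else:
        B = np.zeros((p, K))
        freq = np.clip(Y.mean(axis=0), 1e-12, None)
        b0 = np.log(freq)
        b0 -= b0.mean()
    Bm, b0m = B.copy(), b0.copy()  # momentum iterates
    t = 1.0
    prev_obj = _objective(X, Y, B, b0, lam)
    thresh = step * lam
    check_every = 10
    for it in range(1, max_iter + 1):
        P = _softmax(b0m + X @ Bm)
        R = (P - Y) / n
        G = X.T @ R
        B_new = Bm - step * G
        B_new = np.sign(B_new) * np.maximum(np.abs(B_new) - thresh, 0.0)
        b0_new = b0m - step * R.sum(axis=0)
        b0_new -= b0_new.mean()  # fix the softmax gauge

        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        Bm = B_new + ((t - 1.0) / t_new) * (B_new - B)
        b0m = b0_new + ((t - 1.0) / t_new) * (b0_new - b0)
        B, b0, t = B_new, b0_new, t_new

        if it % check_every == 0:
            obj = _objective(X, Y, B, b0, lam)
            if obj > prev_obj:  # adaptive restart
                Bm, b0m, t = B.copy(), b0.copy(), 1.0
            if abs(prev_obj - obj) <= tol * max(abs(prev_obj), 1.0):
                return B, b0
            prev_obj = obj
    raise ConvergenceError(
        f"no convergence within {max_iter} iterations "
        f"(last objective {prev_obj:.6g}, lambda={lam:.3g}, n={n}, p={p})"
    )


def _cv_lambda(
    X: np.ndarray,
    y: np.ndarray,
    K: int,
    cv_folds: int,
    n_lambdas: int,
    seed: int,
    tol: float,
    max_iter: int,
) -> float:
    from sklearn.model_selection import StratifiedKFold

    lmax = lambda_max(X, y)
    if lmax <= 0:
        return 0.0
    grid = np.geomspace(lmax, lmax * 1e-3, n_lambdas)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    dev = np.full((cv_folds, n_lambdas), np.nan)
    for f, (tr, te) in enumerate(skf.split(X, y)):
        warm = None
        for j, lam in enumerate(grid):
            B, b0 = _fista(X[tr], y[tr], K, lam, tol, max_iter, warm=warm)
            warm = (B, b0)
            P = _softmax(b0 + X[te] @ B)
            ll = np.log(np.clip(P[np.arange(len(te)), y[te]], 1e-300, None))
            dev[f, j] = -2.0 * ll.mean()
    mean = dev.mean(axis=0)
    se = dev.std(axis=0, ddof=1) / np.sqrt(cv_folds)
    best = int(np.argmin(mean))
    # one-standard-error rule: sparsest model within one SE of the minimum
    within = np.nonzero(mean <= mean[best] + se[best])[0]
    return float(grid[within.min()])


def predict(model: FittedModel, fm_or_X) -> tuple[np.ndarray, list[str]]:
    """Class probabilities (rows sum to 1) and argmax labels, ties broken by
    class order."""
    if isinstance(fm_or_X, FeatureMatrix):
        if fm_or_X.feature_names != model.feature_names:
            fm_or_X = fm_or_X.restrict(model.feature_names)
        X = fm_or_X.X
    else:
        X = np.asarray(fm_or_X)
        if X.shape[1] != len(model.feature_names):
            raise ValueError(
                f"design has {X.shape[1]} columns, model expects "
                f"{len(model.feature_names)}"
            )
    P = _softmax(model.intercepts + X.astype(float) @ model.beta)
    labels = [model.classes[k] for k in np.argmax(P, axis=1)]
    return P, labels


# ---------------------------------------------------------------------------
# linking rule atoms to feature columns (for recovery checks)


def required_atoms(rs: RuleSet) -> set[str]:
    """Field atoms referenced by a rule set's criteria tree: vocabulary
    codes plus the pseudo-atoms ``course`` and ``laterality``."""
    atoms: set[str] = set()
    for pred, _ in iter_predicates(rs.criteria):
        if isinstance(pred, (FindingIs, FindingIn, GradeGe)):
            atoms.add(pred.code)
        elif isinstance(pred, (TestIs, TestIn)):
            atoms.add(pred.code)
        elif isinstance(pred, GradeLt):
            atoms.update((pred.lower, pred.higher))
        elif isinstance(pred, CourseIn):
            atoms.add("course")
        elif isinstance(pred, LateralityIn):
            atoms.add("laterality")
    return atoms


def atoms_recovered(statuses: dict[str, str], atoms: set[str]) -> set[str]:
    """Atoms with at least one confirmed feature column."""
    recovered = set()
    for name, status in statuses.items():
        if status != "confirmed":
            continue
        base = name.split(">=")[0].split("=")[0]
        if base in atoms:
            recovered.add(base)
    return recovered
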
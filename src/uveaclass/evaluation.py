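"""Accuracy and misclassification reporting, plus the pipeline driver.

Overall accuracy per anatomic stratum is reported with a Wilson score
95% confidence interval; the per-disease misclassification rate is
defined as 1 minus the recall of that disease against the reference
label, also with a Wilson interval.  The Wilson interval is used because
the published per-stratum estimates carry asymmetric, score-type
intervals; the exact method behind them is not stated, so this choice is
a documented convention, not canon.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .clinical_vocab import Cohort, write_cases, read_cases, default_vocabulary
from .criteria_engine import (
    RuleSet,
    classify_case,
    expr_to_dict,
    load_ruleset,
    shipped_ruleset,
    SHIPPED_RULESET_IDS,
)
from .ml_derivation import (
    boruta_select,
    fit_multinomial_lasso,
    predict,
    recode,
)
from .rule_distillation import distill
from .synthetic_cohort import CohortSpec, generate_cohort

__all__ = [
    "AccuracyReport",
    "PipelineError",
    "wilson_ci",
    "accuracy_report",
    "engine_accuracy",
    "resolve_ruleset",
    "run_pipeline",
]

log = logging.getLogger("uveaclass")


def wilson_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n."""
    if n <= 0:
        raise ValueError("n must be positive")
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


@dataclass
class AccuracyReport:
    """Per-stratum accuracy with per-disease misclassification rates."""

    stratum: str
    n: int
    overall_accuracy: float
    ci95: tuple[float, float]
    per_disease: dict[str, dict] = field(default_factory=dict)
    confusion: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "n": self.n,
            "overall_accuracy": self.overall_accuracy,
            "ci95": list(self.ci95),
            "per_disease": self.per_disease,
            "confusion": None
            if self.confusion is None
            else {
                "labels": list(self.confusion.index),
                "counts": self.confusion.values.tolist(),
            },
        }


def accuracy_report(
    y_pred: Sequence[str], y_true: Sequence[str], stratum: str = ""
) -> AccuracyReport:
    """Accuracy with Wilson 95% CI; per-disease misclassification = 1 - recall."""
    if len(y_pred) != len(y_true):
        raise ValueError("label vectors must have equal length")
    if len(y_true) == 0:
        raise ValueError("label vectors must be non-empty")
    y_pred = list(y_pred)
    y_true = list(y_true)
    labels = sorted(set(y_true) | set(y_pred))
    confusion = pd.crosstab(
        pd.Categorical(y_true, categories=labels),
        pd.Categorical(y_pred, categories=labels),
        dropna=False,
    )
    confusion = confusion.reindex(index=labels, columns=labels, fill_value=0)
    n = len(y_true)
    correct = int(np.trace(confusion.values))
    per_disease: dict[str, dict] = {}
    for lbl in sorted(set(y_true)):
        n_d = int(confusion.loc[lbl].sum())
        miss = n_d - int(confusion.loc[lbl, lbl])
        lo, hi = wilson_ci(miss, n_d)
        per_disease[lbl] = {
            "n": n_d,
            "misclassification_rate": miss / n_d,
            "ci95": [lo, hi],
        }
    return AccuracyReport(
        stratum=stratum,
        n=n,
        overall_accuracy=correct / n,
        ci95=wilson_ci(correct, n),
        per_disease=per_disease,
        confusion=confusion,
    )


def engine_accuracy(cohort: Cohort, rulesets: list[RuleSet]) -> float:
    """Fraction of cases whose true label is among the rule-engine verdicts."""
    if not cohort.cases:
        raise ValueError("empty cohort")
    hits = 0
    for case in cohort.cases:
        result = classify_case(case, rulesets)
        hits += case.true_label in result.final_labels
    return hits / len(cohort.cases)


# ---------------------------------------------------------------------------
# pipeline driver


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def resolve_ruleset(ref: str) -> RuleSet:
    """A shipped rule set id, or a path to a rule DSL JSON file."""
    if ref in SHIPPED_RULESET_IDS:
        return shipped_ruleset(ref)
    return load_ruleset(ref)


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            log.info("stage %s: start", name)
            try:
                out = fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(name, e) from e
            log.info("stage %s: done", name)
            return out

        return wrapped

    return deco


@_stage("simulate")
def _simulate(cfg: dict, seed: int) -> tuple[Cohort, list[RuleSet]]:
    rulesets = [
        (resolve_ruleset(d["ruleset"]), float(d.get("weight", 1.0)))
        for d in cfg["diseases"]
    ]
    spec = CohortSpec(
        diseases=rulesets,
        n_cases=int(cfg["n_cases"]),
        flip_noise=float(cfg.get("flip_noise", 0.0)),
        missing_rate=float(cfg.get("missing_rate", 0.0)),
        train_fraction=float(cfg.get("train_fraction", 0.7)),
        seed=seed,
        background_rate=float(cfg.get("background_rate", 0.05)),
        background_overrides=dict(cfg.get("background_overrides", {})),
    )
    log.info(
        "simulate: n_cases=%d flip_noise=%g missing_rate=%g train_fraction=%g seed=%d",
        spec.n_cases,
        spec.flip_noise,
        spec.missing_rate,
        spec.train_fraction,
        seed,
    )
    return generate_cohort(spec), [rs for rs, _ in rulesets]


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute simulate -> split -> recode -> select -> fit -> validate ->
    distill -> report, writing artifacts under ``out_dir``.

    Deterministic given the config (all seeds derive from ``config["seed"]``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    boruta_cfg = dict(config.get("boruta", {}))
    lasso_cfg = dict(config.get("lasso", {}))
    distill_cfg = dict(config.get("distill", {}))

    rulesets: list[RuleSet] = []
    if "simulate" in config:
        cohort, rulesets = _simulate(config["simulate"], seed)
        write_cases(cohort, out / "cases.csv", "csv")
    elif "cases" in config:
        cohort = _load_cases(config["cases"])
    else:
        raise PipelineError("config", ValueError("config needs 'simulate' or 'cases'"))

    report: dict = {
        "seed": seed,
        "n_cases": len(cohort),
        "strata": {},
    }
    if rulesets:
        try:
            report["engine_accuracy"] = engine_accuracy(cohort, rulesets)
        except Exception as e:  # pragma: no cover
            raise PipelineError("engine-evaluate", e) from e

    by_stratum: dict[str, Cohort] = {}
    for case in cohort.cases:
        by_stratum.setdefault(case.anatomic_class.value, Cohort([], None)).cases.append(
            case
        )
    for stratum, sub in sorted(by_stratum.items()):
        sub.split = (
            {cid: cohort.split[cid] for cid in sub.case_ids()} if cohort.split else None
        )
        labels = {c.true_label for c in sub.cases}
        if len(labels) < 2:
            log.info("stratum %s: single class, skipping model derivation", stratum)
            continue
        report["strata"][stratum] = _derive_stratum(
            sub, stratum, seed, boruta_cfg, lasso_cfg, distill_cfg, out
        )

    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
    return report


@_stage("load-cases")
def _load_cases(path: str) -> Cohort:
    fmt = "json" if str(path).endswith(".json") else "csv"
    cohort = read_cases(path, fmt)
    if cohort.split is None:
        raise ValueError("case file must carry a train/validation split column")
    return cohort


def _derive_stratum(
    sub: Cohort,
    stratum: str,
    seed: int,
    boruta_cfg: dict,
    lasso_cfg: dict,
    distill_cfg: dict,
    out: Path,
) -> dict:
    vocab = default_vocabulary()
    train = sub.subset("train")
    validation = sub.subset("validation")
    if not validation.cases:
        raise PipelineError("split", ValueError(f"stratum {stratum}: empty validation set"))

    try:
        fm_train = recode(train, vocab)
    except Exception as e:
        raise PipelineError("recode", e) from e

    try:
        statuses = boruta_select(
            fm_train,
            n_iter=int(boruta_cfg.get("n_iter", 100)),
            alpha=float(boruta_cfg.get("alpha", 0.05)),
            seed=seed,
            n_estimators=int(boruta_cfg.get("n_estimators", 500)),
        )
    except Exception as e:
        raise PipelineError("select", e) from e
    confirmed = [n for n in fm_train.feature_names if statuses[n] == "confirmed"]
    if not confirmed:
        raise PipelineError(
            "select", ValueError(f"stratum {stratum}: no features confirmed")
        )
    log.info("stratum %s: %d/%d features confirmed", stratum, len(confirmed), fm_train.p)

    fm_sel = fm_train.restrict(confirmed)
    try:
        model = fit_multinomial_lasso(
            fm_sel.X,
            fm_sel.labels,
            classes=fm_sel.classes,
            feature_names=confirmed,
            lam=lasso_cfg.get("lambda", "cv"),
            cv_folds=int(lasso_cfg.get("cv_folds", 5)),
            n_lambdas=int(lasso_cfg.get("n_lambdas", 20)),
            seed=seed,
        )
    except Exception as e:
        raise PipelineError("fit", e) from e
    model.save(out / f"model_{stratum}.json")

    entry: dict = {"n_train": len(train), "n_validation": len(validation)}
    try:
        for name, part in (("train", train), ("validation", validation)):
            fm_part = recode(part, vocab).restrict(confirmed)
            _, pred = predict(model, fm_part)
            truth = [c.true_label for c in part.cases]
            rep = accuracy_report(pred, truth, stratum)
            rep.confusion.to_csv(out / f"confusion_{stratum}_{name}.csv")
            entry[name] = rep.to_dict()
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("validate", e) from e

    try:
        dist = distill(
            model, sub, vocab, fit_on=distill_cfg.get("fit_on", "all"), seed=seed
        )
    except Exception as e:
        raise PipelineError("distill", e) from e
    entry["distillation"] = {
        "agreement": dist.agreement,
        "disagreements": dist.disagreements,
        "complexity": dist.complexity,
    }
    derived = [
        {
            "disease_id": cls,
            "disease_name": f"distilled rule for {cls}",
            "anatomic_class": stratum,
            "criteria": expr_to_dict(expr),
            "exclusions": [],
            "provenance": "distilled from fitted model (exclusions out of scope)",
        }
        for cls, expr in dist.rulesets.items()
    ]
    with open(out / f"rules_derived_{stratum}.json", "w", encoding="utf-8") as fh:
        json.dump(derived, fh, indent=2)
        fh.write("\n")
    return entry
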
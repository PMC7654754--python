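"""Confusion-matrix construction and the full evaluation-statistics suite.

Conventions follow the standard multi-class confusion-matrix toolkit:
predictions on rows, reference labels on columns.  Overall statistics are
accuracy with an exact (Clopper-Pearson) 95% binomial interval, the
no-information rate (largest reference-class prevalence), a one-sided exact
binomial p-value for accuracy exceeding that rate, Cohen's kappa, and the
McNemar-Bowker symmetry test (NaN when any symmetric off-diagonal pair is
empty, where the statistic is undefined).  Per-class statistics are the
one-vs-rest collapse: sensitivity, specificity, predictive values,
precision/recall/F1, prevalence, detection rate and prevalence, balanced
accuracy; 0/0 rates are reported as NaN rather than 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import CANONICAL_SUBTYPES, LabelSet, UNKNOWN_LABEL

logger = logging.getLogger(__name__)

PER_CLASS_COLUMNS = (
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "precision",
    "recall",
    "f1",
    "prevalence",
    "detection_rate",
    "detection_prevalence",
    "balanced_accuracy",
)


@dataclass
class ConfusionMatrix:
    """Counts of (predicted, reference) pairs; rows predict, columns refer."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over the class list")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[f"Pred_{c}" for c in self.classes],
            columns=[f"Ref_{c}" for c in self.classes],
        )


def confusion_matrix(
    predicted: LabelSet,
    reference: LabelSet,
    classes: tuple[str, ...] = CANONICAL_SUBTYPES,
) -> ConfusionMatrix:
    """Cross-tabulate predictions against reference labels.

    Only samples present in both sets contribute; samples whose reference
    (or predicted) label is Unknown are excluded with a logged count.
    """
    pred_map = predicted.mapping
    ref_map = reference.mapping
    shared = [s for s in predicted.sample_ids if s in ref_map]
    if not shared:
        raise ValueError("no samples shared between predictions and reference")
    dropped_unlabeled = len(pred_map) - len(shared)
    if dropped_unlabeled:
        logger.info(
            "%d predicted samples absent from reference, dropped",
            dropped_unlabeled,
        )
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    dropped_unknown = 0
    for s in shared:
        p, r = pred_map[s], ref_map[s]
        if r == UNKNOWN_LABEL or p == UNKNOWN_LABEL:
            dropped_unknown += 1
            continue
        counts[idx[p], idx[r]] += 1
    if dropped_unknown:
        logger.info("%d samples with Unknown labels excluded", dropped_unknown)
    if counts.sum() == 0:
        raise ValueError("no labeled samples to tabulate")
    return ConfusionMatrix(classes=tuple(classes), counts=counts)


def clopper_pearson(successes: int, total: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval from beta quantiles."""
    if total <= 0:
        raise ValueError("total must be > 0")
    lo = (
        0.0
        if successes == 0
        else float(stats.beta.ppf(alpha / 2, successes, total - successes + 1))
    )
    hi = (
        1.0
        if successes == total
        else float(stats.beta.ppf(1 - alpha / 2, successes + 1, total - successes))
    )
    return lo, hi


def _mcnemar_bowker_p(counts: np.ndarray) -> float:
    """Bowker symmetry test p-value; NaN when any off-diagonal pair is empty."""
    k = counts.shape[0]
    chi2 = 0.0
    df = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            s = counts[i, j] + counts[j, i]
            if s == 0:
                return float("nan")
            chi2 += (counts[i, j] - counts[j, i]) ** 2 / s
    return float(stats.chi2.sf(chi2, df))


def overall_stats(cm: ConfusionMatrix, alpha: float = 0.05) -> dict[str, float]:
    """Accuracy, exact CI, no-information rate and its test, kappa, McNemar."""
    counts = cm.counts.astype(float)
    total = cm.total
    trace = float(np.trace(counts))
    accuracy = trace / total
    ci_low, ci_high = clopper_pearson(int(trace), total, alpha)
    col_sums = counts.sum(axis=0)
    row_sums = counts.sum(axis=1)
    null_accuracy = float(col_sums.max()) / total
    accuracy_p = float(
        stats.binomtest(int(trace), total, null_accuracy, alternative="greater").pvalue
    )
    pe = float((row_sums * col_sums).sum()) / total**2
    kappa = (accuracy - pe) / (1 - pe) if pe < 1 else float("nan")
    return {
        "accuracy": accuracy,
        "accuracy_ci_low": ci_low,
        "accuracy_ci_high": ci_high,
        "null_accuracy": null_accuracy,
        "accuracy_p": accuracy_p,
        "kappa": kappa,
        "mcnemar_p": _mcnemar_bowker_p(cm.counts),
    }


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def class_stats(cm: ConfusionMatrix) -> pd.DataFrame:
    """One-vs-rest per-class statistics; 0/0 reported as NaN."""
    counts = cm.counts.astype(float)
    total = cm.total
    rows = {}
    for i, cls in enumerate(cm.classes):
        tp = counts[i, i]
        fp = counts[i, :].sum() - tp
        fn = counts[:, i].sum() - tp
        tn = total - tp - fp - fn
        sens = _ratio(tp, tp + fn)
        spec = _ratio(tn, tn + fp)
        ppv = _ratio(tp, tp + fp)
        npv = _ratio(tn, tn + fn)
        f1 = (
            _ratio(2 * ppv * sens, ppv + sens)
            if np.isfinite(ppv) and np.isfinite(sens) and (ppv + sens) > 0
            else float("nan")
        )
        rows[cls] = {
            "sensitivity": sens,
            "specificity": spec,
            "ppv": ppv,
            "npv": npv,
            "precision": ppv,
            "recall": sens,
            "f1": f1,
            "prevalence": (tp + fn) / total,
            "detection_rate": tp / total,
            "detection_prevalence": (tp + fp) / total,
            "balanced_accuracy": (sens + spec) / 2,
        }
    return pd.DataFrame.from_dict(rows, orient="index")[list(PER_CLASS_COLUMNS)]


@dataclass
class EvalReport:
    """Confusion matrix plus overall and per-class statistic blocks."""

    cm: ConfusionMatrix
    overall: dict[str, float]
    per_class: pd.DataFrame

    def to_flat(self) -> dict[str, float]:
        flat = dict(self.overall)
        for cls in self.per_class.index:
            for col in self.per_class.columns:
                flat[f"{cls}.{col}"] = float(self.per_class.loc[cls, col])
        return flat

    def to_text(self) -> str:
        def pct(x: float) -> str:
            return "NaN" if not np.isfinite(x) else f"{100 * x:.2f}%"

        lines = ["Confusion Matrix", self.cm.to_frame().to_string(), ""]
        lines.append("Overall Stats")
        lines.append(f"Accuracy\t{pct(self.overall['accuracy'])}")
        lines.append(f"Kappa\t{pct(self.overall['kappa'])}")
        lines.append(f"AccuracyLower\t{pct(self.overall['accuracy_ci_low'])}")
        lines.append(f"AccuracyUpper\t{pct(self.overall['accuracy_ci_high'])}")
        lines.append(f"AccuracyNull\t{pct(self.overall['null_accuracy'])}")
        lines.append(f"AccuracyPValue\t{self.overall['accuracy_p']:.2E}")
        mp = self.overall["mcnemar_p"]
        lines.append(
            "McnemarPValue\t" + ("NaN" if not np.isfinite(mp) else f"{mp:.4G}")
        )
        lines.append("")
        lines.append("Class Stats")
        shown = self.per_class.map(lambda v: pct(float(v)))
        shown.index = [f"Class: {c}" for c in self.per_class.index]
        lines.append(shown.to_string())
        return "\n".join(lines) + "\n"


def evaluate(predicted: LabelSet, reference: LabelSet) -> EvalReport:
    """Confusion matrix plus the full statistics suite in one call."""
    cm = confusion_matrix(predicted, reference)
    return EvalReport(cm=cm, overall=overall_stats(cm), per_class=class_stats(cm))


def write_report(report: EvalReport, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(report.to_text())
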
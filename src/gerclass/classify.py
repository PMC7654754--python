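"""Classification of samples against a trained ratio model.

Per sample the procedure is: (1) convert the expression matrix to ratio
values, (2) keep the ratios present in the model, (3) average each
subtype's ratio values into a score, (4) call the subtype with the highest
score.  Because ratios cancel any per-sample global offset on the log
scale, the scores need no further normalization before comparison.

A Welch one-sided t-test of the winning subtype's ratio values against each
other subtype's values (within the sample) yields three p-values whose
maximum is reported as a confidence value: a high value means at least one
competing subtype scores almost as well and the call deserves scrutiny.
It is not the probability the call is correct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import (
    CANONICAL_SUBTYPES,
    ExpressionMatrix,
    LabelSet,
    LINEAR_SCALE,
)
from .ger_model import GERModel
from .preprocess import log_transform

logger = logging.getLogger(__name__)

#: Coverage floors: below ``MIN_COVERAGE_FLAG`` of a subtype's model
#: features the sample is flagged; below ``MIN_COVERAGE_ERROR`` the run
#: errors (unless allow_partial).
MIN_COVERAGE_FLAG = 0.5
MIN_COVERAGE_ERROR = 0.1

#: Confidence values above this raise the "high-p" flag.
HIGH_P_FLAG_THRESHOLD = 0.05


@dataclass
class ClassificationResult:
    """Subtype call for one sample."""

    sample_id: str
    scores: dict[str, float]
    predicted: str
    confidence_p: float
    features_used: dict[str, int]
    flags: list[str] = field(default_factory=list)


def score_sample(values_by_subtype: dict[str, np.ndarray]) -> dict[str, float]:
    """Unweighted mean of each subtype's available ratio values."""
    scores = {}
    for subtype, vec in values_by_subtype.items():
        scores[subtype] = float(np.mean(vec)) if len(vec) else float("nan")
    return scores


def predict_label(scores: dict[str, float]) -> tuple[str, bool]:
    """Argmax over subtype scores; exact ties break by canonical order
    (Group3 < Group4 < SHH < WNT) and raise the tie flag."""
    items = [(s, scores[s]) for s in CANONICAL_SUBTYPES if s in scores]
    if not items:
        raise ValueError("no scores to rank")
    finite = [(s, v) for s, v in items if np.isfinite(v)]
    if len(finite) != len(items):
        bad = [s for s, v in items if not np.isfinite(v)]
        raise ValueError(f"non-finite scores for subtypes: {bad}")
    best = max(v for _, v in finite)
    winners = [s for s, v in finite if v == best]
    return winners[0], len(winners) > 1


def confidence_p(
    values_by_subtype: dict[str, np.ndarray],
    predicted: str,
    alternative: str = "greater",
) -> tuple[float, list[str]]:
    """Max p over Welch t-tests of predicted-subtype values vs each other's.

    One-sided by default (alternative "greater": evidence the winner's
    ratios are higher); "two-sided" available.  Any vector shorter than 2
    makes the test impossible; the p-value degrades to 1 with a flag.
    """
    flags: list[str] = []
    pred_vec = np.asarray(values_by_subtype[predicted], dtype=float)
    p_values = []
    for subtype, vec in values_by_subtype.items():
        if subtype == predicted:
            continue
        other = np.asarray(vec, dtype=float)
        if len(pred_vec) < 2 or len(other) < 2:
            flags.append(f"no-test:{subtype}")
            p_values.append(1.0)
            continue
        res = stats.ttest_ind(
            pred_vec, other, equal_var=False, alternative=alternative
        )
        p = float(res.pvalue)
        p_values.append(1.0 if np.isnan(p) else p)
    return (max(p_values) if p_values else 1.0), flags


def _model_feature_arrays(
    model: GERModel, gene_pos: dict[str, int]
) -> dict[str, tuple[np.ndarray, np.ndarray, int]]:
    """Per subtype: (numerator idx, denominator idx, total model features)."""
    out = {}
    for subtype in CANONICAL_SUBTYPES:
        feats = model.features_for(subtype)
        usable = [
            f
            for f in feats
            if f.numerator in gene_pos and f.denominator in gene_pos
        ]
        num = np.fromiter((gene_pos[f.numerator] for f in usable), dtype=int, count=len(usable))
        den = np.fromiter((gene_pos[f.denominator] for f in usable), dtype=int, count=len(usable))
        out[subtype] = (num, den, len(feats))
    return out


def classify_dataset(
    mat: ExpressionMatrix,
    model: GERModel,
    pseudocount: float = 1.0,
    allow_partial: bool = False,
    alternative: str = "greater",
    zscore: bool = False,
) -> list[ClassificationResult]:
    """Classify every sample of a matrix against a ratio model.

    Model features whose genes are absent from the matrix are dropped and
    counted.  Per-subtype coverage below 50% flags the run; below 10% (or
    zero computable features) it errors unless ``allow_partial``.  Samples
    are independent: the result for one sample never depends on the others.

    ``zscore`` additionally standardizes each sample's model-feature vector
    before scoring — an affine per-sample transform that cannot change the
    winning subtype but makes scores comparable across samples.
    """
    if mat.scale == LINEAR_SCALE:
        mat = log_transform(mat, pseudocount)
    gene_pos = {g: i for i, g in enumerate(mat.gene_ids)}
    arrays = _model_feature_arrays(model, gene_pos)

    dataset_flags: list[str] = []
    missing = sorted(set(model.genes()) - set(mat.gene_ids))
    for subtype, (num, den, total) in arrays.items():
        cov = len(num) / total if total else 0.0
        logger.info(
            "subtype %s: %d/%d model features computable (%.0f%%)",
            subtype, len(num), total, 100 * cov,
        )
        if len(num) == 0 or cov < MIN_COVERAGE_ERROR:
            msg = (
                f"subtype {subtype}: only {len(num)}/{total} model features "
                f"computable; missing genes include {missing[:10]}"
            )
            if not allow_partial:
                raise ValueError(msg)
            dataset_flags.append(f"low-coverage:{subtype}")
        elif cov < MIN_COVERAGE_FLAG:
            dataset_flags.append(f"low-coverage:{subtype}")

    vals = mat.values
    results: list[ClassificationResult] = []
    for j, sample_id in enumerate(mat.sample_ids):
        col = vals[:, j]
        vectors = {
            s: col[num] - col[den] for s, (num, den, _) in arrays.items()
        }
        if zscore:
            pooled = np.concatenate([v for v in vectors.values() if len(v)])
            mu, sd = pooled.mean(), pooled.std(ddof=0)
            if sd > 0:
                vectors = {s: (v - mu) / sd for s, v in vectors.items()}
        scorable = {s: v for s, v in vectors.items() if len(v)}
        scores = score_sample(vectors)
        predicted, tie = predict_label(
            {s: v for s, v in scores.items() if s in scorable}
        )
        p, p_flags = confidence_p(scorable, predicted, alternative)
        flags = list(dataset_flags) + p_flags
        if tie:
            flags.append("tie")
        if p > HIGH_P_FLAG_THRESHOLD:
            flags.append("high-p")
        results.append(
            ClassificationResult(
                sample_id=sample_id,
                scores=scores,
                predicted=predicted,
                confidence_p=p,
                features_used={s: len(v) for s, v in vectors.items()},
                flags=flags,
            )
        )
    return results


def results_to_frame(results: list[ClassificationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"sample_id": r.sample_id}
        for s in CANONICAL_SUBTYPES:
            row[f"score_{s}"] = r.scores.get(s, float("nan"))
        row["predicted"] = r.predicted
        row["confidence_p"] = r.confidence_p
        row["flags"] = ";".join(r.flags)
        rows.append(row)
    return pd.DataFrame(rows)


def results_to_labelset(results: list[ClassificationResult]) -> LabelSet:
    return LabelSet(
        [r.sample_id for r in results], [r.predicted for r in results]
    )


def write_results(results: list[ClassificationResult], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        results_to_frame(results).to_csv(fh, sep="\t", index=False)
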
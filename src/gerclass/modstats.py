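"""Empirical-Bayes moderated two-group differential expression.

The engine fits, per feature, a two-group comparison on log2 values and
shrinks the residual variance toward a prior estimated across features.
With prior degrees of freedom d0 and prior variance s0^2, the posterior
variance is

    s2_post = (d0 * s0^2 + d * s2) / (d0 + d)

and the moderated t-statistic is logFC / (se_unscaled * sqrt(s2_post)) on
d0 + d degrees of freedom, where se_unscaled = sqrt(1/n1 + 1/n2).  The
prior is estimated by moment-matching a scaled F distribution to the
observed sample variances on the log scale (digamma/trigamma equations),
the standard approach in the moderated-t literature.  d0 = 0 recovers the
ordinary pooled-variance t-test; d0 = inf fixes the variance at s0^2.

On top of the engine sits the three-step signature-gene selection used to
build the ratio-feature space:

  step 1  per-subtype pairwise contrasts; a gene is subtype-specific when it
          is up (or down) versus *every* other subtype;
  step 2  top-N genes per pairwise comparison by adjusted p, union;
  step 3  pool steps 1-2 and keep genes significantly up in at least one
          subtype and significantly down in another (one-vs-rest).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .expression_io import CANONICAL_SUBTYPES, LabelSet, LOG2_SCALE

logger = logging.getLogger(__name__)


@dataclass
class EBayesPrior:
    """Scaled-inverse-chi-square variance prior: d0 degrees of freedom,
    prior variance s0_sq.  d0 may be 0 (no moderation) or inf (full
    shrinkage)."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0 (possibly inf)")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be > 0")


@dataclass
class SelectionConfig:
    """Cutoffs for signature-gene and ratio-feature selection.

    adj_p_cutoff: BH-adjusted p-value cutoff (default 0.05).
    logfc_cutoff: |log2 fold change| required at the gene stage (default
        1.0, i.e. two-fold).
    ger_logfc_cutoff: |log2 fold change| required at the ratio stage
        (default 0.58, i.e. 1.5-fold ratios).
    top_n_pairwise: genes taken per pairwise comparison in step 2
        (default 250).
    """

    adj_p_cutoff: float = 0.05
    logfc_cutoff: float = 1.0
    ger_logfc_cutoff: float = 0.58
    top_n_pairwise: int = 250

    def __post_init__(self) -> None:
        if not (0 < self.adj_p_cutoff <= 1):
            raise ValueError("adj_p_cutoff must be in (0, 1]")
        if self.top_n_pairwise < 1:
            raise ValueError("top_n_pairwise must be >= 1")


@dataclass
class DETable:
    """Per-feature moderated-t results for one contrast."""

    contrast_id: str
    frame: pd.DataFrame  # columns: feature, logFC, t, p, adj_p, direction

    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        out.insert(1, "contrast", self.contrast_id)
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            out.to_csv(fh, sep="\t", index=False)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_ebayes_prior(sample_variances, d: float) -> EBayesPrior:
    """Moment-match the variance prior from observed sample variances.

    Under the model s^2 ~ s0^2 * F(d, d0), log s^2 has mean and variance
    expressible through digamma/trigamma functions; matching the observed
    moments yields d0 and s0^2.  When the observed dispersion of log s^2
    does not credibly exceed trigamma(d/2) — the dispersion pure sampling
    noise alone would produce — the prior degrees of freedom are infinite
    (all features share one variance, estimated as the mean sample
    variance).  "Credibly" means the excess dispersion must exceed twice
    its own null standard error; without that guard, sampling noise in the
    dispersion estimate flips the verdict on homogeneous data about half
    the time, yielding spuriously finite (if enormous) prior df.
    """
    s2 = np.asarray(sample_variances, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 10:
        raise ValueError("need at least 10 positive variances to fit prior")
    if d <= 0:
        raise ValueError("residual degrees of freedom must be > 0")
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    tri = float(special.polygamma(1, d / 2.0))
    evar = float(e.var(ddof=1)) - tri
    # null sampling SD of var(e): e has 4th central moment psi'''(d/2)+3*tri^2
    null_se = np.sqrt(
        (float(special.polygamma(3, d / 2.0)) + 2.0 * tri**2) / s2.size
    )
    if evar > 2.0 * null_se:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(
            np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    else:
        d0 = np.inf
        s0_sq = float(s2.mean())
    return EBayesPrior(d0=d0, s0_sq=s0_sq)


def _resolve_groups(labels: LabelSet, side) -> list[str]:
    """A contrast side is a subtype name or a collection of subtype names."""
    if isinstance(side, str):
        side = [side]
    samples: list[str] = []
    for subtype in side:
        got = labels.samples_with_label(subtype)
        if not got:
            raise ValueError(f"no samples labeled {subtype!r}")
        samples.extend(got)
    return samples


def moderated_t_test(
    x1: np.ndarray,
    x2: np.ndarray,
    prior: EBayesPrior | None = None,
    residual_blocks: list[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Vectorized moderated t across features (rows) for two sample groups.

    ``x1``/``x2`` are features x samples arrays of log2 values.  When
    ``prior`` is None it is estimated from the residual variances.  By
    default the residual variance is the two-group pooled estimate
    (df = n1 + n2 - 2).  When a contrast side pools several biological
    groups (one-vs-rest), pass ``residual_blocks`` — a partition of the
    samples into homogeneous groups (each block a features x samples
    array) — and the residual is computed within those blocks
    (df = n - #blocks), the linear-model behavior: systematic differences
    between the pooled groups then do not inflate the per-feature variance.
    Returns a frame with logFC (mean(x1) - mean(x2)), t, p (two-sided),
    and the flag column ``degenerate`` marking features with zero posterior
    variance (p set to 0 when the means differ, 1 when equal).
    """
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each contrast side needs >= 2 samples")
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    lfc = m1 - m2
    if residual_blocks is None:
        residual_blocks = [x1, x2]
    n_total = sum(b.shape[1] for b in residual_blocks)
    d = n_total - len(residual_blocks)
    if d < 1:
        raise ValueError("no residual degrees of freedom")
    rss = np.zeros(x1.shape[0])
    for block in residual_blocks:
        bm = block.mean(axis=1)
        rss += ((block - bm[:, None]) ** 2).sum(axis=1)
    s2 = rss / d
    if prior is None:
        try:
            prior = estimate_ebayes_prior(s2, d)
        except ValueError:
            # too few features to fit a prior: degrade to the ordinary t
            logger.warning(
                "cannot estimate variance prior from %d features; "
                "using unmoderated statistics", len(s2)
            )
            prior = EBayesPrior(d0=0, s0_sq=1.0)
    if prior.d0 == 0:
        s2_post = s2
        df_total = float(d)
    elif np.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = np.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + d * s2) / (prior.d0 + d)
        df_total = float(prior.d0 + d)
    se_unscaled = np.sqrt(1.0 / n1 + 1.0 / n2)
    degenerate = s2_post <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / (se_unscaled * np.sqrt(s2_post))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    if degenerate.any():
        t = np.where(degenerate, np.where(lfc > 0, np.inf, np.where(lfc < 0, -np.inf, 0.0)), t)
        p = np.where(degenerate, np.where(lfc != 0, 0.0, 1.0), p)
        logger.warning("%d features with zero posterior variance", int(degenerate.sum()))
    return pd.DataFrame(
        {"logFC": lfc, "t": t, "p": p, "degenerate": degenerate}
    )


def fit_moderated_de(
    mat,
    labels: LabelSet,
    contrast,
    prior: EBayesPrior | None = None,
    contrast_id: str | None = None,
) -> DETable:
    """Moderated DE for one contrast on a log2 expression or ratio matrix.

    ``mat`` is any object with ``values`` (features x samples),
    ``feature_ids`` and ``sample_ids`` (ExpressionMatrix or GERMatrix).
    ``contrast`` is a pair (target side, reference side); each side is a
    subtype name or collection of names whose samples are pooled.  The
    log fold change compares the pooled side means; the residual variance
    is computed within the constituent subtypes, so one-vs-rest contrasts
    are not penalized by the heterogeneity of the pooled reference.
    """
    if getattr(mat, "scale", LOG2_SCALE) != LOG2_SCALE:
        raise ValueError("differential expression expects log2-scale values")
    target, reference = contrast
    s_t = _resolve_groups(labels, target)
    s_r = _resolve_groups(labels, reference)
    if len(s_t) < 2 or len(s_r) < 2:
        raise ValueError(
            f"contrast sides need >= 2 samples (got {len(s_t)} vs {len(s_r)})"
        )
    col = {s: i for i, s in enumerate(mat.sample_ids)}
    vals = mat.values
    x1 = vals[:, [col[s] for s in s_t]]
    x2 = vals[:, [col[s] for s in s_r]]
    blocks = None
    sides = [side if not isinstance(side, str) else [side] for side in contrast]
    if any(len(side) > 1 for side in sides):
        blocks = []
        for side in sides:
            for subtype in side:
                cols = [col[s] for s in labels.samples_with_label(subtype)]
                if len(cols) >= 2:
                    blocks.append(vals[:, cols])
    res = moderated_t_test(x1, x2, prior=prior, residual_blocks=blocks)
    res.insert(0, "feature", list(mat.feature_ids))
    res["adj_p"] = bh_adjust(res["p"].to_numpy())
    res["direction"] = np.where(res["logFC"] > 0, "up", "down")
    if contrast_id is None:
        fmt = lambda side: side if isinstance(side, str) else "+".join(side)
        contrast_id = f"{fmt(target)}_vs_{fmt(reference)}"
    return DETable(contrast_id=contrast_id, frame=res)


def _sig_up(frame: pd.DataFrame, adj_p: float, lfc: float) -> set[str]:
    m = (frame["adj_p"] < adj_p) & (frame["logFC"] > lfc)
    return set(frame.loc[m, "feature"])


def _sig_down(frame: pd.DataFrame, adj_p: float, lfc: float) -> set[str]:
    m = (frame["adj_p"] < adj_p) & (frame["logFC"] < -lfc)
    return set(frame.loc[m, "feature"])


def _top_n(frame: pd.DataFrame, n: int) -> set[str]:
    # deterministic ordering: adj p, raw p, |logFC| descending, then symbol
    ranked = frame.assign(_abs=frame["logFC"].abs()).sort_values(
        ["adj_p", "p", "_abs", "feature"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    return set(ranked["feature"].head(n))


@dataclass
class SignatureResult:
    """Output of the three-step signature-gene selection."""

    subtype_up: dict[str, set[str]]      # step 1 per-subtype specific-up
    subtype_down: dict[str, set[str]]    # step 1 per-subtype specific-down
    pairwise_union: set[str]             # step 2 union of top-N genes
    ovr_up: dict[str, set[str]]          # one-vs-rest significant up (step 3)
    ovr_down: dict[str, set[str]]        # one-vs-rest significant down (step 3)
    genes: list[str]                     # final pooled signature, sorted

    def direction_in(self, subtype: str, gene: str) -> str | None:
        if gene in self.ovr_up.get(subtype, set()):
            return "up"
        if gene in self.ovr_down.get(subtype, set()):
            return "down"
        return None


def select_signature_genes(
    mat,
    labels: LabelSet,
    config: SelectionConfig | None = None,
) -> SignatureResult:
    """Three-step selection of subtype-discriminating genes on a log2 matrix.

    Step 3 keeps a pooled gene when its one-vs-rest contrasts show it
    significantly (BH-adjusted p below the cutoff) up in at least one
    subtype and significantly down in another.  No fold-change floor is
    applied at this final step: pooling three subtypes into the reference
    dilutes the apparent fold change of the non-elevated groups by ~1/3, so
    a full gene-stage cutoff there would discard genuinely discriminating
    genes that the earlier steps already vetted.
    """
    config = config or SelectionConfig()
    subtypes = labels.present_subtypes(min_samples=2)
    if len(subtypes) < 2:
        raise ValueError("need >= 2 subtypes with >= 2 samples each")
    shared = [s for s in mat.sample_ids if s in set(labels.sample_ids)]
    labels = labels.subset(shared)

    pairwise: dict[tuple[str, str], pd.DataFrame] = {}
    for i, a in enumerate(subtypes):
        for b in subtypes[i + 1:]:
            pairwise[(a, b)] = fit_moderated_de(mat, labels, (a, b)).frame

    def frame_for(s: str, t: str) -> tuple[pd.DataFrame, int]:
        """Pairwise frame oriented as s-vs-t (sign +1) or flipped (-1)."""
        if (s, t) in pairwise:
            return pairwise[(s, t)], +1
        return pairwise[(t, s)], -1

    subtype_up: dict[str, set[str]] = {}
    subtype_down: dict[str, set[str]] = {}
    for s in subtypes:
        ups, downs = [], []
        for t in subtypes:
            if t == s:
                continue
            frame, sign = frame_for(s, t)
            if sign > 0:
                ups.append(_sig_up(frame, config.adj_p_cutoff, config.logfc_cutoff))
                downs.append(_sig_down(frame, config.adj_p_cutoff, config.logfc_cutoff))
            else:
                ups.append(_sig_down(frame, config.adj_p_cutoff, config.logfc_cutoff))
                downs.append(_sig_up(frame, config.adj_p_cutoff, config.logfc_cutoff))
        subtype_up[s] = set.intersection(*ups) if ups else set()
        subtype_down[s] = set.intersection(*downs) if downs else set()

    pairwise_union: set[str] = set()
    for frame in pairwise.values():
        pairwise_union |= _top_n(frame, config.top_n_pairwise)

    pooled: set[str] = set(pairwise_union)
    for s in subtypes:
        pooled |= subtype_up[s] | subtype_down[s]

    ovr_up: dict[str, set[str]] = {}
    ovr_down: dict[str, set[str]] = {}
    for s in subtypes:
        rest = [t for t in subtypes if t != s]
        frame = fit_moderated_de(mat, labels, (s, rest)).frame
        ovr_up[s] = _sig_up(frame, config.adj_p_cutoff, 0.0) & pooled
        ovr_down[s] = _sig_down(frame, config.adj_p_cutoff, 0.0) & pooled

    # a gene cannot be both up and down in the same one-vs-rest contrast,
    # so "up somewhere and down elsewhere" is membership in both unions
    any_up = set().union(*ovr_up.values())
    any_down = set().union(*ovr_down.values())
    genes = sorted(pooled & any_up & any_down)
    if not genes:
        logger.warning("signature selection returned no genes")
    return SignatureResult(
        subtype_up=subtype_up,
        subtype_down=subtype_down,
        pairwise_union=pairwise_union,
        ovr_up=ovr_up,
        ovr_down=ovr_down,
        genes=genes,
    )
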
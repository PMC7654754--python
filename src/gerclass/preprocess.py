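"""Gene filtering cascade applied before feature selection.

The RNA-seq training path filters genes in four steps: (1) drop genes whose
maximum linear expression never exceeds an FPKM floor, so technical noise on
barely-expressed genes cannot masquerade as variance; (2) log2-transform;
(3) drop low-variability genes by standardized coefficient of variation;
(4) drop mitochondrial / ribosomal / small-nuclear-RNA families, whose
expression tracks sampling and capture protocol more than biology.

Every filter is a pure gene-subset operation: it never touches the sample
axis and never alters surviving values.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .expression_io import ExpressionMatrix, LINEAR_SCALE, LOG2_SCALE

logger = logging.getLogger(__name__)

#: Symbol-prefix patterns for excluded gene families (mitochondrial,
#: mitochondrial/cytosolic ribosomal proteins, small nuclear/nucleolar RNA,
#: 5S/7S RNA).  Anchored at the symbol start; case-insensitive.  These are
#: configuration, not code — pass your own list to override.
DEFAULT_EXCLUDED_PATTERNS = (
    r"^MT-",
    r"^MRPL",
    r"^MRPS",
    r"^RPL",
    r"^RPS",
    r"^RNU",
    r"^SNOR",
    r"^RNA5S",
    r"^RN7S",
)


class ConfigError(ValueError):
    """Invalid filter configuration (e.g. a malformed regex)."""


@dataclass
class FilterConfig:
    """Thresholds for the preprocessing cascade.

    fpkm_threshold:
        Linear-scale floor; a gene survives iff max across samples is
        strictly greater (default 20).
    cv_z_threshold:
        Cutoff on the standardized per-gene CV of log2 expression
        (default -1; genes at or above it survive).
    excluded_family_patterns:
        Anchored case-insensitive regexes for families to drop.
    pseudocount:
        Added before log2 (default 1).
    """

    fpkm_threshold: float = 20.0
    cv_z_threshold: float = -1.0
    excluded_family_patterns: tuple[str, ...] = DEFAULT_EXCLUDED_PATTERNS
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.fpkm_threshold < 0:
            raise ConfigError("fpkm_threshold must be >= 0")
        if self.pseudocount <= 0:
            raise ConfigError("pseudocount must be > 0")


def filter_max_expression(mat: ExpressionMatrix, threshold: float = 20.0) -> ExpressionMatrix:
    """Keep genes whose maximum linear expression exceeds ``threshold``.

    The inequality is strict: a gene whose maximum equals the threshold is
    removed.  Linear-scale input required.
    """
    if mat.scale != LINEAR_SCALE:
        raise ValueError(
            "filter_max_expression requires linear-scale values; supply the "
            "matrix before log transform or skip this filter for log2 data"
        )
    keep = mat.values.max(axis=1) > threshold
    return mat.with_data(mat.data.loc[keep])


def log_transform(mat: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(value + pseudocount); flips the scale flag to log2."""
    if mat.scale != LINEAR_SCALE:
        raise ValueError("matrix is already log2-scaled")
    if pseudocount <= 0:
        raise ConfigError("pseudocount must be > 0")
    vals = mat.values
    if (vals < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    data = mat.data.copy()
    data.loc[:, :] = np.log2(vals + pseudocount)
    return mat.with_data(data, scale=LOG2_SCALE)


def filter_cv(mat: ExpressionMatrix, cv_z_threshold: float = -1.0) -> ExpressionMatrix:
    """Drop low-variability genes by standardized coefficient of variation.

    Per gene, CV = sd/mean of log2 values across samples (sample sd,
    ddof=1).  The CV vector is standardized across genes (z-scores), and
    genes with z >= ``cv_z_threshold`` are retained.  Genes whose log-scale
    mean is <= 0 receive CV = +inf (maximally variable relative to mean) and
    are always retained.  If all finite CVs are identical the
    standardization is undefined; everything is retained with a warning.
    """
    if mat.scale != LOG2_SCALE:
        raise ValueError("filter_cv expects log2-scale values")
    if mat.shape[1] < 2:
        raise ValueError("filter_cv needs at least 2 samples")
    vals = mat.values
    means = vals.mean(axis=1)
    sds = vals.std(axis=1, ddof=1)
    cv = np.full(len(means), np.inf)
    ok = means > 0
    cv[ok] = sds[ok] / means[ok]
    finite = np.isfinite(cv)
    if finite.sum() == 0:
        logger.warning("all CVs infinite; retaining all genes")
        return mat.with_data(mat.data.copy())
    mu = cv[finite].mean()
    sigma = cv[finite].std(ddof=1) if finite.sum() > 1 else 0.0
    if sigma == 0:
        logger.warning(
            "CV distribution degenerate (sd 0); standardization undefined, "
            "retaining all genes"
        )
        return mat.with_data(mat.data.copy())
    z = np.where(finite, (cv - mu) / sigma, np.inf)
    return mat.with_data(mat.data.loc[z >= cv_z_threshold])


def exclude_gene_families(
    mat: ExpressionMatrix,
    patterns: tuple[str, ...] = DEFAULT_EXCLUDED_PATTERNS,
) -> ExpressionMatrix:
    """Remove genes whose symbol matches any pattern (anchored, case-insensitive)."""
    try:
        compiled = [re.compile(p, re.IGNORECASE) for p in patterns]
    except re.error as exc:
        raise ConfigError(f"invalid exclusion pattern: {exc}") from exc
    if not compiled:
        return mat.with_data(mat.data.copy())
    keep = [
        g for g in mat.gene_ids if not any(c.match(g) for c in compiled)
    ]
    return mat.with_data(mat.data.loc[keep])


def preprocess(mat: ExpressionMatrix, config: FilterConfig | None = None) -> ExpressionMatrix:
    """Run the full cascade; the linear-only steps are skipped for log2 input.

    Linear input: max-expression filter -> log transform -> CV filter ->
    family exclusion.  Log2 input (microarray): CV filter -> family
    exclusion only, since the FPKM floor is an RNA-seq notion.
    """
    config = config or FilterConfig()
    if mat.scale == LINEAR_SCALE:
        mat = filter_max_expression(mat, config.fpkm_threshold)
        if mat.shape[0] == 0:
            raise ValueError("no genes pass the max-expression filter")
        mat = log_transform(mat, config.pseudocount)
    mat = filter_cv(mat, config.cv_z_threshold)
    mat = exclude_gene_families(mat, config.excluded_family_patterns)
    if mat.shape[0] == 0:
        raise ValueError("no genes survive preprocessing")
    return mat
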
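"""Synthetic labeled expression data with planted subtype structure.

The generator emulates the structure the pipeline's feature selection
assumes: four sample groups (Group3/Group4/SHH/WNT), per-gene log-normal
expression (normal on the log2 scale), and a set of planted marker genes
per subtype that are shifted up or down by a fixed log2 effect in their
subtype only.  A platform pair can be simulated for cross-platform
experiments: a second cohort drawn from the same ground truth with
per-gene additive offsets (systematic technology bias) and a subsampled
gene set (panel/annotation loss).

What it deliberately does not model: gene-gene correlation, batch effects
within a cohort, count noise at low expression, or the mixed hierarchy of
real tumor transcriptomes — results on this generator demonstrate pipeline
correctness, not clinical performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .expression_io import (
    CANONICAL_SUBTYPES,
    ExpressionMatrix,
    LabelSet,
    LINEAR_SCALE,
    LOG2_SCALE,
)


@dataclass
class SimConfig:
    """Generator parameters.

    n_per_subtype:
        Samples per subtype (default 25, a cohort of 100 — the scale of a
        typical single training study).
    n_genes:
        Total genes (default 2000; enough for the filters to act on a
        realistic background while keeping the ratio space tractable).
    n_markers_per_subtype / n_down_markers_per_subtype:
        Planted up-/down-regulated genes per subtype (default 10 each).
    effect_log2fc:
        Planted shift in log2 units (default 3, an eight-fold change —
        marker-grade separation).
    noise_sd:
        Within-group SD on the log2 scale (default 0.5).
    baseline_log2_mean / baseline_log2_sd:
        Per-gene baseline distribution (default 7 +/- 1.5 log2 units, i.e.
        typical expression near 128 linear units).
    platform_shift_sd:
        SD of per-gene additive offsets for the second platform
        (default 0.5).
    platform_b_gene_fraction:
        Fraction of genes retained on the second platform (default 0.96).
    seed:
        RNG seed; every output is reproducible from it.
    """

    n_per_subtype: int = 25
    n_genes: int = 2000
    n_markers_per_subtype: int = 10
    n_down_markers_per_subtype: int = 10
    effect_log2fc: float = 3.0
    noise_sd: float = 0.5
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    platform_shift_sd: float = 0.5
    platform_b_gene_fraction: float = 0.96
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_subtype, self.n_genes) < 1:
            raise ValueError("n_per_subtype and n_genes must be >= 1")
        if self.n_markers_per_subtype < 0 or self.n_down_markers_per_subtype < 0:
            raise ValueError("marker counts must be >= 0")
        per = self.n_markers_per_subtype + self.n_down_markers_per_subtype
        if per * len(CANONICAL_SUBTYPES) > self.n_genes:
            raise ValueError("more planted markers than genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not (0 < self.platform_b_gene_fraction <= 1):
            raise ValueError("platform_b_gene_fraction must be in (0, 1]")


@dataclass
class GroundTruth:
    """Fixed quantities shared by all sample draws from one configuration."""

    gene_ids: list[str]
    baselines: np.ndarray           # per-gene baseline log2 mean
    effects: np.ndarray             # genes x subtypes log2 shifts
    marker_table: pd.DataFrame      # columns: gene, subtype, direction


def _make_ground_truth(config: SimConfig, rng: np.random.Generator) -> GroundTruth:
    width = max(4, len(str(config.n_genes)))
    gene_ids = [f"GENE{i + 1:0{width}d}" for i in range(config.n_genes)]
    baselines = rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes
    )
    per = config.n_markers_per_subtype + config.n_down_markers_per_subtype
    chosen = rng.choice(config.n_genes, per * len(CANONICAL_SUBTYPES), replace=False)
    effects = np.zeros((config.n_genes, len(CANONICAL_SUBTYPES)))
    records = []
    pos = 0
    for k, subtype in enumerate(CANONICAL_SUBTYPES):
        for _ in range(config.n_markers_per_subtype):
            g = chosen[pos]
            effects[g, k] = config.effect_log2fc
            records.append((gene_ids[g], subtype, "up"))
            pos += 1
        for _ in range(config.n_down_markers_per_subtype):
            g = chosen[pos]
            effects[g, k] = -config.effect_log2fc
            records.append((gene_ids[g], subtype, "down"))
            pos += 1
    table = pd.DataFrame(records, columns=["gene", "subtype", "direction"])
    return GroundTruth(
        gene_ids=gene_ids, baselines=baselines, effects=effects,
        marker_table=table,
    )


def _draw_samples(
    truth: GroundTruth,
    config: SimConfig,
    rng: np.random.Generator,
    sample_prefix: str,
    scale: str,
    gene_offsets: np.ndarray | None = None,
    platform: str = "synthetic",
) -> tuple[ExpressionMatrix, LabelSet]:
    n = config.n_per_subtype
    labels = [s for s in CANONICAL_SUBTYPES for _ in range(n)]
    sample_ids = [f"{sample_prefix}{i + 1:04d}" for i in range(len(labels))]
    subtype_idx = np.repeat(np.arange(len(CANONICAL_SUBTYPES)), n)
    mean = truth.baselines[:, None] + truth.effects[:, subtype_idx]
    if gene_offsets is not None:
        mean = mean + gene_offsets[:, None]
    log2_vals = mean + rng.normal(0.0, config.noise_sd, mean.shape)
    if scale == LINEAR_SCALE:
        values = np.maximum(np.exp2(log2_vals) - 1.0, 0.0)
    elif scale == LOG2_SCALE:
        values = log2_vals
    else:
        raise ValueError(f"unknown scale {scale!r}")
    data = pd.DataFrame(values, index=truth.gene_ids, columns=sample_ids)
    mat = ExpressionMatrix(data=data, scale=scale, platform=platform)
    return mat, LabelSet(sample_ids, labels)


def simulate_dataset(
    config: SimConfig,
    scale: str = LINEAR_SCALE,
    sample_prefix: str = "S",
) -> tuple[ExpressionMatrix, LabelSet, pd.DataFrame]:
    """One labeled cohort plus its ground-truth marker table.

    Log2 values are baseline + planted effect + Gaussian noise; on the
    linear scale the output is 2^value - 1 clipped at zero, so a later
    log2(x + 1) transform recovers the log-scale values exactly up to the
    clip.  Identical configs (and seeds) give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    truth = _make_ground_truth(config, rng)
    mat, labels = _draw_samples(truth, config, rng, sample_prefix, scale)
    return mat, labels, truth.marker_table


def simulate_platform_pair(
    config: SimConfig,
    scale: str = LINEAR_SCALE,
    n_genes_platform_b: int | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, LabelSet, pd.DataFrame]:
    """Two cohorts from one ground truth, the second on a shifted platform.

    Cohort A (samples ``A####``) is drawn as in :func:`simulate_dataset`.
    Cohort B (samples ``B####``) is an independent draw with per-gene
    additive offsets ~ Normal(0, platform_shift_sd) and a randomly
    subsampled gene set of ``n_genes_platform_b`` genes (default:
    platform_b_gene_fraction of the total).  Returns both matrices, one
    label set covering the disjoint sample ids of both cohorts, and the
    marker table.
    """
    rng = np.random.default_rng(config.seed)
    truth = _make_ground_truth(config, rng)
    mat_a, labels_a = _draw_samples(
        truth, config, rng, "A", scale, platform="platformA"
    )
    offsets = rng.normal(0.0, config.platform_shift_sd, config.n_genes)
    mat_b, labels_b = _draw_samples(
        truth, config, rng, "B", scale, gene_offsets=offsets,
        platform="platformB",
    )
    if n_genes_platform_b is None:
        n_genes_platform_b = int(
            round(config.platform_b_gene_fraction * config.n_genes)
        )
    if not (1 <= n_genes_platform_b <= config.n_genes):
        raise ValueError("n_genes_platform_b out of range")
    keep = np.sort(
        rng.choice(config.n_genes, n_genes_platform_b, replace=False)
    )
    mat_b = mat_b.with_data(mat_b.data.iloc[keep])
    labels = LabelSet(
        labels_a.sample_ids + labels_b.sample_ids,
        labels_a.labels + labels_b.labels,
    )
    return mat_a, mat_b, labels, truth.marker_table
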
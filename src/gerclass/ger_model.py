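"""Gene-expression-ratio (GER) features: construction, selection, models.

A GER feature is the within-sample log2 ratio of two genes' expression,
numerator over denominator.  Ratios self-normalize: any per-sample offset
common to both genes on the log scale cancels, which is what lets one model
span RNA-seq and microarray data.  A trained model is, per subtype, the set
of directed gene pairs whose ratio is significantly elevated in that
subtype and in no other.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_io import (
    CANONICAL_SUBTYPES,
    ExpressionMatrix,
    LabelSet,
    LINEAR_SCALE,
    LOG2_SCALE,
)
from .modstats import SelectionConfig, fit_moderated_de, select_signature_genes
from .preprocess import FilterConfig, log_transform, preprocess

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GERFeature:
    """Directed gene-pair ratio assigned to one subtype."""

    numerator: str
    denominator: str
    subtype: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ValueError(
                f"degenerate ratio {self.numerator}/{self.denominator}"
            )
        if self.subtype not in CANONICAL_SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.numerator, self.denominator, self.subtype)


@dataclass
class GERModel:
    """Set of subtype-assigned ratio features plus training provenance."""

    features: list[GERFeature]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [f.key for f in self.features]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (numerator, denominator, subtype) features")
        for s in CANONICAL_SUBTYPES:
            if not self.features_for(s):
                logger.warning("model has no features for subtype %s", s)

    def features_for(self, subtype: str) -> list[GERFeature]:
        return [f for f in self.features if f.subtype == subtype]

    def genes(self) -> list[str]:
        out: set[str] = set()
        for f in self.features:
            out.add(f.numerator)
            out.add(f.denominator)
        return sorted(out)

    def __len__(self) -> int:
        return len(self.features)


@dataclass
class GERMatrix:
    """Ratio-feature x sample matrix of log2 ratio values."""

    pairs: list[tuple[str, str]]
    sample_ids: list[str]
    values: np.ndarray  # features x samples, log2-ratio units

    scale: str = LOG2_SCALE  # log2 ratios behave like log2 expression in DE

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.pairs), len(self.sample_ids)):
            raise ValueError("GER matrix shape mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("GER values must be finite")

    @property
    def feature_ids(self) -> list[str]:
        return [f"{a}/{b}" for a, b in self.pairs]


def enumerate_gers(
    genes: list[str], mode: str = "unordered"
) -> list[tuple[str, str]]:
    """All gene pairs from a symbol list.

    ``unordered`` yields one pair per unordered combination, n(n-1)/2, with
    the lexicographically smaller symbol as numerator (orientation is
    resolved later, at selection time).  ``ordered`` yields both
    orientations, n(n-1).
    """
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene symbols")
    ordered_genes = sorted(genes)
    if mode == "unordered":
        return list(itertools.combinations(ordered_genes, 2))
    if mode == "ordered":
        return list(itertools.permutations(ordered_genes, 2))
    raise ValueError(f"unknown mode {mode!r}")


def build_ger_matrix(
    mat: ExpressionMatrix,
    pairs: list[tuple[str, str]],
    pseudocount: float = 1.0,
) -> GERMatrix:
    """Log2 ratio matrix for the given pairs.

    Linear input: value = log2(E_num + pseudocount) - log2(E_den +
    pseudocount).  Log2 input: plain difference.
    """
    gene_pos = {g: i for i, g in enumerate(mat.gene_ids)}
    missing = sorted(
        {g for pair in pairs for g in pair if g not in gene_pos}
    )
    if missing:
        raise ValueError(f"genes absent from matrix: {missing[:20]}")
    vals = mat.values
    if mat.scale == LINEAR_SCALE:
        vals = np.log2(vals + pseudocount)
    num_idx = np.fromiter((gene_pos[a] for a, _ in pairs), dtype=int, count=len(pairs))
    den_idx = np.fromiter((gene_pos[b] for _, b in pairs), dtype=int, count=len(pairs))
    values = vals[num_idx, :] - vals[den_idx, :]
    return GERMatrix(pairs=list(pairs), sample_ids=mat.sample_ids, values=values)


def select_subtype_gers(
    gmat: GERMatrix,
    labels: LabelSet,
    config: SelectionConfig | None = None,
    source: str = "",
) -> list[GERFeature]:
    """Ratios significantly elevated in exactly one subtype, one-vs-rest.

    Each enumerated pair is tested in both orientations (a ratio down in a
    subtype is its flip up): orientation X/Y is kept for subtype S when the
    S-vs-rest contrast shows adjusted p below the cutoff with log2 fold
    change above the ratio cutoff, and no other subtype's contrast does.
    The stored feature is always the up direction in its subtype.
    """
    config = config or SelectionConfig()
    subtypes = labels.present_subtypes(min_samples=2)
    if len(subtypes) < 2:
        raise ValueError("need >= 2 subtypes with >= 2 samples each")
    shared = [s for s in gmat.sample_ids if s in set(labels.sample_ids)]
    labels = labels.subset(shared)

    up = {}
    down = {}
    for s in subtypes:
        rest = [t for t in subtypes if t != s]
        frame = fit_moderated_de(gmat, labels, (s, rest)).frame
        sig = frame["adj_p"] < config.adj_p_cutoff
        up[s] = (sig & (frame["logFC"] > config.ger_logfc_cutoff)).to_numpy()
        down[s] = (sig & (frame["logFC"] < -config.ger_logfc_cutoff)).to_numpy()

    n_up = np.sum([up[s] for s in subtypes], axis=0)
    n_down = np.sum([down[s] for s in subtypes], axis=0)

    features: list[GERFeature] = []
    for s in subtypes:
        only_up = up[s] & (n_up == 1)
        for i in np.flatnonzero(only_up):
            a, b = gmat.pairs[i]
            features.append(GERFeature(a, b, s, source))
        only_down = down[s] & (n_down == 1)
        for i in np.flatnonzero(only_down):
            a, b = gmat.pairs[i]
            features.append(GERFeature(b, a, s, source))  # flipped: up in s
    empty = [s for s in subtypes if not any(f.subtype == s for f in features)]
    if empty:
        logger.warning("no ratio features selected for subtypes: %s", empty)
    return features


def train_on_dataset(
    mat: ExpressionMatrix,
    labels: LabelSet,
    gene_subset: list[str] | None = None,
    filter_config: FilterConfig | None = None,
    selection_config: SelectionConfig | None = None,
    source: str = "",
    enumeration: str = "unordered",
) -> GERModel:
    """Train a ratio model on one labeled dataset.

    Without ``gene_subset`` this is the primary-dataset path: preprocessing
    cascade, three-step signature-gene selection, ratio enumeration and
    subtype-specific ratio selection.  With ``gene_subset`` (the transfer
    path for a second platform) the matrix is first intersected with the
    given genes — typically the genes of an existing model — and the
    signature-selection stage is skipped.
    """
    filter_config = filter_config or FilterConfig()
    selection_config = selection_config or SelectionConfig()
    shared = [s for s in mat.sample_ids if s in set(labels.sample_ids)]
    if not shared:
        raise ValueError("no overlap between matrix samples and labels")
    mat = mat.subset_samples(shared)
    labels = labels.subset(shared)
    if len(labels.present_subtypes(min_samples=2)) < 2:
        raise ValueError("need >= 2 subtypes with >= 2 labeled samples")

    if gene_subset is None:
        filtered = preprocess(mat, filter_config)
        signature = select_signature_genes(filtered, labels, selection_config)
        genes = signature.genes
        if len(genes) < 2:
            raise ValueError("signature selection left < 2 genes")
        work = filtered.subset_genes(genes)
        n_signature = len(genes)
    else:
        genes = sorted(set(gene_subset) & set(mat.gene_ids))
        if len(genes) < 2:
            raise ValueError(
                "gene_subset shares < 2 genes with the matrix "
                f"({len(genes)} found)"
            )
        work = mat.subset_genes(genes)
        if work.scale == LINEAR_SCALE:
            work = log_transform(work, filter_config.pseudocount)
        n_signature = len(genes)

    pairs = enumerate_gers(genes, mode=enumeration)
    gmat = build_ger_matrix(work, pairs, filter_config.pseudocount)
    features = select_subtype_gers(gmat, labels, selection_config, source)
    metadata = {
        "source": source,
        "n_samples": len(labels),
        "n_signature_genes": n_signature,
        "n_pairs": len(pairs),
        "n_features": len(features),
        "enumeration": enumeration,
        "transfer": gene_subset is not None,
        "adj_p_cutoff": selection_config.adj_p_cutoff,
        "logfc_cutoff": selection_config.logfc_cutoff,
        "ger_logfc_cutoff": selection_config.ger_logfc_cutoff,
    }
    return GERModel(features=features, metadata=metadata)


def merge_models(a: GERModel, b: GERModel) -> GERModel:
    """Set union of two models on (numerator, denominator, subtype)."""
    seen: dict[tuple[str, str, str], GERFeature] = {}
    for f in list(a.features) + list(b.features):
        if f.key not in seen:
            seen[f.key] = f
    metadata = {"merged_from": [a.metadata, b.metadata]}
    return GERModel(features=sorted(seen.values(), key=lambda f: f.key), metadata=metadata)


MODEL_COLUMNS = ("numerator", "denominator", "subtype", "source")


def save_model(model: GERModel, path) -> None:
    """Write a model as TSV with a commented JSON metadata header."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        meta = json.dumps(model.metadata, default=str)
        fh.write(f"# gerclass-model-v1 {meta}\n")
        fh.write("\t".join(MODEL_COLUMNS) + "\n")
        for f in sorted(model.features, key=lambda f: f.key):
            fh.write(f"{f.numerator}\t{f.denominator}\t{f.subtype}\t{f.source}\n")


class ModelFormatError(ValueError):
    """Malformed model file."""


def load_model(path) -> GERModel:
    metadata: dict = {}
    features: list[GERFeature] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            payload = line.lstrip("#").strip()
            if payload.startswith("gerclass-model-v1"):
                blob = payload[len("gerclass-model-v1"):].strip()
                if blob:
                    try:
                        metadata = json.loads(blob)
                    except json.JSONDecodeError as exc:
                        raise ModelFormatError(
                            f"{path}:{i + 1}: bad metadata JSON: {exc}"
                        ) from exc
            continue
        body_start = i
        break
    header = lines[body_start].split("\t")
    if tuple(header[:3]) != MODEL_COLUMNS[:3]:
        raise ModelFormatError(
            f"{path}:{body_start + 1}: expected header "
            f"{MODEL_COLUMNS!r}, got {header!r}"
        )
    for lineno, line in enumerate(lines[body_start + 1:], body_start + 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ModelFormatError(f"{path}:{lineno}: expected >= 3 columns")
        num, den, subtype = parts[0], parts[1], parts[2]
        src = parts[3] if len(parts) > 3 else ""
        try:
            features.append(GERFeature(num, den, subtype, src))
        except ValueError as exc:
            raise ModelFormatError(f"{path}:{lineno}: {exc}") from exc
    try:
        return GERModel(features=features, metadata=metadata)
    except ValueError as exc:
        raise ModelFormatError(f"{path}: {exc}") from exc
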
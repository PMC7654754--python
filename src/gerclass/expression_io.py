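"""Reading and writing expression matrices and subtype label tables.

Expression matrices are delimited text (TSV by default): gene symbols in the
first column, a header row of sample identifiers, and numeric expression
values in the body.  RNA-seq matrices are expected on the linear FPKM scale,
microarray matrices on the log2 intensity scale; the scale is auto-detected
but can be forced with ``scale_hint``.

Subtype labels come in many dialects across public datasets ("G3",
"Group 3", "SHH TP53 mutant", ...); :func:`harmonize_labels` collapses them
onto the four-class vocabulary Group3/Group4/SHH/WNT, degrading anything
unrecognized to ``Unknown`` rather than aborting.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The four transcriptomic medulloblastoma subtypes the classifier targets.
CANONICAL_SUBTYPES = ("Group3", "Group4", "SHH", "WNT")
UNKNOWN_LABEL = "Unknown"
LABEL_VOCABULARY = CANONICAL_SUBTYPES + (UNKNOWN_LABEL,)

LINEAR_SCALE = "linear"
LOG2_SCALE = "log2"

#: Threshold for scale auto-detection: log2 expression rarely exceeds 30,
#: while FPKM and linear microarray intensities routinely do.
SCALE_DETECT_MAX = 30.0


class ParseError(ValueError):
    """Malformed input file (non-numeric cell, missing column, ...)."""


def _normalize_raw_label(raw: str) -> str:
    return re.sub(r"[^a-z0-9]+", " ", str(raw).lower()).strip()


# Mapping table from normalized raw labels to canonical subtypes.  This is
# data, not code: extend via the extra_mapping argument of harmonize_labels.
# Letter-group entries follow the historical A=WNT/B=SHH/C=Group3/D=Group4
# nomenclature used by several microarray studies.
DEFAULT_LABEL_MAP: dict[str, str] = {
    "group3": "Group3",
    "group 3": "Group3",
    "g3": "Group3",
    "grp3": "Group3",
    "grp 3": "Group3",
    "gr3": "Group3",
    "group iii": "Group3",
    "group c": "Group3",
    "g34": "Unknown",  # ambiguous Group3/4 annotations stay Unknown
    "group4": "Group4",
    "group 4": "Group4",
    "g4": "Group4",
    "grp4": "Group4",
    "grp 4": "Group4",
    "gr4": "Group4",
    "group iv": "Group4",
    "group d": "Group4",
    "shh": "SHH",
    "shh tp53 mutant": "SHH",
    "shh tp53 wildtype": "SHH",
    "shh tp53 wild type": "SHH",
    "shh mutant": "SHH",
    "shh wildtype": "SHH",
    "sonic hedgehog": "SHH",
    "group b": "SHH",
    "wnt": "WNT",
    "wingless": "WNT",
    "group a": "WNT",
    "unknown": "Unknown",
    "na": "Unknown",
    "": "Unknown",
}

# Fallback patterns applied (in order) when the exact table misses.
_FALLBACK_PATTERNS: tuple[tuple[str, str], ...] = (
    (r"^(shh|sonic)\b", "SHH"),
    (r"^wnt\b", "WNT"),
    (r"^(g|gr|grp|group)\s*(3|iii)\b", "Group3"),
    (r"^(g|gr|grp|group)\s*(4|iv)\b", "Group4"),
)


def harmonize_labels(
    raw_labels: list[str] | pd.Series,
    extra_mapping: dict[str, str] | None = None,
) -> list[str]:
    """Map raw subtype annotations onto {Group3, Group4, SHH, WNT, Unknown}.

    Matching is case-insensitive and punctuation-insensitive; the WHO
    five-subtype scheme (SHH TP53-mutant / SHH TP53-wildtype) collapses onto
    SHH.  Unmatched values map to Unknown with a logged warning — they never
    raise, so a stray annotation cannot abort a classification run.
    """
    table = dict(DEFAULT_LABEL_MAP)
    if extra_mapping:
        table.update(
            {_normalize_raw_label(k): v for k, v in extra_mapping.items()}
        )
    out = []
    for raw in raw_labels:
        key = _normalize_raw_label(raw)
        label = table.get(key)
        if label is None:
            for pat, target in _FALLBACK_PATTERNS:
                if re.match(pat, key):
                    label = target
                    break
        if label is None:
            logger.warning("unrecognized subtype label %r -> Unknown", raw)
            label = UNKNOWN_LABEL
        out.append(label)
    return out


@dataclass
class LabelSet:
    """Sample-to-subtype assignment over the canonical vocabulary."""

    sample_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = pd.Index(self.sample_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicated sample ids: {dupes}")
        bad = sorted(set(self.labels) - set(LABEL_VOCABULARY))
        if bad:
            raise ValueError(
                f"labels outside vocabulary {LABEL_VOCABULARY}: {bad}"
            )

    @property
    def mapping(self) -> dict[str, str]:
        return dict(zip(self.sample_ids, self.labels))

    def subset(self, sample_ids: list[str]) -> "LabelSet":
        m = self.mapping
        return LabelSet(list(sample_ids), [m[s] for s in sample_ids])

    def samples_with_label(self, label: str) -> list[str]:
        return [s for s, l in zip(self.sample_ids, self.labels) if l == label]

    def present_subtypes(self, min_samples: int = 1) -> list[str]:
        """Canonical subtypes with at least ``min_samples`` samples."""
        return [
            s
            for s in CANONICAL_SUBTYPES
            if len(self.samples_with_label(s)) >= min_samples
        ]

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression matrix with a scale flag and platform tag.

    ``data`` holds genes on the rows (unique symbols) and samples on the
    columns.  ``scale`` is ``"linear"`` (FPKM-like, values >= 0) or
    ``"log2"``.
    """

    data: pd.DataFrame
    scale: str = LINEAR_SCALE
    platform: str = ""

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR_SCALE, LOG2_SCALE):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("empty expression matrix")
        if self.data.index.duplicated().any():
            dupes = sorted(self.data.index[self.data.index.duplicated()])
            raise ValueError(f"duplicate gene symbols: {dupes[:10]}")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(vals).all():
            raise ValueError("expression values must be finite (no NaN/inf)")
        if self.scale == LINEAR_SCALE and (vals < 0).any():
            raise ValueError("linear-scale expression values must be >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    # feature_ids lets the DE engine treat expression and ratio matrices alike
    @property
    def feature_ids(self) -> list[str]:
        return self.gene_ids

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_data(self, data: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            data=data, scale=self.scale if scale is None else scale,
            platform=self.platform,
        )

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        return self.with_data(self.data.loc[list(genes)])

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        return self.with_data(self.data[list(samples)])


def detect_scale(values: np.ndarray) -> str:
    """Heuristic scale detection: a matrix maximum below 30 indicates log2."""
    return LOG2_SCALE if float(np.max(values)) < SCALE_DETECT_MAX else LINEAR_SCALE


def _collapse_duplicates(df: pd.DataFrame, method: str) -> pd.DataFrame:
    if not df.index.duplicated().any():
        return df
    if method == "max_mean":
        # keep, per symbol, the row with the highest mean expression
        means = df.mean(axis=1).to_numpy()
        order = np.lexsort((-means, df.index.to_numpy()))
        ranked = df.iloc[order]
        return ranked[~ranked.index.duplicated(keep="first")]
    if method == "mean":
        return df.groupby(level=0, sort=True).mean()
    raise ValueError(f"unknown collapse method {method!r}")


def read_expression(
    path,
    delimiter: str = "\t",
    scale_hint: str | None = None,
    platform: str = "",
    collapse: str = "max_mean",
) -> ExpressionMatrix:
    """Read a genes x samples delimited text matrix.

    Duplicate gene symbols (e.g. multiple microarray probes) are collapsed by
    keeping the row with the highest mean expression (``collapse="max_mean"``,
    the standard probe-collapse rule) or by averaging (``collapse="mean"``).
    Rows are returned sorted by gene symbol so the result is independent of
    input row order.  Scale is auto-detected unless ``scale_hint`` is given.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: empty expression matrix")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad.to_numpy()][0]
                value = df.loc[gene, col]
                raise ParseError(
                    f"{path}: non-numeric value {value!r} at gene {gene!r}, "
                    f"sample {col!r}"
                )
            df[col] = coerced
    if df.isna().to_numpy().any():
        loc = np.argwhere(df.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: missing value at gene {df.index[loc[0]]!r}, "
            f"sample {df.columns[loc[1]]!r}"
        )
    df = _collapse_duplicates(df, collapse).sort_index()
    if df.shape[0] == 0:
        raise ParseError(f"{path}: no genes left after duplicate collapse")
    scale = scale_hint or detect_scale(df.to_numpy())
    return ExpressionMatrix(data=df.astype(float), scale=scale, platform=platform)


def write_expression(mat: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    """Write a matrix as delimited text (UTF-8, LF line endings)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        mat.data.to_csv(fh, sep=delimiter, index_label="gene")


_HEADER_HINTS_SAMPLE = {"sample", "sample_id", "sampleid", "id"}
_HEADER_HINTS_LABEL = {"subtype", "label", "class", "group", "molecular_subtype"}


def read_labels(
    path,
    delimiter: str = "\t",
    extra_mapping: dict[str, str] | None = None,
) -> LabelSet:
    """Read a two-column (sample id, raw subtype) table and harmonize labels.

    A header row is detected and skipped when its cells look like column
    names rather than data.
    """
    df = pd.read_csv(path, sep=delimiter, header=None, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(
            f"{path}: expected two columns (sample id, subtype), "
            f"found {df.shape[1]}"
        )
    first = [str(v).strip().lower() for v in df.iloc[0, :2]]
    if first[0] in _HEADER_HINTS_SAMPLE or first[1] in _HEADER_HINTS_LABEL:
        df = df.iloc[1:]
    if df.shape[0] == 0:
        raise ParseError(f"{path}: no label rows")
    sample_ids = [str(s).strip() for s in df.iloc[:, 0]]
    raw = ["" if pd.isna(v) else str(v) for v in df.iloc[:, 1]]
    if len(set(sample_ids)) != len(sample_ids):
        idx = pd.Index(sample_ids)
        dupes = sorted(idx[idx.duplicated()].unique())
        raise ParseError(f"{path}: duplicated sample ids: {dupes}")
    return LabelSet(sample_ids, harmonize_labels(raw, extra_mapping))


def write_labels(labels: LabelSet, path, delimiter: str = "\t") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"sample_id{delimiter}subtype\n")
        for s, l in zip(labels.sample_ids, labels.labels):
            fh.write(f"{s}{delimiter}{l}\n")
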
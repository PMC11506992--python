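"""Input feature tables: validation, score resolution and point positions.

Four kinds of genomic-feature table are understood, mirroring the inputs of
an integrated GWAS / differential-expression (DE) genome plot:

``gwas``
    one row per genomic variant: *chromosome*, *position* (bp) and either a
    *score* (−log10 p-value) or an adjusted p-value *padj* from which the
    score is derived.
``de``
    one row per gene from a DE analysis: *chromosome*, *start*, *end*,
    a *score*/*padj* pair as above and either a *log2FoldChange* or a raw
    *foldChange*.  The plotted position is the midpoint of [start, end].
``candidate``
    manually curated genes of interest: *chromosome*, *start*, *end* and a
    *name* used as the point label (a missing name keeps the point but
    suppresses the label).
``custom``
    any other position-mapped data type (QTL regions, differentially
    methylated regions, ...): *chromosome*, *position*, *score*, optional
    *name*; an ``aes_type`` tag links the table to its display aesthetics.

Column-name matching is case-sensitive and follows the conventional export
headers (``chromosome``, ``position``, ``start``, ``end``, ``score``,
``padj``, ``foldChange``, ``log2FoldChange``, ``name``).  Any other column
is preserved untouched but ignored by every computation, so users can keep
metadata joined to their tables.

Validation collects *all* problems in a table before raising, so one error
message is enough to fix a CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import SchemaError

KINDS = ("gwas", "de", "candidate", "custom")

#: mandatory columns per table kind (either/or pairs handled separately)
MANDATORY: Mapping[str, tuple[str, ...]] = {
    "gwas": ("chromosome", "position"),
    "de": ("chromosome", "start", "end"),
    "candidate": ("chromosome", "start", "end", "name"),
    "custom": ("chromosome", "position", "score"),
}

_DEFAULT_LABELS = {
    "gwas": "GWAS peaks",
    "de": "DE genes",
    "candidate": "Candidate genes",
    "custom": "Custom",
}


def natural_chrom_key(chrom: str) -> tuple[int, float, str]:
    """Sort key putting numeric-looking chromosome ids first, in numeric
    order ("2" < "10"), followed by the rest lexicographically.

    "chromosome 0" (unplaced bins) therefore sorts before chromosome 1.
    """
    s = str(chrom)
    try:
        return (0, float(s), "")
    except ValueError:
        return (1, 0.0, s)


def sort_chromosomes(chroms: Iterable[str]) -> list[str]:
    """Unique chromosome ids in natural order."""
    return sorted({str(c) for c in chroms}, key=natural_chrom_key)


def resolve_score(score: float | None, padj: float | None) -> float:
    """Resolve a significance score from a score / adjusted-p-value pair.

    A provided score wins; otherwise the score is −log10(padj).  padj must
    lie in [0, 1]; padj = 0 maps to +inf (always significant — the colour
    scale later caps at the largest finite score).  Returns NaN when both
    are missing.
    """
    if score is not None and not (isinstance(score, float) and math.isnan(score)):
        return float(score)
    if padj is None or (isinstance(padj, float) and math.isnan(padj)):
        return float("nan")
    padj = float(padj)
    if padj < 0 or padj > 1:
        raise ValueError(f"padj must lie in [0, 1], got {padj}")
    if padj == 0:
        return float("inf")
    return -math.log10(padj)


def resolve_log2fc(log2fc: float | None, fold_change: float | None) -> float:
    """Resolve a log2 fold-change from a log2FoldChange / foldChange pair.

    A provided log2FoldChange wins; otherwise log2(foldChange), which must
    be positive.  Returns NaN when both are missing.
    """
    if log2fc is not None and not (isinstance(log2fc, float) and math.isnan(log2fc)):
        return float(log2fc)
    if fold_change is None or (isinstance(fold_change, float) and math.isnan(fold_change)):
        return float("nan")
    fold_change = float(fold_change)
    if fold_change <= 0:
        raise ValueError(f"foldChange must be positive, got {fold_change}")
    return math.log2(fold_change)


def gene_midpoint(start: float, end: float) -> float:
    """Plotted position of an interval feature: the (fractional) midpoint."""
    if end < start:
        raise ValueError(f"end ({end}) < start ({start})")
    return (start + end) / 2


@dataclass(frozen=True)
class FeatureTable:
    """A validated table of genomic features of one kind.

    ``data`` always carries the resolved columns the rest of the pipeline
    reads: ``position`` (bp, fractional for interval features), ``score``
    (gwas/de/custom) and ``log2fc`` (de).  Original input columns are kept.
    """

    kind: str
    data: pd.DataFrame
    label: str = ""
    aes_type: str | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown table kind {self.kind!r}; expected one of {KINDS}")
        if not self.label:
            object.__setattr__(self, "label", _DEFAULT_LABELS[self.kind])

    def __len__(self) -> int:
        return len(self.data)

    @property
    def chromosomes(self) -> list[str]:
        return sort_chromosomes(self.data["chromosome"]) if len(self.data) else []

    def with_data(self, data: pd.DataFrame) -> "FeatureTable":
        return replace(self, data=data)


def _coerce_numeric(df: pd.DataFrame, col: str, problems: list[str]) -> pd.Series:
    """Coerce a column to float, recording rows that fail as problems."""
    raw = df[col]
    num = pd.to_numeric(raw, errors="coerce")
    bad = num.isna() & raw.notna()
    if bad.any():
        rows = list(df.index[bad][:5])
        problems.append(f"column {col!r} is not numeric at rows {rows}")
    return num.astype(float)


def _vec_neglog10(padj: pd.Series) -> pd.Series:
    with np.errstate(divide="ignore"):
        out = -np.log10(padj.to_numpy(dtype=float))
    return pd.Series(out, index=padj.index)


def validate_table(
    raw: pd.DataFrame,
    kind: str,
    label: str = "",
    aes_type: str | None = None,
) -> FeatureTable:
    """Validate a raw table and derive its resolved columns.

    Checks mandatory columns for ``kind``, either/or column pairs
    (score/padj, foldChange/log2FoldChange), numeric coercion, coordinate
    sanity (positions ≥ 0, end ≥ start) and value domains (padj in [0, 1],
    foldChange > 0).  All violations are collected into a single
    :class:`~genotracks.errors.SchemaError`.

    Resolution rules: a ``score`` column takes precedence over ``padj``
    (which is then ignored entirely); ``log2FoldChange`` likewise over
    ``foldChange``; interval features get ``position`` = (start + end) / 2.
    Row order and extra columns are preserved; validation is idempotent.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown table kind {kind!r}; expected one of {KINDS}")
    if not isinstance(raw, pd.DataFrame):
        raw = pd.DataFrame(raw)

    problems: list[str] = []
    cols = set(raw.columns)
    for col in MANDATORY[kind]:
        if col not in cols:
            problems.append(f"missing mandatory column {col!r}")
    if kind in ("gwas", "de") and not ({"score", "padj"} & cols):
        problems.append("one of columns 'score' or 'padj' is required")
    if kind == "de" and not ({"foldChange", "log2FoldChange"} & cols):
        problems.append("one of columns 'foldChange' or 'log2FoldChange' is required")
    if problems:
        raise SchemaError(kind, problems)

    df = raw.copy()
    df["chromosome"] = df["chromosome"].astype(str)

    # coordinate columns
    if kind in ("gwas", "custom"):
        pos = _coerce_numeric(df, "position", problems)
        if (pos.dropna() < 0).any():
            problems.append("column 'position' contains negative values")
        df["position"] = pos
    else:
        start = _coerce_numeric(df, "start", problems)
        end = _coerce_numeric(df, "end", problems)
        if (start.dropna() < 0).any():
            problems.append("column 'start' contains negative values")
        bad = (end < start).fillna(False)
        if bad.any():
            problems.append(f"end < start at rows {list(df.index[bad][:5])}")
        df["start"], df["end"] = start, end
        if not problems:
            df["position"] = (start + end) / 2

    # score resolution (column-level precedence: score wins over padj)
    if kind in ("gwas", "de", "custom"):
        if "score" in cols:
            df["score"] = _coerce_numeric(df, "score", problems)
        else:
            padj = _coerce_numeric(df, "padj", problems)
            out_of_range = ((padj < 0) | (padj > 1)).fillna(False)
            if out_of_range.any():
                problems.append(
                    f"column 'padj' outside [0, 1] at rows {list(df.index[out_of_range][:5])}"
                )
            if not problems:
                df["score"] = _vec_neglog10(padj)

    # log2 fold-change resolution (log2FoldChange wins over foldChange)
    if kind == "de":
        if "log2FoldChange" in cols:
            df["log2fc"] = _coerce_numeric(df, "log2FoldChange", problems)
        else:
            fc = _coerce_numeric(df, "foldChange", problems)
            nonpos = (fc <= 0).fillna(False)
            if nonpos.any():
                problems.append(
                    f"column 'foldChange' must be positive; bad rows {list(df.index[nonpos][:5])}"
                )
            if not problems:
                df["log2fc"] = np.log2(fc)

    if kind == "candidate":
        df["name"] = df["name"].astype("string")
    if kind == "custom" and "name" in cols:
        df["name"] = df["name"].astype("string")

    if problems:
        raise SchemaError(kind, problems)
    return FeatureTable(kind=kind, data=df, label=label, aes_type=aes_type)


def read_feature_csv(
    path: str | Path,
    kind: str,
    label: str = "",
    aes_type: str | None = None,
) -> FeatureTable:
    """Read a UTF-8 CSV with a header row and validate it as ``kind``.

    Missing values may be encoded as empty fields or ``NA``.
    """
    raw = pd.read_csv(path, keep_default_na=False, na_values=["", "NA"])
    if not label:
        label = Path(path).stem
    return validate_table(raw, kind, label=label, aes_type=aes_type)


def write_feature_csv(table: FeatureTable, path: str | Path) -> None:
    """Write a validated table back to CSV (missing values as empty fields)."""
    table.data.to_csv(path, index=False, na_rep="")
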
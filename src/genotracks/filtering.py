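"""Significance filtering, chromosome lengths and display windows.

The pipeline between validated tables and the plot layout:

1. :func:`apply_threshold` keeps features whose score (and, for DE, whose
   absolute log2 fold-change) meets the user's thresholds; features with a
   missing score or log2fc are dropped.  Candidate-gene tables carry no
   score and pass through unfiltered.
2. :func:`compute_chrom_length` infers per-chromosome lengths as the
   maximum feature position/end across the *unfiltered* inputs, so facet
   widths stay stable as thresholds change; user-supplied lengths override
   inferred ones.
3. :func:`apply_chrom_limits` crops chromosomes to user windows (closed
   intervals), i.e. zooming into regions of interest.
4. :func:`remove_empty_chromosomes` drops chromosomes with no surviving
   feature from the facet list.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GenotracksError
from .tables import FeatureTable, natural_chrom_key, sort_chromosomes


@dataclass(frozen=True)
class Thresholds:
    """Significance thresholds per track family.

    ``score_thr_*`` are on the −log10(p) scale; ``log2fc_thr`` applies to
    the *absolute* log2 fold-change of DE genes (0 = no fold-change
    filtering).
    """

    score_thr_gwas: float = 1.3
    score_thr_de: float = 1.3
    log2fc_thr: float = 0.0
    score_thr_custom: float = 1.3

    def __post_init__(self):
        if self.log2fc_thr < 0:
            raise ValueError("log2fc_thr must be >= 0 (applied to |log2fc|)")

    def for_kind(self, kind: str) -> float:
        return {
            "gwas": self.score_thr_gwas,
            "de": self.score_thr_de,
            "custom": self.score_thr_custom,
        }.get(kind, float("-inf"))


@dataclass
class ChromosomeLengths:
    """Mapping chromosome id → length in bp, kept in natural order."""

    entries: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.entries = {
            str(c): float(v)
            for c, v in sorted(self.entries.items(), key=lambda kv: natural_chrom_key(kv[0]))
        }

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, chrom: str) -> bool:
        return str(chrom) in self.entries

    def __getitem__(self, chrom: str) -> float:
        return self.entries[str(chrom)]

    @property
    def chromosomes(self) -> list[str]:
        return list(self.entries)

    def with_user_lengths(self, user: Mapping[str, float]) -> "ChromosomeLengths":
        """Override inferred lengths with user-supplied values.

        User entries win entirely for the chromosomes they list; other
        chromosomes keep their inferred length.
        """
        merged = dict(self.entries)
        for c, v in user.items():
            v = float(v)
            if v <= 0:
                raise ValueError(f"chromosome length must be > 0, got {v} for {c!r}")
            merged[str(c)] = v
        return ChromosomeLengths(merged)

    def restrict(self, chroms: Iterable[str]) -> "ChromosomeLengths":
        keep = {str(c) for c in chroms}
        return ChromosomeLengths({c: v for c, v in self.entries.items() if c in keep})


@dataclass
class ChromosomeLimits:
    """Per-chromosome [min, max] bp display window.

    Chromosomes absent from the mapping are shown in full.  Boundaries are
    inclusive, mirroring the ≥ threshold convention.
    """

    entries: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        clean: dict[str, tuple[float, float]] = {}
        for c, (lo, hi) in self.entries.items():
            lo, hi = float(lo), float(hi)
            if lo < 0 or hi <= lo:
                raise ValueError(f"invalid limits for chromosome {c!r}: [{lo}, {hi}]")
            clean[str(c)] = (lo, hi)
        self.entries = clean

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, chrom: str) -> tuple[float, float] | None:
        return self.entries.get(str(chrom))


def apply_threshold(
    table: FeatureTable,
    score_thr: float,
    log2fc_thr: float | None = None,
) -> FeatureTable:
    """Keep features with score ≥ ``score_thr`` (and, for DE tables,
    |log2fc| ≥ ``log2fc_thr``).

    Features with a missing score — or, for DE, a missing log2 fold-change
    — are removed.  Candidate tables pass through unchanged (they carry no
    score).  Row order is preserved; the result's rows are a subset of the
    input's.
    """
    if table.kind == "candidate":
        return table
    if log2fc_thr is not None and table.kind != "de":
        raise ValueError("log2fc_thr applies to DE tables only")
    score = table.data["score"]
    keep = score.notna() & (score >= score_thr)
    if table.kind == "de":
        thr = 0.0 if log2fc_thr is None else float(log2fc_thr)
        l2fc = table.data["log2fc"]
        keep &= l2fc.notna() & (l2fc.abs() >= thr)
    return table.with_data(table.data.loc[keep])


def filter_tables(
    tables: Sequence[FeatureTable],
    thresholds: Thresholds,
    per_track_thr: Mapping[int, float] | None = None,
) -> list[FeatureTable]:
    """Apply :func:`apply_threshold` to every table.

    ``per_track_thr`` maps a table's index in ``tables`` to a score
    threshold overriding the family default — used for polyploid-GWAS
    tracks that each carry their own significance threshold.
    """
    out = []
    for i, t in enumerate(tables):
        thr = (per_track_thr or {}).get(i, thresholds.for_kind(t.kind))
        l2 = thresholds.log2fc_thr if t.kind == "de" else None
        out.append(apply_threshold(t, thr, l2))
    return out


def compute_chrom_length(tables: Iterable[FeatureTable]) -> ChromosomeLengths:
    """Infer chromosome lengths as the maximum feature coordinate.

    Per chromosome: the max over all tables of ``position`` and, for
    interval features, ``end``.  Raises if every table is empty.
    """
    maxima: dict[str, float] = {}
    for t in tables:
        if not len(t):
            continue
        df = t.data
        cols = ["position"] + (["end"] if "end" in df.columns else [])
        per = df.melt(id_vars=["chromosome"], value_vars=cols, value_name="bp")
        per = per.dropna(subset=["bp"])
        for c, v in per.groupby("chromosome", observed=True)["bp"].max().items():
            c = str(c)
            maxima[c] = max(maxima.get(c, float("-inf")), float(v))
    if not maxima:
        raise GenotracksError("no features to infer chromosome lengths from")
    return ChromosomeLengths(maxima)


def apply_chrom_limits(
    tables: Sequence[FeatureTable],
    limits: ChromosomeLimits | None,
) -> list[FeatureTable]:
    """Crop features on limited chromosomes to their [min, max] window.

    Boundary positions are retained (closed interval).  A limit naming a
    chromosome absent from every table triggers a warning and is ignored.
    """
    if limits is None or not len(limits):
        return list(tables)
    known = {c for t in tables for c in t.chromosomes}
    for c in limits.entries:
        if c not in known:
            warnings.warn(f"chromosome limit for unknown chromosome {c!r} ignored")
    out = []
    for t in tables:
        df = t.data
        if not len(df):
            out.append(t)
            continue
        keep = pd.Series(True, index=df.index)
        for c, (lo, hi) in limits.entries.items():
            on_c = df["chromosome"] == c
            keep &= ~on_c | (df["position"].between(lo, hi))
        out.append(t.with_data(df.loc[keep]))
    return out


def remove_empty_chromosomes(
    tables: Sequence[FeatureTable],
    lengths: ChromosomeLengths,
) -> tuple[list[FeatureTable], ChromosomeLengths]:
    """Drop chromosomes with zero retained features from the facet list.

    Intended for already-filtered tables ("only display chromosomes with
    significant markers").  Tables are returned unchanged; only the length
    mapping — hence the facet set — shrinks.
    """
    occupied: set[str] = set()
    for t in tables:
        occupied.update(t.chromosomes)
    return list(tables), lengths.restrict(occupied)


def read_chrom_lengths_csv(path: str | Path) -> dict[str, float]:
    """Read a 2-column (chromosome, length) CSV into a plain mapping."""
    df = pd.read_csv(path)
    if not {"chromosome", "length"} <= set(df.columns):
        raise GenotracksError(
            f"chromosome-length file {path} needs columns 'chromosome' and 'length'"
        )
    return {str(c): float(v) for c, v in zip(df["chromosome"], df["length"])}


def read_chrom_limits(path: str | Path) -> ChromosomeLimits:
    """Read display limits from JSON ``{chrom: [min, max]}`` or a 3-column
    (chromosome, min, max) CSV, selected by file extension."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        obj = json.loads(path.read_text())
        return ChromosomeLimits({str(c): (v[0], v[1]) for c, v in obj.items()})
    df = pd.read_csv(path)
    if not {"chromosome", "min", "max"} <= set(df.columns):
        raise GenotracksError(
            f"chromosome-limits file {path} needs columns 'chromosome', 'min', 'max'"
        )
    return ChromosomeLimits(
        {str(r.chromosome): (float(r.min), float(r.max)) for r in df.itertuples()}
    )
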
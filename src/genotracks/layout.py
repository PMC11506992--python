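"""Declarative plot layout.

:func:`build_plot_spec` turns filtered feature tables plus chromosome
lengths/limits into a :class:`PlotSpec` — a renderer-independent, fully
deterministic description of the figure:

* one **facet** per chromosome, x-axis in bp over [0, length] or the
  user's zoom window;
* one **track** (horizontal band) per input table, ordered top-to-bottom
  GWAS, DE, custom, candidate genes;
* a **point** per retained feature, coloured by its score (DE points can
  be coloured by log2 fold-change instead);
* a vertical **guide line** at every point's position, in the originating
  track's line colour, to expose cross-track co-location;
* **labels** for candidate genes with a name, and for custom tracks that
  opted in, placed by a deterministic greedy repel so label boxes never
  overlap;
* one **colour scale** per score family (GWAS, DE, each custom type) with
  domain = [min, max] of the finite scores plotted.

Because the spec is plain data (dataclasses of str/float), it serialises
to JSON for snapshot tests and two builds from equal inputs are
structurally identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, NothingToPlotError
from .filtering import ChromosomeLengths, ChromosomeLimits
from .tables import FeatureTable

logger = logging.getLogger(__name__)

#: fixed colour for candidate-gene points (they carry no score)
CANDIDATE_COLOUR = "forestgreen"


@dataclass(frozen=True)
class TrackAesthetics:
    """Display contract for one track type.

    ``point_shape`` accepts a matplotlib marker string or an R ``pch``
    integer (a small translation table covers the common codes).
    ``fill_scale`` names a matplotlib colormap; ``None`` means the default
    score gradient (viridis).
    """

    y_label: str = ""
    line_colour: str = "grey"
    point_shape: str | int = "o"
    show_name: bool = False
    fill_scale: str | None = None
    scale_name: str | None = None


DEFAULT_AESTHETICS: Mapping[str, TrackAesthetics] = {
    "gwas": TrackAesthetics(line_colour="grey", point_shape="o", scale_name="GWAS score"),
    "de": TrackAesthetics(line_colour="lightblue", point_shape="o", scale_name="DE score"),
    "candidate": TrackAesthetics(line_colour=CANDIDATE_COLOUR, point_shape="D", show_name=True),
}

#: R pch → matplotlib marker, for configs written against the R idiom
_PCH_TO_MARKER = {
    15: "s", 16: "o", 17: "^", 18: "D", 19: "o", 20: ".",
    21: "o", 22: "s", 23: "D", 24: "^", 25: "v",
}


def marker_for(shape: str | int) -> str:
    if isinstance(shape, int):
        return _PCH_TO_MARKER.get(shape, "o")
    return shape


@dataclass(frozen=True)
class Facet:
    chromosome: str
    xmin: float
    xmax: float


@dataclass(frozen=True)
class Track:
    index: int          # 0 = top band
    kind: str
    label: str
    aes_type: str | None
    line_colour: str
    point_shape: str | int
    scale_id: str | None  # None for score-less (candidate) tracks


@dataclass(frozen=True)
class Point:
    chromosome: str
    track: int
    x: float
    value: float | None   # colour value; None for candidate points
    scale_id: str | None


@dataclass(frozen=True)
class GuideLine:
    chromosome: str
    x: float
    colour: str


@dataclass(frozen=True)
class Label:
    chromosome: str
    track: int
    x: float        # anchor (point) position
    x_label: float  # placed label position
    row: int        # vertical displacement slot within the track band
    text: str


@dataclass(frozen=True)
class ColourScale:
    scale_id: str
    name: str
    cmap: str
    vmin: float
    vmax: float


@dataclass
class PlotSpec:
    """Complete, renderer-independent description of the figure."""

    facets: list[Facet] = field(default_factory=list)
    tracks: list[Track] = field(default_factory=list)
    points: list[Point] = field(default_factory=list)
    guide_lines: list[GuideLine] = field(default_factory=list)
    labels: list[Label] = field(default_factory=list)
    scales: list[ColourScale] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class LayoutOptions:
    """Display options that change what the layout emits."""

    colour_de_by_log2fc: bool = False
    #: approximate width of one label character as a fraction of the facet
    #: x-range; drives the greedy label repel
    label_char_frac: float = 0.012
    #: maximum vertical label rows before thinning kicks in
    max_label_rows: int = 4


def place_labels(
    labels: Sequence[tuple[float, str]],
    axis_range: tuple[float, float],
    char_frac: float = 0.012,
    max_rows: int = 4,
) -> list[tuple[float, float, int, str]]:
    """Place labels without box overlap, deterministically.

    Each label is a (x, text) anchor within ``axis_range``.  Labels are
    processed in x order (ties broken by input order) and assigned the
    first vertical row in which their box does not overlap the previous
    box in that row; a box's width is ``len(text) * char_frac * range``.
    Labels that fit no row within ``max_rows`` are thinned with a warning.

    Returns (x_anchor, x_label, row, text) tuples; boxes on distinct rows
    are disjoint by construction, boxes on one row are disjoint in x.
    """
    lo, hi = axis_range
    span = hi - lo
    if span <= 0 or not labels:
        return []
    order = sorted(range(len(labels)), key=lambda i: (labels[i][0], i))
    row_right = [float("-inf")] * max_rows  # right edge of last box per row
    placed: list[tuple[float, float, int, str]] = []
    dropped = 0
    for i in order:
        x, text = labels[i]
        width = max(len(text), 1) * char_frac * span
        # keep the box inside the axis
        x_label = min(max(x, lo + width / 2), hi - width / 2) if width < span else (lo + hi) / 2
        left, right = x_label - width / 2, x_label + width / 2
        for row in range(max_rows):
            if left > row_right[row]:
                row_right[row] = right
                placed.append((x, x_label, row, text))
                break
        else:
            dropped += 1
    if dropped:
        logger.warning("thinned %d overlapping labels that fit no row", dropped)
    return placed


def _track_order_key(table: FeatureTable) -> int:
    return {"gwas": 0, "de": 1, "custom": 2, "candidate": 3}[table.kind]


def build_plot_spec(
    filtered_tables: Sequence[FeatureTable],
    lengths: ChromosomeLengths,
    limits: ChromosomeLimits | None = None,
    aes: Mapping[str, TrackAesthetics] | None = None,
    options: LayoutOptions | None = None,
) -> PlotSpec:
    """Assemble the declarative plot description.

    ``aes`` maps each custom table's ``aes_type`` tag to its
    :class:`TrackAesthetics`; GWAS/DE/candidate tracks use built-in
    defaults.  Raises :class:`NothingToPlotError` if no feature survived
    filtering and :class:`ConfigError` for an unknown ``aes_type``.
    """
    options = options or LayoutOptions()
    aes = aes or {}

    # facets, in natural chromosome order, with zoom windows applied
    facets = []
    for chrom in lengths.chromosomes:
        window = limits.get(chrom) if limits is not None else None
        xmin, xmax = window if window else (0.0, lengths[chrom])
        facets.append(Facet(chromosome=chrom, xmin=xmin, xmax=xmax))
    facet_range = {f.chromosome: (f.xmin, f.xmax) for f in facets}

    # tracks: stable sort keeps input order within each kind
    ordered = sorted(filtered_tables, key=_track_order_key)
    tracks: list[Track] = []
    scales: dict[str, ColourScale] = {}
    for idx, table in enumerate(ordered):
        if table.kind == "custom":
            if table.aes_type is None or table.aes_type not in aes:
                raise ConfigError(
                    f"custom table {table.label!r} has aes_type {table.aes_type!r} "
                    f"with no matching TrackAesthetics entry"
                )
            a = aes[table.aes_type]
            label = a.y_label or table.label
        else:
            a = DEFAULT_AESTHETICS[table.kind]
            label = table.label

        if table.kind == "candidate":
            scale_id = None
        elif table.kind == "custom":
            scale_id = f"custom:{table.aes_type}"
        elif table.kind == "de" and options.colour_de_by_log2fc:
            scale_id = "de:log2fc"
        else:
            scale_id = table.kind
        tracks.append(
            Track(
                index=idx,
                kind=table.kind,
                label=label,
                aes_type=table.aes_type,
                line_colour=a.line_colour,
                point_shape=a.point_shape,
                scale_id=scale_id,
            )
        )

        if scale_id is not None:
            values = (
                table.data["log2fc"]
                if scale_id == "de:log2fc"
                else table.data["score"]
            )
            finite = values[np.isfinite(values)]
            if len(finite):
                lo, hi = float(finite.min()), float(finite.max())
            elif len(values):
                lo = hi = 0.0  # all-infinite track: flat scale
            else:
                lo = hi = 0.0
            name = a.scale_name or (
                "DE log2FC" if scale_id == "de:log2fc" else label
            )
            cmap = a.fill_scale or "viridis"
            prev = scales.get(scale_id)
            if prev is None:
                scales[scale_id] = ColourScale(scale_id, name, cmap, lo, hi)
            elif len(values):
                scales[scale_id] = ColourScale(
                    scale_id, prev.name, prev.cmap, min(prev.vmin, lo), max(prev.vmax, hi)
                )

    # points, guide lines and labels
    points: list[Point] = []
    guide_lines: list[GuideLine] = []
    labels: list[Label] = []
    for track, table in zip(tracks, ordered):
        show_names = (
            table.kind == "candidate"
            or (table.kind == "custom" and aes[table.aes_type].show_name)
        )
        per_facet_labels: dict[str, list[tuple[float, str]]] = {}
        for row in table.data.itertuples(index=False):
            chrom = str(row.chromosome)
            if chrom not in facet_range:
                continue
            x = float(row.position)
            if track.scale_id is None:
                value = None
            elif track.scale_id == "de:log2fc":
                value = float(row.log2fc)
            else:
                value = float(row.score)
            points.append(Point(chrom, track.index, x, value, track.scale_id))
            guide_lines.append(GuideLine(chrom, x, track.line_colour))
            if show_names:
                name = getattr(row, "name", None)
                if name is not None and not pd.isna(name):
                    text = str(name)
                    if text:
                        per_facet_labels.setdefault(chrom, []).append((x, text))
        for chrom, lab in per_facet_labels.items():
            for x_anchor, x_label, row_slot, text in place_labels(
                lab,
                facet_range[chrom],
                char_frac=options.label_char_frac,
                max_rows=options.max_label_rows,
            ):
                labels.append(Label(chrom, track.index, x_anchor, x_label, row_slot, text))

    if not points:
        raise NothingToPlotError("nothing to plot: no feature passed the thresholds")

    return PlotSpec(
        facets=facets,
        tracks=tracks,
        points=points,
        guide_lines=guide_lines,
        labels=labels,
        scales=[scales[s] for s in sorted(scales)],
    )
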
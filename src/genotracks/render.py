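"""Rasterise / vectorise a PlotSpec with matplotlib.

The renderer walks a :class:`~genotracks.layout.PlotSpec` and draws one
subplot per chromosome facet, tracks as integer y bands (top band =
track 0), guide lines beneath the points, candidate/custom labels with
connector stems, and one colourbar per score family.

Output is deterministic for a fixed spec + options: SVG ids are salted
with a constant, and PDF/SVG creation dates are suppressed, so repeated
renders are byte-identical — a property the test suite relies on for
snapshot comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from matplotlib import colormaps
from matplotlib.colors import Normalize
from matplotlib.cm import ScalarMappable

from .errors import GenotracksError
from .layout import PlotSpec, marker_for

FORMATS = ("png", "pdf", "svg")


@dataclass(frozen=True)
class RenderOptions:
    """Physical rendering parameters.

    ``height`` defaults to ``1 + 0.8 × n_tracks`` inches per facet row so
    label bands stay legible as tracks are added.
    """

    width: float = 11.0
    height: float | None = None
    dpi: int = 300
    format: str | None = None  # inferred from the path suffix when None
    title: str | None = None
    legend_position: str = "right"  # right | bottom | none
    point_size: float = 30.0
    ncol: int = 2  # facets per row

    def __post_init__(self):
        if self.dpi <= 0 or self.width <= 0 or (self.height is not None and self.height <= 0):
            raise ValueError("width, height and dpi must be positive")
        if self.format is not None and self.format not in FORMATS:
            raise ValueError(f"format must be one of {FORMATS}, got {self.format!r}")
        if self.legend_position not in ("right", "bottom", "none"):
            raise ValueError("legend_position must be 'right', 'bottom' or 'none'")


def _mb_formatter(x, _pos):
    return f"{x / 1e6:g}"


def render(spec: PlotSpec, options: RenderOptions, path: str | Path) -> Path:
    """Draw ``spec`` and write it to ``path`` (PNG, PDF or SVG).

    Returns the written path.  The same spec and options always produce
    the same bytes.
    """
    path = Path(path)
    fmt = options.format or path.suffix.lstrip(".").lower()
    if fmt not in FORMATS:
        raise GenotracksError(f"unsupported output format {fmt!r}; use one of {FORMATS}")
    if not spec.points:
        raise GenotracksError("refusing to render an empty plot spec")

    n_tracks = len(spec.tracks)
    n_facets = len(spec.facets)
    ncol = max(1, min(options.ncol, n_facets))
    nrow = -(-n_facets // ncol)
    height = options.height if options.height is not None else nrow * (1 + 0.8 * n_tracks)

    with plt.rc_context({"svg.hashsalt": "genotracks", "figure.max_open_warning": 0}):
        fig, axes = plt.subplots(
            nrow, ncol,
            figsize=(options.width, height),
            squeeze=False,
            constrained_layout=True,
        )
        axmap = {}
        for i, facet in enumerate(spec.facets):
            ax = axes[i // ncol][i % ncol]
            axmap[facet.chromosome] = ax
            ax.set_xlim(facet.xmin, facet.xmax)
            ax.set_ylim(-0.6, n_tracks - 0.4)
            ax.invert_yaxis()  # track 0 on top
            ax.set_title(f"chromosome {facet.chromosome}", fontsize=9)
            ax.xaxis.set_major_formatter(plt.FuncFormatter(_mb_formatter))
            ax.set_xlabel("position (Mb)", fontsize=8)
            ax.tick_params(labelsize=7)
            if i % ncol == 0:
                ax.set_yticks(range(n_tracks))
                ax.set_yticklabels([t.label for t in spec.tracks], fontsize=8)
            else:
                ax.set_yticks(range(n_tracks))
                ax.set_yticklabels([])
        for j in range(n_facets, nrow * ncol):
            axes[j // ncol][j % ncol].set_axis_off()

        # guide lines first so points draw on top
        for gl in spec.guide_lines:
            axmap[gl.chromosome].axvline(
                gl.x, color=gl.colour, linewidth=0.6, alpha=0.7, zorder=1
            )

        scales = {s.scale_id: s for s in spec.scales}
        norms = {
            sid: Normalize(
                vmin=s.vmin,
                vmax=s.vmax if s.vmax > s.vmin else s.vmin + 1e-9,
                clip=True,  # +inf scores (padj = 0) cap at the top colour
            )
            for sid, s in scales.items()
        }
        tracks = {t.index: t for t in spec.tracks}
        for pt in spec.points:
            ax = axmap[pt.chromosome]
            track = tracks[pt.track]
            if pt.scale_id is None:
                colour = "forestgreen"
            else:
                s = scales[pt.scale_id]
                cmap = colormaps[s.cmap]
                colour = cmap(norms[pt.scale_id](pt.value))
            ax.scatter(
                [pt.x], [pt.track],
                s=options.point_size,
                marker=marker_for(track.point_shape),
                c=[colour],
                edgecolors="black",
                linewidths=0.3,
                zorder=3,
            )

        # labels with connector stems, offset within the track band
        for lab in spec.labels:
            ax = axmap[lab.chromosome]
            y_point = lab.track
            y_text = lab.track + 0.18 + 0.14 * lab.row
            ax.annotate(
                lab.text,
                xy=(lab.x, y_point),
                xytext=(lab.x_label, y_text),
                fontsize=6,
                ha="center",
                va="top",
                arrowprops={"arrowstyle": "-", "linewidth": 0.4, "color": "black"},
                zorder=4,
            )

        if options.legend_position != "none" and scales:
            loc = options.legend_position
            for sid in sorted(scales):
                s = scales[sid]
                sm = ScalarMappable(norm=norms[sid], cmap=colormaps[s.cmap])
                fig.colorbar(
                    sm,
                    ax=axes,
                    label=s.name,
                    location=loc,
                    shrink=0.5,
                    aspect=30,
                    pad=0.02,
                )
        if options.title:
            fig.suptitle(options.title)

        metadata = {"Date": None} if fmt == "svg" else (
            {"CreationDate": None} if fmt == "pdf" else None
        )
        try:
            # OSError (unwritable path, ...) propagates: the CLI maps it to
            # its I/O exit code
            fig.savefig(path, format=fmt, dpi=options.dpi, metadata=metadata)
        finally:
            plt.close(fig)
    return path
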
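# Methods

## Model of the figure

A genotracks figure is a deterministic function of (tables, thresholds,
lengths, limits, aesthetics): chromosome facets on a shared bp x-axis,
one horizontal track per input table, points at feature positions, guide
lines, labels and per-family colour scales. The pipeline is

validate → resolve (score, log2fc, position) → threshold filter →
window crop → empty-chromosome removal → declarative `PlotSpec` →
matplotlib render.

The `PlotSpec` intermediate is plain data (JSON-serialisable) so layouts
can be snapshot-tested and compared across the CLI and library paths
without rendering.

## Input resolution rules

- **Score.** `score` column if present (then `padj` is ignored entirely,
  including rows where `score` is missing), else −log₁₀(`padj`). `padj`
  must lie in [0, 1]; out-of-range values are errors rather than being
  silently clamped. `padj = 0` resolves to +∞: the record passes every
  threshold and its colour clips to the top of the scale, whose domain is
  capped at the largest finite score in the family — dropping such records
  would hide exactly the strongest signals.
- **log₂ fold-change.** `log2FoldChange` if present, else
  log₂(`foldChange`) with `foldChange` required positive.
- **Position.** Interval features plot at the fractional midpoint
  (start + end) / 2 — no rounding, since sub-bp resolution is harmless and
  avoids a tie-break rule. The derived value is stored in the `position`
  column; an existing `position` column on an interval table is
  overwritten by it. All other unrecognised columns are preserved
  untouched and ignored by computation, so user metadata survives a
  round trip through the package.
- Coordinates are treated as 1-based inclusive bp positions; position 0 is
  accepted (chromosome "0" conventionally bins unplaced features).
- Duplicate markers are kept and both plotted; the package does not
  deduplicate user data.

Validation collects every violation in a table (all missing columns, all
bad rows) before raising a single schema error, matching how a user
actually fixes a CSV.

## Filtering semantics

- Retention is `score ≥ thr` — a feature exactly at the threshold is kept
  — and for DE additionally `|log2fc| ≥ log2fc_thr`. The absolute value
  keeps down-regulated genes symmetrically, matching volcano-plot
  practice. Features with missing score or (DE) missing log2fc are always
  excluded, even when the other quantity passes.
- Candidate tables bypass score filtering entirely but are still cropped
  by chromosome windows.
- Chromosome lengths are computed on the **unfiltered** inputs so facet
  widths do not shrink as thresholds tighten; user-supplied lengths
  override inferred ones per listed chromosome.
- Window boundaries are inclusive, mirroring the threshold convention.
  A window naming a chromosome absent from the data warns and is ignored.
- Empty-chromosome removal drops a facet only when *no* track retains a
  feature on it; candidate genes therefore keep their chromosomes alive.
- Chromosome ids sort naturally: numeric-looking ids numerically
  ("2" < "10"), the rest lexicographically after them.

## Layout choices

- Track order top-to-bottom: GWAS tracks, DE tracks, custom tracks,
  candidate genes; input order is preserved within a kind. Candidate
  labels hang below their points, which is why that track sits at the
  bottom.
- One guide line per plotted feature, in its track's line colour, spanning
  all tracks and drawn beneath the points. Coincident features from
  different tracks draw overplotted lines rather than a merged one.
- One colour scale per score family — all GWAS tracks share one, DE
  another (or a log2fc scale when the colour-by-log2fc option is set), and
  each custom `aes_type` gets its own, with scale domain = [min, max] of
  the finite scores plotted in that family. Candidate points use a single
  fixed colour.
- Label placement is a greedy interval-scheduling repel: labels are
  processed in x order and assigned the first vertical row whose previous
  box they do not overlap, with box width estimated as
  `len(text) × label_char_frac × facet span` (default 0.012). Labels that
  fit none of `max_label_rows` (default 4) rows are thinned
  deterministically with a warning. This trades the visual polish of
  force-directed repulsion for byte-for-byte reproducible output.
- Facets share the bp unit with per-facet ranges; tick labels are in Mb.

## Rendering

Matplotlib (Agg) with one subplot per facet, wrapped at `ncol` facets per
row (default 2). Default size: 11 in wide, `rows × (1 + 0.8 × n_tracks)`
in tall at 300 dpi, so label bands stay legible as tracks are added.
Output formats: PNG, PDF, SVG. Renders are deterministic for fixed
spec + options: the SVG hash salt is pinned and SVG/PDF creation dates are
suppressed, so repeated renders of the same spec are byte-identical — the
property the snapshot tests assert. R `pch` marker codes in aesthetics
configs are translated to matplotlib markers (18 → diamond, 24 → triangle,
...).

## Polyploid-GWAS bridge

The exchange format is deliberately CSV, not a language-native serialised
object: a scores file (`trait, model, marker, chromosome, position,
score`) and a thresholds file (`trait, model, threshold`). Every
(trait, model) pair present in the scores must have a threshold; the pair
becomes a GWAS track labelled `"trait, model"` whose own threshold
replaces the global GWAS threshold at filtering — the track-specific
threshold is always used when present. Filtering a track by its threshold
is by construction the same operation as the generic score filter, an
identity the tests assert rather than assume. Markers with missing scores
pass through ingestion and fall out at filtering, like every other NA.

## Synthetic data generator

The generator produces every input dialect with planted signal:

- 12 chromosomes of 60 Mb (a potato-like genome), 10,000 markers and
  3,000 genes by default, uniform positions;
- null scores are −log₁₀(U(0,1)) — uniform p-values — so the expected
  fraction of scores ≥ t is exactly 10⁻ᵗ and calibration is testable in
  closed form;
- two planted regions (chromosome 3 at 15 Mb ± 0.5 Mb, chromosome 10 at
  48.75 Mb ± 0.25 Mb) add +6 score units to every marker/gene inside, far
  above the conventional genome-wide threshold of 4, so recovery of the
  planted chromosome set is guaranteed up to null false positives
  (expected 10⁻⁴ × n markers above 4);
- candidate genes sit at planted-region centres with names (every third
  filler candidate is unnamed to exercise label suppression); DE tables
  carry `padj` + `log2FoldChange` and GWAS tables carry `score`, covering
  both resolution paths; a trait × model export (3 traits × 4 models by
  default) reuses a marker subset, with the planted effect injected only
  under the first trait's general and additive models and per-pair
  thresholds jittered around 4.

The generator emulates the *geometry* of real datasets, not their
genetics: no linkage disequilibrium, no allele-frequency structure, no
correlation between expression and genotype. Passing tests therefore
demonstrate the plotting and filtering machinery, not statistical
performance on real GWAS data.

Problem sizes in the test suite are scaled to what the properties need:
20,000 markers for null-tail calibration (3-binomial-σ bands at
t ∈ {1, 2, 3}), 4,000 markers for planted-recovery runs, smaller sizes
elsewhere; the full suite runs in seconds.

## Known limitations

- No window smoothing, peak merging or LD clumping: individually
  significant features are plotted as-is.
- Overplotting is possible at dense loci; guide lines from coincident
  features stack.
- The greedy label repel can thin labels in extremely dense candidate
  panels rather than shrinking text.
- Interactive exploration (zoom, hover) is out of scope; the output is a
  static summary figure. Genome browsers serve the interactive case.
- Native R serialised objects are not read; polyploid-GWAS results enter
  through the documented CSV export.
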
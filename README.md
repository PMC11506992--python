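# genotracks

Aligned per-chromosome track plots that integrate genome-wide association
study (GWAS) results, differential-expression (DE) results, manually
curated candidate genes and arbitrary position-mapped data in a single
static figure.

## The problem

A GWAS yields per-marker scores (−log₁₀ *p*) along the genome, classically
shown as a Manhattan plot; a DE analysis yields per-gene scores and log₂
fold-changes, classically shown as a volcano plot. Neither display can be
aligned with the other, so the question that usually matters — *which
genomic regions are supported by both the genomics and the transcriptomics,
and by prior literature?* — ends up answered with tables or Venn diagrams.
Circular (Circos-style) layouts can stack the layers but make positional
comparison across layers imprecise.

genotracks draws the linear alternative: the x-axis is physical position in
bp, each chromosome is a facet, and each input table occupies one
horizontal track. Only features passing user-set significance thresholds
are drawn, as points coloured by their score, with a vertical guide line at
every feature position so co-location across tracks is visible at a glance.
Candidate genes carry name labels placed without overlap. Any data type
that maps to a genomic position (QTL intervals, differentially methylated
regions, chromatin accessibility peaks, ...) can be added as a custom track
with its own colour scale, marker shape and guide-line colour.

For polyploid organisms (e.g. autotetraploid potato), GWAS tools score each
marker under several genetic models — general, additive, simplex dominant
with respect to the reference or alternate allele — and compute a separate
significance threshold per trait × model combination. A bridge ingests such
results from a two-file CSV export and renders one track per trait × model
pair, each filtered by its own threshold.

## Core rules

- A feature's score is the provided `score` column or, failing that,
  −log₁₀(`padj`); a provided score wins and `padj` is then ignored. The
  usual conventions fall out: padj 0.05 ↔ score 1.3, *p* 10⁻⁴ ↔ score 4.
- A DE gene's log₂ fold-change is `log2FoldChange` or, failing that,
  log₂(`foldChange`).
- Interval features (genes) are plotted at (start + end) / 2.
- A feature is drawn iff score ≥ `score_thr` and (DE) |log2fc| ≥
  `log2fc_thr`; features with missing score or log2fc are excluded.
  Candidate genes carry no score and are always drawn.
- Chromosome lengths default to the maximum feature coordinate per
  chromosome across the *unfiltered* inputs; users can supply lengths, zoom
  into per-chromosome `[min, max]` windows, and drop chromosomes without
  significant features.

## Worked example

```python
import genotracks as gt
from genotracks.cli import run_pipeline

data = gt.simulate_dataset(gt.SimulationConfig(seed=42))
tables = [data.gwas, data.de, data.candidate]
thresholds = gt.Thresholds(score_thr_gwas=4, score_thr_de=1.3, log2fc_thr=0)

spec = run_pipeline(tables, thresholds, remove_empty_chrom=True)
print(f"facets (chromosomes shown): {[f.chromosome for f in spec.facets]}")
print(f"tracks (top to bottom):     {[t.label for t in spec.tracks]}")
print(f"plotted points:             {spec.n_points}")
print(f"guide lines:                {len(spec.guide_lines)}")
print(f"candidate labels:           {[l.text for l in spec.labels]}")

path = gt.render(spec, gt.RenderOptions(width=11, dpi=150), "example.png")
print(f"figure written to:          {path}")
```

prints

```
facets (chromosomes shown): ['1', '2', '3', '4', '5', '6', '7', '8', '9', '10', '11', '12']
tracks (top to bottom):     ['GWAS', 'DE', 'Candidates']
plotted points:             206
guide lines:                206
candidate labels:           ['CAND_3_0', 'CAND_x1', 'CAND_10_1', 'CAND_x0', 'CAND_x3', 'CAND_x4']
figure written to:          example.png
```

The simulated dataset plants two trait-associated regions (chromosomes 3
and 10, effect +6 score units); `CAND_3_0` and `CAND_10_1` are the
candidate genes placed at those region centres, and in the figure their
guide lines coincide with significant GWAS markers and DE genes. The 206
points are every feature at or above its threshold: with 10,000 null
markers, essentially no marker reaches 4 outside the planted regions,
while the DE threshold 1.3 (padj ≤ 0.05) retains the expected ≈5 % of
3,000 null genes plus the planted ones. All 12 chromosomes remain because
candidate genes — which bypass score filtering — occupy every one.

The same run from the shell:

```sh
genotracks make-fixtures --out-dir fx --seed 42
genotracks plot --gwas fx/gwas.csv --de fx/de.csv --can fx/candidate.csv \
    --score-thr-gwas 4 --score-thr-de 1.3 --log2fc-thr 0 \
    --remove-empty-chrom -o example.png
```

and for a polyploid trait × model export:

```sh
genotracks polygwas-plot --scores fx/polygwas_scores.csv \
    --thresholds fx/polygwas_thresholds.csv \
    --traits tuber_eye_depth --models general,additive \
    --remove-empty-chrom -o polygwas.png
```

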
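"""Synthetic GWAS / DE / candidate / custom / polyploid-GWAS data.

Generates the full set of inputs the package consumes, with *planted*
significant regions so that recovery can be asserted:

* marker and gene positions are uniform over each chromosome;
* null scores are drawn as −log10(U(0,1)) — i.e. p-values uniform under
  the null — so the tail fraction above a threshold t is exactly 10^−t,
  giving tests a closed form to calibrate against;
* every marker/gene falling inside a planted region gets a fixed score
  offset added, and candidate genes are placed at the planted-region
  centres with names, so a sufficiently large effect guarantees that the
  chromosomes surviving empty-chromosome removal are exactly the planted
  ones;
* a polyploid-GWAS export (trait × genetic model groups with per-group
  thresholds) is derived from the same marker map.

Everything is deterministic given the seed.  The generator emulates the
*layout* of real potato-scale datasets (12 chromosomes of ~60 Mb), not
their genetics: there is no linkage disequilibrium, allele-frequency
structure or expression covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .polygwas import PolyGwasExport
from .tables import FeatureTable, validate_table

DEFAULT_TRAITS = ("tuber_eye_depth", "tuber_shape", "sucrose")
DEFAULT_MODELS = ("general", "additive", "1-dom-ref", "1-dom-alt")


@dataclass(frozen=True)
class PlantedRegion:
    """A genomic window whose features receive the score offset."""

    chromosome: str
    centre: float  # bp
    half_width: float  # bp

    @property
    def lo(self) -> float:
        return self.centre - self.half_width

    @property
    def hi(self) -> float:
        return self.centre + self.half_width


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic datasets.

    Defaults emulate a potato-like genome: 12 numbered chromosomes of
    60 Mb, two planted trait-associated regions, and an effect of +6
    score units — far above any conventional genome-wide threshold.
    """

    n_chromosomes: int = 12
    chrom_length: float = 60e6
    n_markers: int = 10_000
    n_genes: int = 3_000
    n_candidates: int = 8
    planted_regions: tuple[PlantedRegion, ...] = (
        PlantedRegion("3", 15e6, 0.5e6),
        PlantedRegion("10", 48.75e6, 0.25e6),
    )
    effect: float = 6.0
    mean_gene_length: float = 3_000.0
    seed: int = 0
    traits: tuple[str, ...] = DEFAULT_TRAITS
    models: tuple[str, ...] = DEFAULT_MODELS
    n_polygwas_markers: int = 500
    polygwas_threshold: float = 4.0

    def __post_init__(self):
        chroms = set(self.chromosome_ids)
        for r in self.planted_regions:
            if r.chromosome not in chroms:
                raise ConfigError(f"planted region on unknown chromosome {r.chromosome!r}")
            if r.lo < 0 or r.hi > self.chrom_length:
                raise ConfigError(
                    f"planted region [{r.lo:g}, {r.hi:g}] outside chromosome "
                    f"{r.chromosome!r} bounds [0, {self.chrom_length:g}]"
                )

    @property
    def chromosome_ids(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]

    @property
    def planted_chromosomes(self) -> set[str]:
        return {r.chromosome for r in self.planted_regions}


@dataclass
class SimulatedData:
    """The full bundle of synthetic inputs."""

    gwas: FeatureTable
    de: FeatureTable
    candidate: FeatureTable
    custom: dict[str, FeatureTable]  # aes_type tag -> table
    polygwas: PolyGwasExport
    config: SimulationConfig


def _null_scores(rng: np.random.Generator, n: int) -> np.ndarray:
    """−log10 of uniform p-values: P(score ≥ t) = 10^−t."""
    return -np.log10(rng.uniform(size=n))


def _in_planted(config: SimulationConfig, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
    hit = np.zeros(len(pos), dtype=bool)
    for r in config.planted_regions:
        hit |= (chrom == r.chromosome) & (pos >= r.lo) & (pos <= r.hi)
    return hit


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedData:
    """Generate GWAS, DE, candidate, custom and polyploid-GWAS inputs."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    chrom_ids = np.array(config.chromosome_ids)

    # GWAS markers
    g_chrom = rng.choice(chrom_ids, size=config.n_markers)
    g_pos = np.floor(rng.uniform(0, config.chrom_length, size=config.n_markers))
    g_score = _null_scores(rng, config.n_markers)
    g_score[_in_planted(config, g_chrom, g_pos)] += config.effect
    gwas = validate_table(
        pd.DataFrame(
            {
                "chromosome": g_chrom,
                "position": g_pos.astype(int),
                "score": g_score,
                "marker": [f"snp_{i:05d}" for i in range(config.n_markers)],
            }
        ),
        "gwas",
        label="GWAS",
    )

    # DE genes: padj derived from the null score; log2FC larger in planted regions
    d_chrom = rng.choice(chrom_ids, size=config.n_genes)
    d_len = rng.exponential(config.mean_gene_length, size=config.n_genes) + 200
    d_start = np.floor(rng.uniform(0, config.chrom_length - d_len))
    d_end = np.floor(d_start + d_len)
    d_mid = (d_start + d_end) / 2
    d_score = _null_scores(rng, config.n_genes)
    planted_genes = _in_planted(config, d_chrom, d_mid)
    d_score[planted_genes] += config.effect
    d_padj = np.power(10.0, -d_score)
    d_l2fc = rng.normal(0, 0.5, size=config.n_genes)
    d_l2fc[planted_genes] += rng.choice([-2.0, 2.0], size=planted_genes.sum())
    de = validate_table(
        pd.DataFrame(
            {
                "chromosome": d_chrom,
                "start": d_start.astype(int),
                "end": d_end.astype(int),
                "padj": d_padj,
                "log2FoldChange": d_l2fc,
                "gene_id": [f"gene_{i:05d}" for i in range(config.n_genes)],
            }
        ),
        "de",
        label="DE",
    )

    # candidate genes: one at each planted centre (named), the rest random
    c_rows = []
    for i, r in enumerate(config.planted_regions):
        c_rows.append(
            {
                "chromosome": r.chromosome,
                "start": int(r.centre - 1_500),
                "end": int(r.centre + 1_500),
                "name": f"CAND_{r.chromosome}_{i}",
            }
        )
    n_extra = max(config.n_candidates - len(c_rows), 0)
    e_chrom = rng.choice(chrom_ids, size=n_extra)
    e_start = np.floor(rng.uniform(0, config.chrom_length - 3_000, size=n_extra))
    for j in range(n_extra):
        c_rows.append(
            {
                "chromosome": e_chrom[j],
                "start": int(e_start[j]),
                "end": int(e_start[j]) + 3_000,
                # every third extra candidate is unnamed: point without label
                "name": None if j % 3 == 2 else f"CAND_x{j}",
            }
        )
    candidate = validate_table(pd.DataFrame(c_rows), "candidate", label="Candidates")

    # custom tracks: QTL-like regions (few, named) and DMR-like sites (many)
    n_qtl = max(config.n_chromosomes // 3, 2)
    q_chrom = rng.choice(chrom_ids, size=n_qtl)
    q_pos = np.floor(rng.uniform(0, config.chrom_length, size=n_qtl))
    qtl = validate_table(
        pd.DataFrame(
            {
                "chromosome": q_chrom,
                "position": q_pos.astype(int),
                "score": _null_scores(rng, n_qtl) + 3.0,
                "name": [f"QTL_{i}" for i in range(n_qtl)],
            }
        ),
        "custom",
        label="QTL regions",
        aes_type="QTL",
    )
    n_dmr = config.n_genes // 10
    m_chrom = rng.choice(chrom_ids, size=n_dmr)
    m_pos = np.floor(rng.uniform(0, config.chrom_length, size=n_dmr))
    m_score = _null_scores(rng, n_dmr)
    m_score[_in_planted(config, m_chrom, m_pos)] += config.effect
    dmr = validate_table(
        pd.DataFrame(
            {
                "chromosome": m_chrom,
                "position": m_pos.astype(int),
                "score": m_score,
            }
        ),
        "custom",
        label="Diff. methylated regions",
        aes_type="DMR",
    )

    # polyploid-GWAS export on a marker subset; the first trait carries the
    # planted signal under the general and additive models only
    idx = rng.choice(config.n_markers, size=min(config.n_polygwas_markers, config.n_markers), replace=False)
    idx.sort()
    p_chrom, p_pos = g_chrom[idx], g_pos[idx]
    rows = []
    for trait in config.traits:
        for model in config.models:
            s = _null_scores(rng, len(idx))
            if trait == config.traits[0] and model in ("general", "additive"):
                s[_in_planted(config, p_chrom, p_pos)] += config.effect
            rows.append(
                pd.DataFrame(
                    {
                        "trait": trait,
                        "model": model,
                        "marker": [f"snp_{i:05d}" for i in idx],
                        "chromosome": p_chrom,
                        "position": p_pos.astype(int),
                        "score": s,
                    }
                )
            )
    thresholds = {
        (t, m): config.polygwas_threshold + round(rng.uniform(-0.3, 0.3), 3)
        for t in config.traits
        for m in config.models
    }
    polygwas = PolyGwasExport(records=pd.concat(rows, ignore_index=True), thresholds=thresholds)

    return SimulatedData(
        gwas=gwas, de=de, candidate=candidate,
        custom={"QTL": qtl, "DMR": dmr},
        polygwas=polygwas, config=config,
    )


def write_fixtures(data: SimulatedData, out_dir: str | Path) -> dict[str, Path]:
    """Write every synthetic input as CSV in the package's exchange dialects.

    Returns a mapping of logical names to written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False, na_rep="")
        paths[name] = p

    _write("gwas", data.gwas.data)
    _write("de", data.de.data.drop(columns=["score", "log2fc", "position"]))
    _write("candidate", data.candidate.data.drop(columns=["position"]))
    for tag, table in data.custom.items():
        _write(f"custom_{tag.lower()}", table.data)
    _write("polygwas_scores", data.polygwas.records)
    thr = pd.DataFrame(
        [(t, m, v) for (t, m), v in data.polygwas.thresholds.items()],
        columns=["trait", "model", "threshold"],
    )
    _write("polygwas_thresholds", thr)
    lengths = pd.DataFrame(
        {"chromosome": data.config.chromosome_ids, "length": int(data.config.chrom_length)}
    )
    _write("chrom_lengths", lengths)
    return paths
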
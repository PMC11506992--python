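"""Bridge for polyploid GWAS results organised by trait × genetic model.

Polyploid GWAS tools (e.g. for autotetraploids) score every marker under
several genetic models — general, additive, simplex dominant with respect
to the reference or alternate allele — and compute a separate significance
threshold for each trait × model combination.  This module ingests such
results from a language-neutral CSV export:

``scores.csv``      header ``trait,model,marker,chromosome,position,score``
``thresholds.csv``  header ``trait,model,threshold``

and turns each retained (trait, model) pair into a GWAS feature track
labelled ``"<trait>, <model>"`` carrying its own threshold, which the
filtering step uses in place of the global GWAS threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import SchemaError
from .tables import FeatureTable, validate_table

SCORE_COLUMNS = ("trait", "model", "marker", "chromosome", "position", "score")
THRESHOLD_COLUMNS = ("trait", "model", "threshold")


@dataclass
class PolyGwasExport:
    """Scores for every trait × genetic-model pair, plus their thresholds.

    Invariant (enforced at construction): every (trait, model) pair in
    ``records`` has a threshold entry.
    """

    records: pd.DataFrame
    thresholds: dict[tuple[str, str], float]

    def __post_init__(self):
        pairs = self.pairs
        missing = [p for p in pairs if p not in self.thresholds]
        if missing:
            raise SchemaError(
                "polygwas",
                [f"no threshold for (trait, model) pair {t!r}, {m!r}" for t, m in missing],
            )

    @property
    def pairs(self) -> list[tuple[str, str]]:
        """(trait, model) pairs in order of first appearance."""
        seen = self.records[["trait", "model"]].drop_duplicates()
        return [(str(t), str(m)) for t, m in seen.itertuples(index=False)]

    @property
    def traits(self) -> list[str]:
        return list(dict.fromkeys(t for t, _ in self.pairs))

    @property
    def models(self) -> list[str]:
        return list(dict.fromkeys(m for _, m in self.pairs))


def read_polygwas_export(
    scores_csv: str | Path,
    thresholds_csv: str | Path,
) -> PolyGwasExport:
    """Read the two-file CSV export and join thresholds to score groups.

    Raises a schema error when a column is missing or a (trait, model)
    pair present in the scores has no threshold, and a value error on a
    duplicated (trait, model, marker) triple.
    """
    scores = pd.read_csv(scores_csv, keep_default_na=False, na_values=["", "NA"])
    thr = pd.read_csv(thresholds_csv, keep_default_na=False, na_values=["", "NA"])
    problems = [
        f"scores file missing column {c!r}" for c in SCORE_COLUMNS if c not in scores.columns
    ] + [
        f"thresholds file missing column {c!r}"
        for c in THRESHOLD_COLUMNS
        if c not in thr.columns
    ]
    if problems:
        raise SchemaError("polygwas", problems)

    dup = scores.duplicated(subset=["trait", "model", "marker"])
    if dup.any():
        bad = scores.loc[dup, ["trait", "model", "marker"]].head(5)
        raise ValueError(
            "duplicate (trait, model, marker) rows in scores export: "
            + "; ".join(f"({t}, {m}, {k})" for t, m, k in bad.itertuples(index=False))
        )
    for col in ("trait", "model"):
        scores[col] = scores[col].astype(str)
        thr[col] = thr[col].astype(str)
    thresholds = {
        (t, m): float(v) for t, m, v in thr[["trait", "model", "threshold"]].itertuples(index=False)
    }
    return PolyGwasExport(records=scores, thresholds=thresholds)


def to_gwas_tracks(
    export: PolyGwasExport,
    traits: Sequence[str] | None = None,
    models: Sequence[str] | None = None,
) -> list[tuple[FeatureTable, float]]:
    """One GWAS track per retained (trait, model) pair, with its threshold.

    ``traits`` / ``models`` subset the export; by default every pair is
    returned.  Markers with a missing score are kept here and removed at
    filtering, consistent with how NA scores are handled everywhere else.
    """
    if traits is not None:
        traits = [str(t) for t in traits]
        unknown = sorted(set(traits) - set(export.traits))
        if unknown or not traits:
            raise ValueError(
                f"unknown or empty trait selection {unknown or traits}; "
                f"valid traits: {export.traits}"
            )
    if models is not None:
        models = [str(m) for m in models]
        unknown = sorted(set(models) - set(export.models))
        if unknown or not models:
            raise ValueError(
                f"unknown or empty model selection {unknown or models}; "
                f"valid models: {export.models}"
            )

    out: list[tuple[FeatureTable, float]] = []
    for trait, model in export.pairs:
        if traits is not None and trait not in traits:
            continue
        if models is not None and model not in models:
            continue
        sub = export.records[
            (export.records["trait"] == trait) & (export.records["model"] == model)
        ]
        table = validate_table(
            sub.drop(columns=["trait", "model"]),
            "gwas",
            label=f"{trait}, {model}",
        )
        out.append((table, export.thresholds[(trait, model)]))
    if not out:
        raise ValueError("trait/model selection matched no (trait, model) pair")
    return out
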
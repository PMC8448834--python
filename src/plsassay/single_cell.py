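"""Single-cell QC filters, per-cell normalization, and viral-load enrichment.

Two filter families mirror the assay's upstream processing:

* per-cell filters — read alignment rate (>= 50%, inclusive) and aligned
  read pairs (>= 100,000, inclusive); mitochondrial fraction (> 80%
  removed, strict) and total transcripts (< 1500 removed, strict);
* per-gene filters — transcripts whose Pearson correlation with the
  KCNQ1OT1 artifact gene exceeds 0.4 are removed, and genes must reach
  ``minexpr`` counts in at least ``minnumber`` cells.

Passing cells are normalized so every column sum equals the minimum total
of the passing cells.  The biological readout correlates each gene with
the per-cell viral load (Pearson) and scores the signature halves on that
correlation ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import EnrichmentParams, EnrichmentResult, gsea, rank_by_correlation
from .signature import ExpressionMatrix, PrognosticSignature

logger = logging.getLogger(__name__)

__all__ = [
    "CellQCParams",
    "CellStats",
    "filter_cells_alignment",
    "filter_cells_counts",
    "filter_artifact_and_rare_genes",
    "sc_normalize",
    "viral_load_enrichment",
]


@dataclass(frozen=True)
class CellQCParams:
    """Thresholds for the single-cell filters (defaults are the assay's)."""

    mintotal: int = 1500
    mito_max: float = 0.80
    artifact_gene: str = "KCNQ1OT1"
    artifact_r: float = 0.4
    minexpr: int = 2
    minnumber: int = 5
    align_rate_min: float = 0.50
    aligned_pairs_min: int = 100_000
    mito_prefixes: tuple[str, ...] = ("MT-",)

    def __post_init__(self) -> None:
        if not (0 <= self.mito_max <= 1 and 0 <= self.align_rate_min <= 1):
            raise ValueError("fraction thresholds must lie in [0, 1]")
        if min(self.mintotal, self.minexpr, self.minnumber, self.aligned_pairs_min) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class CellStats:
    """Per-cell alignment statistics and the viral-load covariate."""

    cell_id: str
    total_transcripts: int | None = None
    mito_fraction: float | None = None
    align_rate: float | None = None
    aligned_pairs: int | None = None
    viral_load: float | None = None


def filter_cells_alignment(stats: Sequence[CellStats], p: CellQCParams) -> list[str]:
    """Keep cells with align_rate >= 50% and >= 100,000 aligned pairs.

    Both thresholds are inclusive ("at least").
    """
    kept = []
    for s in stats:
        if s.align_rate is None or s.aligned_pairs is None:
            raise ValueError(f"cell {s.cell_id!r}: missing alignment statistics")
        if s.align_rate >= p.align_rate_min and s.aligned_pairs >= p.aligned_pairs_min:
            kept.append(s.cell_id)
    return kept


def _mito_mask(gene_ids: pd.Index, p: CellQCParams) -> np.ndarray:
    return np.array([any(g.startswith(pre) for pre in p.mito_prefixes) for g in gene_ids])


def filter_cells_counts(
    counts: ExpressionMatrix,
    p: CellQCParams = CellQCParams(),
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Drop cells with > 80% mitochondrial counts or < 1500 transcripts.

    Both thresholds are strict, matching the wording of the originating
    protocol (">80%" removed, "<1500" removed).  Returns the filtered
    matrix and per-rule removal counts.
    """
    vals = counts.values.to_numpy(dtype=float)
    totals = vals.sum(axis=0)
    mito = _mito_mask(counts.gene_ids, p)
    with np.errstate(invalid="ignore"):
        mito_frac = np.where(totals > 0, vals[mito].sum(axis=0) / totals, 1.0)
    drop_mito = mito_frac > p.mito_max
    drop_total = totals < p.mintotal
    keep = ~(drop_mito | drop_total)
    removed = {
        "mito_fraction": int(drop_mito.sum()),
        "min_total": int(drop_total.sum()),
    }
    filtered = counts.subset_samples(list(counts.sample_ids[keep]))
    return filtered, removed


def filter_artifact_and_rare_genes(
    counts: ExpressionMatrix,
    p: CellQCParams = CellQCParams(),
) -> tuple[ExpressionMatrix, dict[str, list[str]]]:
    """Remove artifact-correlated transcripts and rarely expressed genes.

    Genes whose Pearson correlation with the artifact gene exceeds
    ``artifact_r`` are removed (the artifact gene correlates perfectly
    with itself and is removed too); remaining genes must show at least
    ``minexpr`` counts in at least ``minnumber`` cells.  If the artifact
    gene is absent the correlation rule is skipped with a warning.
    """
    vals = counts.values.to_numpy(dtype=float)
    gene_ids = counts.gene_ids
    removed_artifact: list[str] = []
    if p.artifact_gene in gene_ids:
        ref = counts.values.loc[p.artifact_gene].to_numpy(dtype=float)
        if ref.std() > 0:
            centered = vals - vals.mean(axis=1, keepdims=True)
            ref_c = ref - ref.mean()
            denom = np.sqrt((centered**2).sum(axis=1)) * np.sqrt((ref_c**2).sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(denom > 0, centered @ ref_c / denom, 0.0)
            removed_artifact = list(gene_ids[r > p.artifact_r])
    else:
        logger.warning(
            "artifact gene %r not in matrix; correlation filter skipped", p.artifact_gene
        )
    keep1 = ~gene_ids.isin(removed_artifact)
    expressed = (vals >= p.minexpr).sum(axis=1) >= p.minnumber
    removed_rare = list(gene_ids[keep1 & ~expressed])
    keep = keep1 & expressed
    out = ExpressionMatrix(
        values=counts.values.loc[gene_ids[keep]],
        scale=counts.scale,
        sample_meta=counts.sample_meta,
    )
    return out, {"artifact_correlated": removed_artifact, "rare": removed_rare}


def sc_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each cell to the minimum total transcript count.

    Every cell's counts are divided by its own total and multiplied by the
    minimum total across cells, so all column sums end up exactly equal
    while within-cell proportions are untouched.
    """
    if counts.n_samples < 1:
        raise ValueError("no cells to normalize")
    vals = counts.values.to_numpy(dtype=float)
    totals = vals.sum(axis=0)
    if (totals <= 0).any():
        bad = list(counts.sample_ids[totals <= 0])
        raise ValueError(f"zero-total cell(s): {bad}")
    scaled = vals / totals[None, :] * totals.min()
    return ExpressionMatrix(
        values=pd.DataFrame(scaled, index=counts.gene_ids, columns=counts.sample_ids),
        scale=counts.scale,
        sample_meta=counts.sample_meta,
    )


def viral_load_enrichment(
    counts: ExpressionMatrix,
    viral_load: Sequence[float],
    sig: PrognosticSignature,
    params: EnrichmentParams = EnrichmentParams(),
) -> tuple[EnrichmentResult, EnrichmentResult, dict[str, float]]:
    """Correlation-ranked enrichment of the signature halves vs viral load.

    Genes are ranked by their Pearson correlation with the per-cell viral
    load and the poor/good sets are scored preranked.  Additionally the
    Pearson correlation between each set's mean expression and the viral
    load is reported (with its two-sided p-value), matching the set-level
    correlation readout.
    """
    load = np.asarray(viral_load, dtype=float)
    if len(load) != counts.n_samples:
        raise ValueError("viral load length does not match cell count")
    if np.std(load) == 0:
        raise ValueError("viral load is constant across cells")
    rl = rank_by_correlation(counts, load)
    results = gsea(rl, [sig.poor, sig.good], params)
    poor = next(r for r in results if r.set_name == sig.poor.name)
    good = next(r for r in results if r.set_name == sig.good.name)
    set_corr: dict[str, float] = {}
    for label, gs in (("poor", sig.poor), ("good", sig.good)):
        present = [g for g in gs.genes if g in counts.gene_ids]
        mean_expr = counts.values.loc[present].mean(axis=0).to_numpy()
        if np.std(mean_expr) == 0:
            set_corr[f"r_{label}"], set_corr[f"p_{label}"] = float("nan"), float("nan")
        else:
            r, pval = stats.pearsonr(mean_expr, load)
            set_corr[f"r_{label}"], set_corr[f"p_{label}"] = float(r), float(pval)
    return poor, good, set_corr
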
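"""Housekeeping-gene normalization and display transforms for bulk matrices.

The assay measures a small gene panel (NanoString-style counts), so library
size cannot be estimated from the panel itself; instead each sample is
scaled by the geometric mean of its housekeeping-gene counts.  Scale
factors are re-centred on their own geometric mean so the grand scale of
the matrix is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .signature import ExpressionMatrix, GeneSet

__all__ = [
    "NormalizationResult",
    "housekeeping_normalize",
    "log2_with_pseudocount",
    "row_zscore",
]


@dataclass
class NormalizationResult:
    matrix: ExpressionMatrix
    factors: pd.Series  # per-sample housekeeping geometric mean
    method: str = "housekeeping-geomean"

    def write_factors(self, path: str | Path) -> None:
        self.factors.rename("factor").to_csv(path, sep="\t", index_label="sample_id")


def housekeeping_normalize(
    m: ExpressionMatrix,
    hk: GeneSet,
    pseudocount: float = 0.5,
) -> NormalizationResult:
    """Scale each sample by its housekeeping geometric mean.

    factor_s = geomean over housekeeping genes g of (count[g, s] + pseudocount);
    sample s is multiplied by reference / factor_s with reference the
    geometric mean of all factors, so the product of the applied scalings
    is exactly 1.

    Raises if the matrix is not count-scale or no housekeeping gene is
    present.  The pseudocount keeps factors strictly positive in the
    presence of zero counts.
    """
    if m.scale != "counts":
        raise ValueError("housekeeping normalization expects a count-scale matrix")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    hk_present = [g for g in hk.genes if g in m.gene_ids]
    if not hk_present:
        raise ValueError(
            f"no housekeeping gene of {hk.name!r} found in matrix"
        )
    hk_vals = m.values.loc[hk_present].to_numpy(dtype=float) + pseudocount
    if (hk_vals <= 0).any():
        raise ValueError("non-positive housekeeping values; increase pseudocount")
    factors = np.exp(np.log(hk_vals).mean(axis=0))
    reference = np.exp(np.log(factors).mean())
    scaled = m.values.to_numpy(dtype=float) * (reference / factors)[None, :]
    out = ExpressionMatrix(
        values=pd.DataFrame(scaled, index=m.gene_ids, columns=m.sample_ids),
        scale="counts",
        sample_meta=m.sample_meta,
    )
    return NormalizationResult(
        matrix=out,
        factors=pd.Series(factors, index=m.sample_ids, name="factor"),
    )


def log2_with_pseudocount(m: ExpressionMatrix, c: float = 1.0) -> ExpressionMatrix:
    """log2(value + c) transform; flips the scale flag to ``log2``."""
    if m.scale != "counts":
        raise ValueError("matrix is already log-scale")
    if c <= 0:
        raise ValueError("pseudocount must be positive")
    return ExpressionMatrix(
        values=np.log2(m.values + c),
        scale="log2",
        sample_meta=m.sample_meta,
    )


def row_zscore(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-scores (mean 0, sample sd 1 with the n-1 denominator).

    Constant rows map to all-zero rows rather than NaN.  This is the
    display transform behind signature heatmaps of log2-normalized data.
    """
    if m.n_samples < 2:
        raise ValueError("row z-scores require at least 2 samples")
    vals = m.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return ExpressionMatrix(
        values=pd.DataFrame(z, index=m.gene_ids, columns=m.sample_ids),
        scale="log2",
        sample_meta=m.sample_meta,
    )
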
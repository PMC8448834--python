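"""PLS status classification, reversal assessment and screen orchestration.

A sample comparison is classified by scoring the poor-prognosis and
good-prognosis halves of the signature against the case-vs-reference
ranking.  The induction score is the NES difference Δ = NES_poor −
NES_good; the global label is *poor* (Δ > 0), *good* (Δ < 0), or
*indeterminate* when neither set reaches significance (min q ≥ α, with
α = 0.25 by convention).

Reversal of an induced poor-prognosis signature by a compound is read
one-sidedly: the poor set must be suppressed (NES < 0) and/or the good
set induced (NES > 0), significantly, in the treated-vs-injured-control
comparison.  A screen ranks compounds by their best reversal-direction
q-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import EnrichmentParams, EnrichmentResult, gsea
from .normalization import housekeeping_normalize, log2_with_pseudocount
from .signature import ExpressionMatrix, GeneSet, PrognosticSignature, match_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "PLSStatus",
    "ScreenResult",
    "assess_pls",
    "global_status",
    "heatmap_encode",
    "assess_reversal",
    "run_screen",
    "screen_frame",
]

ALPHA_DEFAULT = 0.25


class CoverageError(ValueError):
    """Signature coverage in the matrix is below the required fraction."""


@dataclass
class PLSStatus:
    """Paired poor/good enrichment results and the derived classification."""

    poor: EnrichmentResult
    good: EnrichmentResult
    delta: float
    global_label: str
    heatmap: dict[str, float]
    alpha: float = ALPHA_DEFAULT
    reversal_significant: bool | None = None

    def to_dict(self) -> dict:
        return {
            "global_label": self.global_label,
            "delta": self.delta,
            "alpha": self.alpha,
            "poor": {
                "ES": self.poor.es,
                "NES": self.poor.nes,
                "p_nominal": self.poor.p_nominal,
                "fdr_q": self.poor.fdr_q,
                "n_hits": self.poor.n_hits,
                "leading_edge": list(self.poor.leading_edge),
            },
            "good": {
                "ES": self.good.es,
                "NES": self.good.nes,
                "p_nominal": self.good.p_nominal,
                "fdr_q": self.good.fdr_q,
                "n_hits": self.good.n_hits,
                "leading_edge": list(self.good.leading_edge),
            },
            "heatmap": self.heatmap,
            "reversal_significant": self.reversal_significant,
        }


@dataclass
class ScreenResult:
    compounds: pd.DataFrame  # one row per compound, ranked
    statuses: Mapping[str, PLSStatus]

    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    @property
    def n_hits(self) -> int:
        return int(self.compounds["hit"].sum())

    @property
    def hit_rate(self) -> float:
        return self.n_hits / self.n_compounds

    @property
    def hits(self) -> list[str]:
        return list(self.compounds.loc[self.compounds["hit"], "compound"])


def global_status(
    poor: EnrichmentResult, good: EnrichmentResult, alpha: float = ALPHA_DEFAULT
) -> tuple[str, float]:
    """Classify a comparison from its two set-level results.

    Δ = NES_poor − NES_good; the label follows sign(Δ) but only when at
    least one set is significant at ``alpha``.
    """
    nes_p = poor.nes if np.isfinite(poor.nes) else 0.0
    nes_g = good.nes if np.isfinite(good.nes) else 0.0
    delta = nes_p - nes_g
    if min(poor.fdr_q, good.fdr_q) >= alpha or delta == 0:
        return "indeterminate", delta
    return ("poor" if delta > 0 else "good"), delta


def heatmap_encode(r: EnrichmentResult, floor: float = 1e-4) -> float:
    """Signed significance for simplified heatmaps: sign(NES) x -log10(q)."""
    q = max(min(r.fdr_q, 1.0), floor)
    sign = np.sign(r.nes) if np.isfinite(r.nes) else 0.0
    return float(sign * -np.log10(q))


def _prepare_joint(
    case: ExpressionMatrix,
    reference: ExpressionMatrix,
    sig: PrognosticSignature,
    min_coverage: float,
    hk_pseudocount: float,
) -> tuple[ExpressionMatrix, list[str], list[str]]:
    """Merge arms on the shared gene space and normalize jointly."""
    shared = case.gene_ids.intersection(reference.gene_ids)
    if len(shared) < 2:
        raise ValueError("case and reference share fewer than 2 genes")
    case_ids = [f"case:{s}" for s in case.sample_ids]
    ref_ids = [f"ref:{s}" for s in reference.sample_ids]
    merged = pd.concat(
        [
            case.values.loc[shared].set_axis(case_ids, axis=1),
            reference.values.loc[shared].set_axis(ref_ids, axis=1),
        ],
        axis=1,
    )
    if case.scale != reference.scale:
        raise ValueError("case and reference matrices are on different scales")
    m = ExpressionMatrix(values=merged, scale=case.scale)

    report = match_matrix(sig, m)
    low = {
        k: report.coverage[k]
        for k in ("poor", "good")
        if report.coverage[k] < min_coverage
    }
    if low:
        missing = {k: list(report.missing[k]) for k in low}
        raise CoverageError(
            f"signature coverage below {min_coverage:.0%}: "
            + "; ".join(f"{k}={v:.0%}, missing {missing[k]}" for k, v in low.items())
        )

    if m.scale == "counts":
        m = housekeeping_normalize(m, sig.housekeeping, pseudocount=hk_pseudocount).matrix
        m = log2_with_pseudocount(m)
    return m, case_ids, ref_ids


def assess_pls(
    case: ExpressionMatrix,
    reference: ExpressionMatrix,
    sig: PrognosticSignature,
    params: EnrichmentParams = EnrichmentParams(),
    alpha: float = ALPHA_DEFAULT,
    min_coverage: float = 0.5,
    hk_pseudocount: float = 0.5,
) -> PLSStatus:
    """Full signature-status readout of a case-vs-reference comparison.

    The two arms are merged, jointly housekeeping-normalized (count-scale
    inputs), log2-transformed, ranked case-vs-reference, and both
    signature halves are scored with a shared permutation null.
    """
    m, case_ids, ref_ids = _prepare_joint(case, reference, sig, min_coverage, hk_pseudocount)
    results = gsea((m, case_ids, ref_ids), [sig.poor, sig.good], params)
    poor = next(r for r in results if r.set_name == sig.poor.name)
    good = next(r for r in results if r.set_name == sig.good.name)
    label, delta = global_status(poor, good, alpha)
    heat = {
        "poor": heatmap_encode(poor),
        "good": heatmap_encode(good),
        "global": heatmap_encode(poor) - heatmap_encode(good),
    }
    return PLSStatus(
        poor=poor, good=good, delta=delta, global_label=label, heatmap=heat, alpha=alpha
    )


def assess_reversal(
    treated: ExpressionMatrix,
    control: ExpressionMatrix,
    sig: PrognosticSignature,
    params: EnrichmentParams = EnrichmentParams(),
    alpha: float = ALPHA_DEFAULT,
    **kwargs,
) -> PLSStatus:
    """Score a treated-vs-injured-control comparison for signature reversal.

    Reversal is significant iff the poor set is significantly suppressed
    (q < α and NES < 0) or the good set significantly induced (q < α and
    NES > 0).
    """
    status = assess_pls(treated, control, sig, params, alpha=alpha, **kwargs)
    status.reversal_significant = bool(
        (status.poor.fdr_q < alpha and status.poor.nes < 0)
        or (status.good.fdr_q < alpha and status.good.nes > 0)
    )
    return status


def _rank_key(status: PLSStatus) -> float:
    """Best q among the sets moving in the reversal direction (else 1)."""
    qs = []
    if status.poor.nes < 0:
        qs.append(status.poor.fdr_q)
    if status.good.nes > 0:
        qs.append(status.good.fdr_q)
    return min(qs) if qs else 1.0


def run_screen(
    arms: Mapping[str, ExpressionMatrix],
    control: ExpressionMatrix,
    sig: PrognosticSignature,
    params: EnrichmentParams = EnrichmentParams(),
    alpha: float = ALPHA_DEFAULT,
    **kwargs,
) -> ScreenResult:
    """Assess every compound arm against the injured control and rank.

    Compounds are ordered by their best reversal-direction q ascending,
    ties broken by |Δ| descending and then compound id; the hit flag is
    the per-compound reversal significance.
    """
    if not arms:
        raise ValueError("screen requires at least one compound arm")
    statuses: dict[str, PLSStatus] = {}
    for i, (cid, arm) in enumerate(arms.items()):
        p = EnrichmentParams(
            weight_p=params.weight_p,
            n_perm=params.n_perm,
            perm_mode=params.perm_mode,
            seed=params.seed + i,
            metric=params.metric,
        )
        statuses[cid] = assess_reversal(arm, control, sig, p, alpha=alpha, **kwargs)
    rows = []
    for cid, st in statuses.items():
        rows.append(
            {
                "compound": cid,
                "q_poor": st.poor.fdr_q,
                "q_good": st.good.fdr_q,
                "NES_poor": st.poor.nes,
                "NES_good": st.good.nes,
                "delta": st.delta,
                "hit": bool(st.reversal_significant),
                "_key": _rank_key(st),
            }
        )
    df = pd.DataFrame(rows)
    df["_absdelta"] = df["delta"].abs()
    df = df.sort_values(
        ["_key", "_absdelta", "compound"], ascending=[True, False, True]
    ).reset_index(drop=True)
    df.insert(1, "rank", np.arange(1, len(df) + 1))
    df = df.drop(columns=["_key", "_absdelta"])
    return ScreenResult(compounds=df, statuses=statuses)


def screen_frame(result: ScreenResult) -> pd.DataFrame:
    """Ranked screen table (compound, q/NES per set, delta, hit)."""
    return result.compounds.copy()
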
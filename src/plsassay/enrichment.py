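"""Weighted running-sum gene-set enrichment with a permutation null.

This module implements the Kolmogorov–Smirnov-style running-sum statistic
used to score the prognostic signature against a ranked gene list: genes
are ordered by a phenotype metric (signal-to-noise, log2 fold change) or a
per-sample covariate correlation; walking down the list, the running sum
increases by the (weighted) metric magnitude at gene-set members and
decreases by a constant at non-members; the enrichment score ES is the
maximal signed deviation of that walk.  A permutation null (random gene
sets of matched size by default, or phenotype-label shuffles) yields the
normalized score NES = ES / mean(|same-sign null ES|), a nominal p-value,
and a pooled-null FDR q-value across all queried sets.

The assay convention treats q < 0.25 as significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .signature import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "EnrichmentParams",
    "EnrichmentResult",
    "rank_by_phenotype",
    "rank_by_correlation",
    "enrichment_score",
    "null_distribution",
    "nes_and_fdr",
    "gsea",
    "read_rnk",
    "write_rnk",
    "results_frame",
]


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by a ranking metric, best (most positive) first.

    Ties in the metric are broken by gene id ascending so that every
    ranking is strictly reproducible.
    """

    genes: tuple[str, ...]
    metric: np.ndarray  # aligned with genes, descending
    metric_name: str = "metric"

    def __post_init__(self) -> None:
        metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != len(metric):
            raise ValueError("genes and metric lengths differ")
        if len(self.genes) < 2:
            raise ValueError("ranked list needs at least 2 genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")
        if np.any(np.diff(metric) > 0):
            raise ValueError("metric must be sorted descending")
        if not np.all(np.isfinite(metric)):
            raise ValueError("metric contains non-finite values")
        object.__setattr__(self, "metric", metric)

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_unsorted(
        cls, genes: Sequence[str], metric: Sequence[float], metric_name: str = "metric"
    ) -> "RankedList":
        genes = np.asarray(genes, dtype=object)
        metric = np.asarray(metric, dtype=float)
        order = np.lexsort((genes, -metric))  # metric desc, then gene id asc
        return cls(tuple(genes[order]), metric[order], metric_name)


@dataclass(frozen=True)
class EnrichmentParams:
    """Knobs for the enrichment run.

    weight_p: exponent on |metric| in the running sum (0 = classic KS,
        1 = weighted, the default).
    n_perm: permutations for the null (>= 100 for FDR reporting).
    perm_mode: ``gene_set`` (random same-size sets; default, robust at the
        assay's ~3 replicates per arm) or ``phenotype`` (label shuffles).
    metric: ranking metric for phenotype mode.
    """

    weight_p: float = 1.0
    n_perm: int = 1000
    perm_mode: str = "gene_set"
    seed: int = 0
    metric: str = "signal2noise"

    def __post_init__(self) -> None:
        if self.weight_p < 0:
            raise ValueError("weight_p must be non-negative")
        if self.weight_p not in (0, 1, 2):
            raise ValueError("weight_p must be one of 0, 1, 2")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100 for FDR reporting")
        if self.perm_mode not in ("gene_set", "phenotype"):
            raise ValueError(f"unknown perm_mode {self.perm_mode!r}")
        if self.metric not in ("signal2noise", "log2fc", "pearson"):
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    leading_edge: tuple[str, ...]
    n_hits: int
    null_summary: dict = field(default_factory=dict)
    degenerate: bool = False


# ---------------------------------------------------------------------------
# ranking metrics


def _signal2noise(case: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """(mu_case - mu_ref) / (sigma_case + sigma_ref), sigmas floored.

    Each group sd is floored at max(0.2 * |group mean|, 0.2), the GSEA-style
    guard against near-zero variance at small replicate numbers.
    """
    mu_c, mu_r = case.mean(axis=1), ref.mean(axis=1)
    sd_c, sd_r = case.std(axis=1, ddof=1), ref.std(axis=1, ddof=1)
    sd_c = np.maximum(sd_c, np.maximum(0.2 * np.abs(mu_c), 0.2))
    sd_r = np.maximum(sd_r, np.maximum(0.2 * np.abs(mu_r), 0.2))
    return (mu_c - mu_r) / (sd_c + sd_r)


def rank_by_phenotype(
    m: ExpressionMatrix,
    case: Sequence[str],
    ref: Sequence[str],
    metric: str = "signal2noise",
) -> RankedList:
    """Rank genes by a case-vs-reference differential metric."""
    case, ref = list(case), list(ref)
    unknown = (set(case) | set(ref)) - set(m.sample_ids)
    if unknown:
        raise ValueError(f"unknown sample labels: {sorted(unknown)}")
    if set(case) & set(ref):
        raise ValueError("case and reference groups overlap")
    c = m.values[case].to_numpy(dtype=float)
    r = m.values[ref].to_numpy(dtype=float)
    if metric == "signal2noise":
        if c.shape[1] < 2 or r.shape[1] < 2:
            raise ValueError("signal2noise requires >= 2 replicates per group")
        scores = _signal2noise(c, r)
    elif metric == "log2fc":
        if m.scale != "log2":
            raise ValueError("log2fc metric expects a log2-scale matrix")
        scores = c.mean(axis=1) - r.mean(axis=1)
    else:
        raise ValueError(f"unknown phenotype metric {metric!r}")
    return RankedList.from_unsorted(list(m.gene_ids), scores, metric)


def rank_by_correlation(m: ExpressionMatrix, covariate: Sequence[float]) -> RankedList:
    """Rank genes by Pearson correlation with a per-sample covariate.

    Zero-variance genes are excluded (their correlation is undefined); the
    number dropped is logged.
    """
    cov = np.asarray(covariate, dtype=float)
    if len(cov) != m.n_samples:
        raise ValueError("covariate length does not match sample count")
    if m.n_samples < 3:
        raise ValueError("correlation ranking requires >= 3 samples")
    if np.std(cov) == 0:
        raise ValueError("covariate is constant; correlation undefined")
    vals = m.values.to_numpy(dtype=float)
    keep = vals.std(axis=1) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("rank_by_correlation: excluded %d zero-variance gene(s)", n_dropped)
    vals = vals[keep]
    vc = vals - vals.mean(axis=1, keepdims=True)
    cc = cov - cov.mean()
    r = (vc @ cc) / (np.sqrt((vc**2).sum(axis=1)) * np.sqrt((cc**2).sum()))
    return RankedList.from_unsorted(list(np.asarray(m.gene_ids, dtype=object)[keep]), r, "pearson")


# ---------------------------------------------------------------------------
# running-sum statistic


def sample_index_sets(
    rng: np.random.Generator, n: int, k: int, draws: int
) -> np.ndarray:
    """``draws`` sorted random k-subsets of range(n), as a (draws, k) array.

    Implemented as the k smallest of n iid uniform keys per draw, which is
    a uniform subset; falls back to per-draw sampling when the key matrix
    would be too large.
    """
    if draws * n <= 2e7:
        keys = rng.random((draws, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    else:
        idx = np.stack([rng.choice(n, size=k, replace=False) for _ in range(draws)])
    idx.sort(axis=1)
    return idx


def _hit_weights(absmetric_at_hits: np.ndarray, weight_p: float) -> np.ndarray:
    if weight_p == 0:
        return np.ones_like(absmetric_at_hits)
    w = absmetric_at_hits ** weight_p
    if w.sum() == 0:  # all hit metrics exactly zero: fall back to equal weights
        return np.ones_like(w)
    return w


def enrichment_score(
    rl: RankedList, s: GeneSet, weight_p: float = 1.0
) -> tuple[float, np.ndarray, tuple[str, ...]]:
    """ES, full running sum, and leading edge of one set on one ranking.

    The running sum gains |metric|^p / N_R at each set member and loses
    1/(N - N_H) at each non-member; ES is its maximal signed deviation
    from zero.  The leading edge is the set members at or before the
    maximum (ES > 0), or at or after the minimum (ES < 0).
    """
    n = len(rl)
    member = np.isin(np.asarray(rl.genes, dtype=object), list(s.genes))
    n_hits = int(member.sum())
    if n_hits == 0:
        raise ValueError(f"gene set {s.name!r} has no genes in the ranked list")
    if n_hits == n:
        raise ValueError(f"gene set {s.name!r} covers the whole ranked list")
    # accumulate hit weights and miss counts separately, dividing once, so
    # the extremes (e.g. a set occupying the bottom ranks) are exact
    w_full = np.zeros(n)
    w = _hit_weights(np.abs(rl.metric[member]), weight_p)
    w_full[member] = w
    cum_hit = np.cumsum(w_full) / w.sum()
    cum_miss = np.cumsum(~member) / (n - n_hits)
    running = cum_hit - cum_miss
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    # ties in |deviation| (common for weight_p = 0) resolve to the positive
    # extreme, with a small tolerance so the rule is float-stable
    if running[i_max] + running[i_min] >= -1e-12:
        es = float(running[i_max])
        le_mask = member & (np.arange(n) <= i_max)
    else:
        es = float(running[i_min])
        le_mask = member & (np.arange(n) >= i_min)
    leading = tuple(np.asarray(rl.genes, dtype=object)[le_mask])
    return es, running, leading


def _es_from_positions(
    positions: np.ndarray, absmetric: np.ndarray, n: int, weight_p: float
) -> np.ndarray:
    """Vectorized ES for many same-size hit-position vectors.

    ``positions`` is (B, h) of sorted 0-based ranks.  Between hits the
    running sum decays linearly, so its extrema occur only immediately
    after a hit (candidate maxima) or immediately before one (candidate
    minima); evaluating those 2h points reproduces the full walk exactly.
    """
    pos = np.asarray(positions)
    if pos.ndim == 1:
        pos = pos[None, :]
    b, h = pos.shape
    if weight_p == 0:
        cum = np.broadcast_to(np.arange(1, h + 1, dtype=float) / h, (b, h))
    else:
        w = absmetric[pos] ** weight_p
        tot = w.sum(axis=1, keepdims=True)
        flat = (tot == 0).ravel()
        if flat.any():
            w[flat] = 1.0
            tot = w.sum(axis=1, keepdims=True)
        cum = np.cumsum(w, axis=1) / tot
    miss = (pos - np.arange(h)) / (n - h)  # misses strictly before each hit
    dev_after = cum - miss
    dev_before = np.concatenate([np.zeros((b, 1)), cum[:, :-1]], axis=1) - miss
    es_pos = np.maximum(dev_after.max(axis=1), 0.0)
    es_neg = np.minimum(dev_before.min(axis=1), 0.0)
    return np.where(es_pos + es_neg >= -1e-12, es_pos, es_neg)


def null_distribution(
    rl: RankedList,
    set_size: int,
    params: EnrichmentParams,
    rerank: tuple[ExpressionMatrix, Sequence[str], Sequence[str]] | None = None,
    genes: Sequence[str] | None = None,
) -> np.ndarray:
    """Sample the null ES distribution for one set size.

    ``gene_set`` mode scores ``n_perm`` random same-size gene sets on the
    fixed ranking; ``phenotype`` mode shuffles the sample labels, re-ranks
    and re-scores the given ``genes`` (requires the matrix context in
    ``rerank``).
    """
    n = len(rl)
    if not 1 <= set_size < n:
        raise ValueError(f"set size {set_size} invalid for list of {n}")
    rng = np.random.default_rng(params.seed)
    if params.perm_mode == "gene_set":
        pos = sample_index_sets(rng, n, set_size, params.n_perm)
        return _es_from_positions(pos, np.abs(rl.metric), n, params.weight_p)
    if rerank is None:
        raise ValueError("phenotype permutation requires the matrix context")
    if genes is None:
        raise ValueError("phenotype permutation requires the gene-set members")
    m, case, ref = rerank
    labels = list(case) + list(ref)
    n_case = len(case)
    # fixed hit identity: the permutation shuffles the phenotype, the set stays
    out = np.empty(params.n_perm)
    hit_genes = set(genes)
    for i in range(params.n_perm):
        perm = rng.permutation(labels)
        prl = rank_by_phenotype(m, perm[:n_case], perm[n_case:], params.metric)
        member = np.isin(np.asarray(prl.genes, dtype=object), list(hit_genes))
        out[i] = _es_from_positions(
            np.flatnonzero(member)[None, :], np.abs(prl.metric), len(prl), params.weight_p
        )[0]
    return out


def nes_and_fdr(
    observed: list[EnrichmentResult],
    nulls: dict[str, np.ndarray],
    n_perm: int | None = None,
) -> list[EnrichmentResult]:
    """Complete draft results with NES, nominal p and pooled-null FDR q.

    NES divides each ES by the mean magnitude of same-sign null ES values
    for its own set; null ES are normalized the same way and pooled across
    sets.  q for a positive NES* is the ratio of the pooled-null tail
    fraction at NES* to the observed tail fraction, clamped to
    [1/(n_perm+1), 1]; negative NES mirror.  The add-one convention keeps
    nominal p strictly positive.
    """
    norm_nulls = []
    completed = []
    for r in observed:
        null = np.asarray(nulls[r.set_name], dtype=float)
        if n_perm is None:
            n_perm = len(null)
        pos, neg = null[null > 0], null[null < 0]
        mean_pos = pos.mean() if len(pos) else np.nan
        mean_neg = np.abs(neg).mean() if len(neg) else np.nan
        r.null_summary = {
            "n": len(null),
            "mean_pos": float(mean_pos) if len(pos) else None,
            "mean_neg": float(-mean_neg) if len(neg) else None,
        }
        nn = np.concatenate(
            [pos / mean_pos if len(pos) else pos, neg / mean_neg if len(neg) else neg]
        )
        norm_nulls.append(nn)
        same = pos if r.es > 0 else neg if r.es < 0 else null
        if r.es != 0 and len(same) == 0:
            r.nes, r.p_nominal, r.fdr_q, r.degenerate = float("nan"), 1.0, 1.0, True
            continue
        if r.es == 0:
            r.nes, r.p_nominal = 0.0, 1.0
        else:
            r.nes = r.es / (mean_pos if r.es > 0 else mean_neg)
            r.p_nominal = (1 + int((np.abs(same) >= abs(r.es)).sum())) / (1 + len(same))
        completed.append(r)

    pooled = np.concatenate(norm_nulls) if norm_nulls else np.array([])
    obs_nes = np.array([r.nes for r in completed])
    floor = 1.0 / (n_perm + 1) if n_perm else 0.0
    for r in completed:
        if r.nes > 0:
            n_null_side = max(int((pooled > 0).sum()), 1)
            num = (pooled >= r.nes).sum() / n_null_side
            den = (obs_nes >= r.nes).sum() / max(int((obs_nes > 0).sum()), 1)
        elif r.nes < 0:
            n_null_side = max(int((pooled < 0).sum()), 1)
            num = (pooled <= r.nes).sum() / n_null_side
            den = (obs_nes <= r.nes).sum() / max(int((obs_nes < 0).sum()), 1)
        else:
            r.fdr_q = 1.0
            continue
        r.fdr_q = float(np.clip(num / den if den > 0 else 1.0, floor, 1.0))
    return observed


def gsea(
    input: RankedList | tuple[ExpressionMatrix, Sequence[str], Sequence[str]],
    sets: Sequence[GeneSet],
    params: EnrichmentParams = EnrichmentParams(),
) -> list[EnrichmentResult]:
    """Rank (if needed), score each set, build nulls, and attach NES/FDR.

    ``input`` is either a preranked list or a (matrix, case samples,
    reference samples) triple.  Deterministic given ``params.seed``.
    """
    if isinstance(input, RankedList):
        rl = input
        context = None
    else:
        m, case, ref = input
        rl = rank_by_phenotype(m, case, ref, params.metric)
        context = (m, case, ref)

    if np.all(rl.metric == rl.metric[0]):
        # constant metric: the ranking is pure tie-breaking and carries no
        # information, so every set is degenerate by definition
        logger.warning("constant ranking metric; all enrichments degenerate")
        out = []
        for s in sets:
            member = np.isin(np.asarray(rl.genes, dtype=object), list(s.genes))
            out.append(
                EnrichmentResult(
                    set_name=s.name, es=0.0, nes=0.0, p_nominal=1.0, fdr_q=1.0,
                    leading_edge=(), n_hits=int(member.sum()), degenerate=True,
                )
            )
        return out

    drafts: list[EnrichmentResult] = []
    members: dict[str, np.ndarray] = {}
    for s in sets:
        es, _, leading = enrichment_score(rl, s, params.weight_p)
        member = np.isin(np.asarray(rl.genes, dtype=object), list(s.genes))
        members[s.name] = member
        drafts.append(
            EnrichmentResult(
                set_name=s.name,
                es=es,
                nes=float("nan"),
                p_nominal=1.0,
                fdr_q=1.0,
                leading_edge=leading,
                n_hits=int(member.sum()),
            )
        )

    nulls: dict[str, np.ndarray] = {}
    if params.perm_mode == "gene_set":
        by_size: dict[int, np.ndarray] = {}
        for d in drafts:
            if d.n_hits not in by_size:
                by_size[d.n_hits] = null_distribution(rl, d.n_hits, params)
            nulls[d.set_name] = by_size[d.n_hits]
    else:
        if context is None:
            raise ValueError("phenotype permutation requires matrix input")
        m, case, ref = context
        rng = np.random.default_rng(params.seed)
        labels = np.asarray(list(case) + list(ref), dtype=object)
        n_case = len(case)
        null_mat = np.empty((params.n_perm, len(drafts)))
        for i in range(params.n_perm):
            perm = rng.permutation(labels)
            prl = rank_by_phenotype(m, list(perm[:n_case]), list(perm[n_case:]), params.metric)
            order = {g: j for j, g in enumerate(prl.genes)}
            for k, d in enumerate(drafts):
                hit_genes = np.asarray(rl.genes, dtype=object)[members[d.set_name]]
                pos = np.sort([order[g] for g in hit_genes])
                null_mat[i, k] = _es_from_positions(
                    np.asarray(pos)[None, :], np.abs(prl.metric), len(prl), params.weight_p
                )[0]
        for k, d in enumerate(drafts):
            nulls[d.set_name] = null_mat[:, k]

    return nes_and_fdr(drafts, nulls, n_perm=params.n_perm)


# ---------------------------------------------------------------------------
# I/O


def read_rnk(path: str | Path) -> RankedList:
    """Read a two-column ranked list (gene, metric); header optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    try:
        float(df.iloc[0, 1])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    return RankedList.from_unsorted(
        df.iloc[:, 0].astype(str).str.strip().tolist(),
        df.iloc[:, 1].astype(float).to_numpy(),
    )


def write_rnk(rl: RankedList, path: str | Path) -> None:
    pd.DataFrame({"gene": rl.genes, "metric": rl.metric}).to_csv(
        path, sep="\t", header=False, index=False
    )


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results (leading edge comma-joined)."""
    return pd.DataFrame(
        {
            "set": [r.set_name for r in results],
            "ES": [r.es for r in results],
            "NES": [r.nes for r in results],
            "p_nominal": [r.p_nominal for r in results],
            "fdr_q": [r.fdr_q for r in results],
            "n_hits": [r.n_hits for r in results],
            "leading_edge": [",".join(r.leading_edge) for r in results],
        }
    )
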
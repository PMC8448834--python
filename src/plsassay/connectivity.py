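"""Connectivity-map-style in-silico compound prioritization.

Each perturbagen is represented by a differential z-score profile over
probes (landmark = directly measured, inferred = imputed).  Probes are
collapsed to genes (landmark priority, then maximum |z|), the query
signature's up genes (poor prognosis) and down genes (good prognosis) are
located in the z-ranked profile, and a two-tag Kolmogorov–Smirnov
statistic yields a connectivity score in [-1, 1]: negative scores mark
compounds whose profile opposes the query, i.e. candidate signature
reversers.  A signed percentile tau on the -100..100 scale positions each
score against a background of random queries; the selection filters are
the screen's published conventions (negative score with p < 0.05, or
tau < -90).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import sample_index_sets
from .signature import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeEntry",
    "PerturbationProfile",
    "QuerySignature",
    "ConnectivityResult",
    "collapse_probes",
    "extract_target_signature",
    "ks_tag",
    "connectivity_score",
    "tau_percentile",
    "select_candidates",
    "read_profiles",
    "write_profiles",
    "results_frame",
]


@dataclass(frozen=True)
class ProbeEntry:
    probe: str
    gene: str
    z: float
    probe_class: str = "landmark"  # landmark | inferred

    def __post_init__(self) -> None:
        if self.probe_class not in ("landmark", "inferred"):
            raise ValueError(f"unknown probe class {self.probe_class!r}")
        if not np.isfinite(self.z):
            raise ValueError(f"probe {self.probe!r}: non-finite z-score")


@dataclass
class PerturbationProfile:
    """Per-compound differential z-score profile with probe metadata."""

    perturbagen: str
    entries: tuple[ProbeEntry, ...]

    def __post_init__(self) -> None:
        probes = [e.probe for e in self.entries]
        if len(set(probes)) != len(probes):
            raise ValueError(f"profile {self.perturbagen!r}: duplicate probe ids")


@dataclass(frozen=True)
class QuerySignature:
    """Up/down query gene sets (poor-prognosis up, good-prognosis down)."""

    up: GeneSet
    down: GeneSet

    def __post_init__(self) -> None:
        overlap = set(self.up.genes) & set(self.down.genes)
        if overlap:
            raise ValueError("up and down query sets overlap: " + ", ".join(sorted(overlap)))


@dataclass
class ConnectivityResult:
    perturbagen: str
    ks_up: float
    ks_down: float
    s_raw: float
    score: float = float("nan")
    p_perm: float = 1.0
    tau: float = float("nan")


def collapse_probes(p: PerturbationProfile) -> pd.Series:
    """Collapse probe-level z-scores to one value per gene.

    Landmark probes take priority over inferred ones; among the candidate
    probes the one with the largest |z| wins, ties broken by probe id
    ascending.  Returns a gene -> z series.
    """
    df = pd.DataFrame(
        {
            "probe": [e.probe for e in p.entries],
            "gene": [e.gene for e in p.entries],
            "z": [e.z for e in p.entries],
            "is_landmark": [e.probe_class == "landmark" for e in p.entries],
        }
    )
    df["absz"] = df["z"].abs()
    # sort so the winner is first: landmark first, |z| desc, probe id asc
    df = df.sort_values(
        ["gene", "is_landmark", "absz", "probe"],
        ascending=[True, False, False, True],
    )
    best = df.drop_duplicates("gene", keep="first")
    return pd.Series(best["z"].to_numpy(), index=best["gene"].to_numpy(), name=p.perturbagen)


def extract_target_signature(profile: pd.Series, k: int = 100) -> QuerySignature:
    """Top-k up and bottom-k down genes of a gene-level profile.

    When the profile is shorter than 2k the two sets are shrunk to
    floor(n/2) so they can never overlap.
    """
    n = len(profile)
    if n < 2:
        raise ValueError("profile needs at least 2 genes")
    k = min(k, n // 2)
    # z descending, gene id ascending on ties
    order = np.lexsort((profile.index.to_numpy(dtype=object), -profile.to_numpy()))
    genes = profile.index.to_numpy(dtype=object)[order]
    name = profile.name or "profile"
    return QuerySignature(
        up=GeneSet(name=f"{name}_up", genes=tuple(genes[:k])),
        down=GeneSet(name=f"{name}_down", genes=tuple(genes[-k:])),
    )


def ks_tag(n: int, positions: Sequence[int], t: int | None = None) -> float:
    """Two-sided KS statistic for ``t`` tags at 1-based ``positions`` in a
    list of length ``n``.

    a = max_j (j/t - V_j/n), b = max_j (V_j/n - (j-1)/t); returns a if
    a >= b else -b.  Positive values mean the tags crowd the top of the
    list.
    """
    v = np.asarray(positions, dtype=float)
    if t is None:
        t = len(v)
    if t != len(v):
        raise ValueError("t does not match the number of positions")
    if not 1 <= t < n:
        raise ValueError(f"need 1 <= t < n, got t={t}, n={n}")
    if np.any(np.diff(v) <= 0) or v[0] < 1 or v[-1] > n:
        raise ValueError("positions must be strictly increasing within 1..n")
    j = np.arange(1, t + 1, dtype=float)
    a = np.max(j / t - v / n)
    b = np.max(v / n - (j - 1) / t)
    return float(a if a >= b else -b)


def _ks_many(n: int, pos_matrix: np.ndarray) -> np.ndarray:
    """Vectorized ks_tag over rows of sorted 1-based position matrices."""
    v = np.asarray(pos_matrix, dtype=float)
    t = v.shape[1]
    j = np.arange(1, t + 1, dtype=float)
    a = (j / t - v / n).max(axis=1)
    b = (v / n - (j - 1) / t).max(axis=1)
    return np.where(a >= b, a, -b)


def _tag_positions(ordered_genes: np.ndarray, tag_genes: Sequence[str]) -> np.ndarray:
    member = np.isin(ordered_genes, list(tag_genes))
    return np.flatnonzero(member) + 1  # 1-based


def _order_profile(profile: pd.Series) -> np.ndarray:
    genes = profile.index.to_numpy(dtype=object)
    order = np.lexsort((genes, -profile.to_numpy(dtype=float)))
    return genes[order]


def _s_raw(ks_up: float, ks_down: float) -> float:
    if np.sign(ks_up) == np.sign(ks_down):
        return 0.0
    return ks_up - ks_down


def connectivity_score(
    profiles: Sequence[PerturbationProfile | pd.Series],
    query: QuerySignature,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[ConnectivityResult]:
    """Score every profile in a collection against one up/down query.

    Per profile: genes ranked by z descending; ks_up / ks_down from the
    two tag sets; s_raw = ks_up - ks_down when their signs differ, else 0;
    the final score rescales s_raw by the collection extremes (positives
    by the maximum, negatives by |minimum|) into [-1, 1].  p_perm compares
    |s_raw| with random same-size tag pairs (add-one convention).
    Profiles sharing no gene with either query set are skipped with a
    warning.
    """
    rng = np.random.default_rng(seed)
    results: list[ConnectivityResult] = []
    for prof in profiles:
        series = collapse_probes(prof) if isinstance(prof, PerturbationProfile) else prof
        name = prof.perturbagen if isinstance(prof, PerturbationProfile) else str(series.name)
        ordered = _order_profile(series)
        n = len(ordered)
        pos_up = _tag_positions(ordered, query.up.genes)
        pos_down = _tag_positions(ordered, query.down.genes)
        if len(pos_up) == 0 or len(pos_down) == 0 or len(pos_up) == n or len(pos_down) == n:
            logger.warning("profile %r shares no usable gene with the query; skipped", name)
            continue
        ks_up = ks_tag(n, pos_up)
        ks_down = ks_tag(n, pos_down)
        s = _s_raw(ks_up, ks_down)
        # permutation null: random tag pairs of the same sizes
        null_up = sample_index_sets(rng, n, len(pos_up), n_perm) + 1
        null_down = sample_index_sets(rng, n, len(pos_down), n_perm) + 1
        ku, kd = _ks_many(n, null_up), _ks_many(n, null_down)
        s_null = np.where(np.sign(ku) == np.sign(kd), 0.0, ku - kd)
        p = (1 + int((np.abs(s_null) >= abs(s)).sum())) / (1 + n_perm)
        results.append(
            ConnectivityResult(perturbagen=name, ks_up=ks_up, ks_down=ks_down, s_raw=s, p_perm=p)
        )
    if not results:
        return results
    s_vals = np.array([r.s_raw for r in results])
    p_max = s_vals.max()
    q_min = s_vals.min()
    for r in results:
        if r.s_raw > 0 and p_max > 0:
            r.score = r.s_raw / p_max
        elif r.s_raw < 0 and q_min < 0:
            r.score = r.s_raw / abs(q_min)
        else:
            r.score = 0.0
    return results


def tau_percentile(score: float, background: Sequence[float]) -> float:
    """Signed percentile of |score| within a background score sample.

    tau = sign(score) * 100 * rank(|score|) / |background| where rank
    counts background scores with magnitude <= |score|.
    """
    bg = np.abs(np.asarray(background, dtype=float))
    if len(bg) == 0:
        raise ValueError("background is empty")
    if score == 0:
        return 0.0
    rank = int((bg <= abs(score)).sum())
    return float(np.sign(score) * 100.0 * rank / len(bg))


def random_query_background(
    profiles: Sequence[PerturbationProfile | pd.Series],
    up_size: int,
    down_size: int,
    n_queries: int = 1000,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Background s_raw scores from random queries of matched sizes.

    For each profile, random disjoint up/down gene sets of the query's
    sizes are scored; the per-profile score samples serve as the tau
    background.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for prof in profiles:
        series = collapse_probes(prof) if isinstance(prof, PerturbationProfile) else prof
        name = prof.perturbagen if isinstance(prof, PerturbationProfile) else str(series.name)
        n = len(series)
        k_up = min(up_size, (n - 1) // 2)
        k_down = min(down_size, (n - 1) // 2)
        picks = sample_index_sets(rng, n, k_up + k_down, n_queries)
        # split each sorted draw into disjoint up/down tag sets
        cols = np.argsort(rng.random((n_queries, k_up + k_down)), axis=1)
        rows = np.arange(n_queries)[:, None]
        pos_up = np.sort(picks[rows, cols[:, :k_up]], axis=1) + 1
        pos_down = np.sort(picks[rows, cols[:, k_up:]], axis=1) + 1
        ku, kd = _ks_many(n, pos_up), _ks_many(n, pos_down)
        out[name] = np.where(np.sign(ku) == np.sign(kd), 0.0, ku - kd)
    return out


def attach_tau(
    results: Sequence[ConnectivityResult],
    backgrounds: dict[str, np.ndarray],
) -> list[ConnectivityResult]:
    """Fill in tau for each result from its per-profile background.

    The background holds raw (unscaled) scores, so tau is computed on
    s_raw against the background s_raw magnitudes.
    """
    for r in results:
        r.tau = tau_percentile(r.s_raw, backgrounds[r.perturbagen])
    return list(results)


def select_candidates(results: Sequence[ConnectivityResult], criterion: str) -> list[str]:
    """Apply the published selection filters.

    ``cmap``: negative score and permutation p < 0.05;
    ``lincs``: tau < -90.
    """
    if criterion == "cmap":
        return [r.perturbagen for r in results if r.score < 0 and r.p_perm < 0.05]
    if criterion == "lincs":
        return [r.perturbagen for r in results if r.tau < -90]
    raise ValueError(f"unknown criterion {criterion!r}")


# ---------------------------------------------------------------------------
# I/O


def read_profiles(path: str | Path) -> list[PerturbationProfile]:
    """Read a profile TSV (perturbagen, probe, gene, z, probe_class)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"perturbagen", "probe", "gene", "z", "probe_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    profiles = []
    for name, grp in df.groupby("perturbagen", sort=False):
        entries = tuple(
            ProbeEntry(
                probe=str(r.probe), gene=str(r.gene), z=float(r.z), probe_class=str(r.probe_class)
            )
            for r in grp.itertuples()
        )
        profiles.append(PerturbationProfile(perturbagen=str(name), entries=entries))
    return profiles


def write_profiles(profiles: Sequence[PerturbationProfile], path: str | Path) -> None:
    rows = [
        {
            "perturbagen": p.perturbagen,
            "probe": e.probe,
            "gene": e.gene,
            "z": e.z,
            "probe_class": e.probe_class,
        }
        for p in profiles
        for e in p.entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def results_frame(results: Sequence[ConnectivityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "perturbagen": [r.perturbagen for r in results],
            "ks_up": [r.ks_up for r in results],
            "ks_down": [r.ks_down for r in results],
            "score": [r.score for r in results],
            "p_perm": [r.p_perm for r in results],
            "tau": [r.tau for r in results],
        }
    )
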
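"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written as plain position-by-position loops, kept
deliberately separate from the package's vectorized code paths.
"""

from __future__ import annotations

import numpy as np


def es_brute_force(member: np.ndarray, metric: np.ndarray, weight_p: float) -> float:
    """Running-sum ES by walking the ranked list one position at a time."""
    n = len(member)
    n_hits = int(member.sum())
    weights = [abs(metric[i]) ** weight_p if weight_p > 0 else 1.0 for i in range(n) if member[i]]
    total_w = sum(weights)
    if total_w == 0:
        weights = [1.0] * n_hits
        total_w = float(n_hits)
    run = 0.0
    hi, lo = 0.0, 0.0
    wi = 0
    for i in range(n):
        if member[i]:
            run += weights[wi] / total_w
            wi += 1
        else:
            run -= 1.0 / (n - n_hits)
        hi = max(hi, run)
        lo = min(lo, run)
    # |deviation| ties resolve to the positive extreme (float-stable rule)
    return hi if hi + lo >= -1e-12 else lo


def ks_brute_force(n: int, positions: list[int]) -> float:
    """Exhaustive maximization of the two-tag KS deviations."""
    t = len(positions)
    a = max(j / t - positions[j - 1] / n for j in range(1, t + 1))
    b = max(positions[j - 1] / n - (j - 1) / t for j in range(1, t + 1))
    return a if a >= b else -b


def pooled_fdr_oracle(
    obs_es: dict[str, float], nulls: dict[str, np.ndarray]
) -> dict[str, float]:
    """Independently coded pooled-null NES/FDR procedure (plain loops)."""
    nes = {}
    means = {}
    for name, es in obs_es.items():
        null = nulls[name]
        same = [x for x in null if (x > 0) == (es > 0) and x != 0]
        means[name] = float(np.mean(np.abs(same))) if same else float("nan")
        nes[name] = es / means[name] if same else float("nan")
    pooled = []
    for name, null in nulls.items():
        for x in null:
            if x > 0:
                pos_mean = np.mean([y for y in null if y > 0])
                pooled.append(x / pos_mean)
            elif x < 0:
                neg_mean = np.mean([abs(y) for y in null if y < 0])
                pooled.append(x / neg_mean)
    pooled = np.asarray(pooled)
    obs = np.asarray([v for v in nes.values() if np.isfinite(v)])
    out = {}
    n_perm = len(next(iter(nulls.values())))
    for name, v in nes.items():
        if not np.isfinite(v) or v == 0:
            out[name] = 1.0
            continue
        if v > 0:
            num = (pooled >= v).sum() / max((pooled > 0).sum(), 1)
            den = (obs >= v).sum() / max((obs > 0).sum(), 1)
        else:
            num = (pooled <= v).sum() / max((pooled < 0).sum(), 1)
            den = (obs <= v).sum() / max((obs < 0).sum(), 1)
        q = num / den if den > 0 else 1.0
        out[name] = float(min(max(q, 1.0 / (n_perm + 1)), 1.0))
    return out
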
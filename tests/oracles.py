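"""Independent brute-force reimplementations used as test oracles.

Everything here is deliberately naive — exhaustive loops, full DP matrices,
subset enumeration — and shares no code with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_split(values) -> int | None:
    """Exhaustive two-segment least-squares split index (min within-segment SSE)."""
    v = list(map(float, values))
    n = len(v)
    if n < 2:
        return None
    best_k, best_sse = None, None
    for k in range(1, n):
        left, right = v[:k], v[k:]
        sse = sum((x - sum(left) / len(left)) ** 2 for x in left) + sum(
            (x - sum(right) / len(right)) ** 2 for x in right
        )
        if best_sse is None or sse < best_sse:
            best_k, best_sse = k, sse
    total = sum((x - sum(v) / n) ** 2 for x in v)
    if best_sse >= total - 1e-12:
        return None
    return best_k


def smith_waterman_score(a: str, b: str, match=1, mismatch=-1, gap=-2) -> float:
    """Full-matrix local alignment score (quadratic DP, linear gap penalty)."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = H[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            H[i, j] = max(0.0, diag, H[i - 1, j] + gap, H[i, j - 1] + gap)
    return float(H.max())


def exhaustive_min_cover(universe: set, sets: dict[str, set]) -> int:
    """Size of the smallest sub-collection of ``sets`` covering ``universe``."""
    names = sorted(sets)
    for size in range(0, len(names) + 1):
        for combo in itertools.combinations(names, size):
            covered = set().union(*(sets[c] for c in combo)) if combo else set()
            if universe <= covered:
                return size
    raise ValueError("universe not coverable")


def quartile_membership(all_values, candidate_median_values) -> bool:
    """Is the median of the candidates inside [Q1, Q3] of all values (inclusive)?"""
    med = float(np.median(np.asarray(candidate_median_values, dtype=float)))
    srt = np.sort(np.asarray(all_values, dtype=float))
    q1 = np.percentile(srt, 25)
    q3 = np.percentile(srt, 75)
    return bool(q1 <= med <= q3)


def pairwise_within(points: np.ndarray, anchors: np.ndarray, radius: float) -> np.ndarray:
    """All-pairs distance check: which points lie within radius of any anchor."""
    out = np.zeros(len(points), dtype=bool)
    for i, p in enumerate(points):
        for q in anchors:
            if np.hypot(p[0] - q[0], p[1] - q[1]) <= radius:
                out[i] = True
                break
    return out
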
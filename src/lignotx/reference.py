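"""Naive reference implementations used to validate the fast code paths.

These are deliberately simple, loop-based re-statements of the definitions
(sliding-window motif scan, Sum((O-E)^2/E) chi-square, O(n^3) agglomerative
linkage). They trade speed for transparency and stay independent of the
optimized implementations they check.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .motifs import IUPAC

_RC = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def naive_scan(seq: str, pattern: str, strands: str = "both", prevent_overlap: bool = True) -> list[int]:
    """Greedy left-to-right non-overlapping IUPAC match positions, by definition."""

    def matches_at(s: str, pat: str, i: int) -> bool:
        for j, letter in enumerate(pat):
            c = s[i + j]
            if c == "N":
                if letter != "N":
                    return False
            elif c not in IUPAC[letter]:
                return False
        return True

    seq = seq.upper()
    pats = [pattern.upper()]
    if strands == "both":
        pats.append(pattern.upper().translate(_RC)[::-1])
    k = len(pattern)
    accepted: list[int] = []
    last_end = -1
    for i in range(len(seq) - k + 1):
        if any(matches_at(seq, p, i) for p in pats):
            if prevent_overlap and i < last_end:
                continue
            accepted.append(i)
            last_end = i + k
    return accepted


def naive_chi2(table: Sequence[Sequence[float]]) -> float:
    """Pearson chi-square by the textbook Sum over cells of (O-E)^2/E."""
    t = np.asarray(table, dtype=float)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = t.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            stat += (t[i, j] - e) ** 2 / e
    return stat


def naive_yates_chi2(table: Sequence[Sequence[float]]) -> float:
    """Yates-corrected chi-square: Sum (|O-E| - 0.5)^2 / E, floored at 0 shift."""
    t = np.asarray(table, dtype=float)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = t.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            stat += (max(abs(t[i, j] - e) - 0.5, 0.0)) ** 2 / e
    return stat


def naive_average_linkage(points: np.ndarray, method: str = "average") -> list[float]:
    """Merge heights of O(n^3) agglomerative clustering on Euclidean distances.

    Cluster distances are recomputed from scratch at every step from the
    original point-pair distances (unweighted average / max / min over
    member pairs). Returns the n-1 merge heights in merge order.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    clusters: list[list[int]] = [[i] for i in range(n)]
    heights: list[float] = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                pair = [d[i, j] for i in clusters[a] for j in clusters[b]]
                if method == "average":
                    dist = float(np.mean(pair))
                elif method == "complete":
                    dist = float(np.max(pair))
                elif method == "single":
                    dist = float(np.min(pair))
                else:
                    raise ValueError(method)
                if best is None or dist < best[0]:
                    best = (dist, a, b)
        dist, a, b = best
        heights.append(dist)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return heights


def naive_condition_means(values: np.ndarray, condition_of_column: Sequence[str]) -> dict[str, list[float]]:
    """Loop-based per-condition row means of a genes x samples array."""
    out: dict[str, list[float]] = {}
    conds = []
    for c in condition_of_column:
        if c not in conds:
            conds.append(c)
    for cond in conds:
        cols = [j for j, c in enumerate(condition_of_column) if c == cond]
        means = []
        for row in values:
            means.append(sum(row[j] for j in cols) / len(cols))
        out[cond] = means
    return out
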